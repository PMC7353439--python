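"""Core domain types and unit conventions.

All quantities are stored internally in SI units (seconds, metres,
kilograms, kg/m^3).  File I/O and the CLI speak the laboratory units of
the ion-release protocol (hours, mg/L) and convert at the boundary;
1 mg/L == 1e-3 kg/m^3.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

HOUR = 3600.0  # s
MG_PER_L = 1e-3  # kg/m^3
LITRE = 1e-3  # m^3

#: Molar-mass ratio Cu / CuO, the copper mass fraction of copper(II) oxide.
CU_FRACTION_CUO = 63.546 / 79.545


class ShrinkcoreError(ValueError):
    """Base class for domain errors raised by this package."""


class InvalidInputError(ShrinkcoreError):
    pass


class InsufficientDataError(ShrinkcoreError):
    pass


class DegenerateFitError(ShrinkcoreError):
    pass


class DataInconsistencyWarning(UserWarning):
    """Measured concentrations imply conversion above 1 before clipping."""


class Regime(str, enum.Enum):
    """Candidate rate-limiting step of the shrinking-core dissolution.

    ``MIXED`` is only meaningful for the numerical resistances-in-series
    oracle; the linearizable conversion laws are single-regime.
    """

    LIQUID_FILM = "liquid_film"
    POROUS_SHELL = "porous_shell"
    CORE_REACTION = "core_reaction"
    MIXED = "mixed"


#: The three single-resistance regimes, in canonical (tie-break) order.
SINGLE_REGIMES = (Regime.LIQUID_FILM, Regime.POROUS_SHELL, Regime.CORE_REACTION)


@dataclass(frozen=True)
class ParticleSpec:
    """Physical description of a copper species as homogeneous spheres.

    Parameters
    ----------
    species_label : str
        Free-text label, e.g. ``"Cu-NPs"``.
    radius_R : float
        Initial particle radius R in metres.
    density_rho : float
        Particle (compound) density in kg/m^3.
    copper_mass_fraction : float
        Mass fraction of elemental copper in the compound, in (0, 1].
        1.0 for metallic Cu, Cu/CuO molar-mass ratio (~0.799) for CuO.
    """

    species_label: str
    radius_R: float
    density_rho: float
    copper_mass_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.radius_R > 0:
            raise InvalidInputError("radius_R must be > 0")
        if not self.density_rho > 0:
            raise InvalidInputError("density_rho must be > 0")
        if not 0 < self.copper_mass_fraction <= 1:
            raise InvalidInputError("copper_mass_fraction must be in (0, 1]")

    @property
    def particle_mass(self) -> float:
        """Mass of one particle (compound), kg."""
        return self.density_rho * (4.0 / 3.0) * np.pi * self.radius_R**3

    @property
    def copper_mass_per_particle(self) -> float:
        """Elemental-copper mass of one particle, kg."""
        return self.particle_mass * self.copper_mass_fraction


#: Commercial Cu nanoparticles (<25 nm diameter -> R = 12.5 nm).
CU_NP = ParticleSpec("Cu-NPs", radius_R=12.5e-9, density_rho=8960.0,
                     copper_mass_fraction=1.0)
#: Commercial CuO nanoparticles (<50 nm diameter -> R = 25 nm).
CUO_NP = ParticleSpec("CuO-NPs", radius_R=25e-9, density_rho=6315.0,
                      copper_mass_fraction=CU_FRACTION_CUO)


@dataclass
class SCMParameters:
    """Transport and reaction constants of the shrinking-core model.

    Only the constants relevant to the regime in use need to be set;
    unused constants may stay at 0 (interpreted as "no such resistance"
    by the mixed-control oracle).

    Attributes
    ----------
    k_s : float
        Surface-reaction rate constant, m/s.
    D_e : float
        Effective diffusivity through the porous product shell, m^2/s.
    k_l : float
        Liquid-film mass-transfer coefficient, m/s.
    C_s : float
        Dissolved-ion concentration at the core surface (saturation),
        kg/m^3; the driving force for shell diffusion and core reaction.
    C_shell : float
        Concentration at the outer shell boundary, kg/m^3.
    C_l : float
        Bulk-liquid concentration, kg/m^3; driving force for pure
        liquid-film control.
    N0 : float
        Apparent number of dissolving particles (dimensionless count).
    """

    k_s: float = 0.0
    D_e: float = 0.0
    k_l: float = 0.0
    C_s: float = 1.0
    C_shell: float = 0.0
    C_l: float = 1.0
    N0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_s", "D_e", "k_l"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        for name in ("C_s", "C_shell", "C_l"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")


def _as_1d_float(x: Any, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


@dataclass
class DissolutionSeries:
    """Measured dissolved Cu2+ concentration against time.

    Attributes
    ----------
    times : ndarray
        Sampling times in seconds, strictly increasing, t >= 0.
    concentration : ndarray
        Dissolved copper concentration, kg/m^3.
    volume_V : float
        Solution volume, m^3.
    initial_copper_mass : float
        Total dissolvable elemental-copper mass, kg. Conversion is
        dissolved mass relative to this value.
    """

    times: np.ndarray
    concentration: np.ndarray
    volume_V: float
    initial_copper_mass: float
    label: str = ""

    def __post_init__(self) -> None:
        self.times = _as_1d_float(self.times, "times")
        self.concentration = _as_1d_float(self.concentration, "concentration")
        if self.times.size != self.concentration.size:
            raise InvalidInputError("times and concentration differ in length")
        if self.times.size and self.times[0] < 0:
            raise InvalidInputError("times must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(self.concentration < 0):
            raise InvalidInputError("concentrations must be >= 0")
        if self.volume_V <= 0:
            raise InvalidInputError("volume_V must be > 0")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def times_h(self) -> np.ndarray:
        return self.times / HOUR

    @property
    def concentration_mg_L(self) -> np.ndarray:
        return self.concentration / MG_PER_L


@dataclass
class ConversionSeries:
    """Dimensionless conversion X(t) in [0, 1] derived from a dissolution series."""

    times: np.ndarray
    X: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _as_1d_float(self.times, "times")
        self.X = _as_1d_float(self.X, "X")
        if self.times.size != self.X.size:
            raise InvalidInputError("times and X differ in length")
        if np.any((self.X < 0) | (self.X > 1)):
            raise InvalidInputError("X must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.times.size

    def rescaled_to_plateau(self) -> "ConversionSeries":
        """Renormalize so the maximum observed conversion becomes 1.

        Useful for real curves where only an unknown sub-population of
        the loaded particles dissolves: the shrinking-core laws describe
        per-particle conversion, which saturates at 1 even when the
        dissolved fraction of the total loading is tiny.
        """
        xmax = float(np.max(self.X)) if self.X.size else 0.0
        if xmax <= 0:
            raise InvalidInputError("cannot rescale an all-zero conversion series")
        meta = dict(self.meta)
        meta["rescaled_by"] = xmax
        return ConversionSeries(self.times.copy(), np.clip(self.X / xmax, 0.0, 1.0), meta)


def conversion_from_concentration(
    series: DissolutionSeries,
    spec: ParticleSpec | None = None,
    tolerance: float = 0.05,
) -> ConversionSeries:
    """Map measured concentrations to dimensionless conversion.

    X(t) = C(t) * V / m_Cu,0, clipped to [0, 1].  ``spec`` is accepted
    for API symmetry with the other pipeline stages but is not needed:
    ``initial_copper_mass`` is already elemental-copper mass.

    A :class:`DataInconsistencyWarning` is emitted (and recorded in the
    result metadata) if any pre-clip X exceeds ``1 + tolerance``; the
    default tolerance admits ~2.5 sigma of multiplicative measurement
    noise at the plateau before flagging the metadata as inconsistent.
    """
    if series.initial_copper_mass <= 0:
        raise InvalidInputError("initial_copper_mass must be > 0")
    raw = series.concentration * series.volume_V / series.initial_copper_mass
    meta: dict = {"initial_copper_mass": series.initial_copper_mass,
                  "volume_V": series.volume_V, "label": series.label}
    overshoot = float(np.max(raw, initial=0.0))
    if overshoot > 1.0 + tolerance:
        meta["inconsistent_overshoot"] = overshoot
        warnings.warn(
            f"conversion exceeds 1 before clipping (max {overshoot:.4f}); "
            "check volume / initial mass metadata",
            DataInconsistencyWarning,
            stacklevel=2,
        )
    return ConversionSeries(series.times.copy(), np.clip(raw, 0.0, 1.0), meta)
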