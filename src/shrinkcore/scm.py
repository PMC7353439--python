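"""Shrinking-core conversion laws, characteristic times, and forward model.

A spherical particle of initial radius R dissolves from an unreacted
core of radius r(t), leaving a porous product shell.  Conversion is the
reacted volume fraction

    X = 1 - (r/R)^3.

For each candidate rate-limiting step the integrated law takes the
linear form t/tau = g(X) with

    liquid film    g(X) = X
    porous shell   g(X) = 1 - 3(1-X)^(2/3) + 2(1-X)
    core reaction  g(X) = 1 - (1-X)^(1/3)

and characteristic (complete-conversion) times

    tau_film  = rho R / (3 k_l C_l)
    tau_shell = rho R^2 / (6 D_e C_s)
    tau_rxn   = rho R / (k_s C_s)

These closed forms follow from the classical quasi-steady
resistances-in-series treatment of non-catalytic fluid-solid reactions
(Levenspiel); the numerical oracle :func:`ode_oracle` integrates the
same flux balance directly and is used to cross-check them.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .types import (
    ConversionSeries,
    DissolutionSeries,
    InvalidInputError,
    ParticleSpec,
    Regime,
    SCMParameters,
    SINGLE_REGIMES,
)

__all__ = [
    "g_regime",
    "invert_g",
    "tau",
    "forward_concentration",
    "particle_count_from_mass",
    "ode_oracle",
]


def _check_unit_interval(x: np.ndarray, name: str) -> None:
    if np.any((x < 0) | (x > 1)):
        raise InvalidInputError(f"{name} must lie in [0, 1]")


def g_regime(X, regime: Regime):
    """Dimensionless time t/tau as a function of conversion X.

    Strictly increasing bijection of [0, 1] onto [0, 1] for each of the
    three single-resistance regimes.
    """
    regime = Regime(regime)
    X = np.asarray(X, dtype=float)
    _check_unit_interval(X, "X")
    u3 = 1.0 - X  # (r/R)^3
    if regime is Regime.LIQUID_FILM:
        out = X.copy()
    elif regime is Regime.CORE_REACTION:
        out = 1.0 - np.cbrt(u3)
    elif regime is Regime.POROUS_SHELL:
        out = 1.0 - 3.0 * np.cbrt(u3) ** 2 + 2.0 * u3
    else:
        raise InvalidInputError("g is defined for single regimes only")
    return out if out.ndim else float(out)


def _g_shell_of_u(u: float) -> float:
    # shell law in terms of u = r/R: decreasing from 1 at u=0 to 0 at u=1
    return 1.0 - 3.0 * u * u + 2.0 * u**3


def invert_g(s, regime: Regime):
    """Conversion X at dimensionless time s = t/tau (inverse of :func:`g_regime`).

    Closed form for liquid-film (X = s) and core-reaction
    (X = 1 - (1-s)^3) control; bracketed root-finding on u = (1-X)^(1/3)
    for the cubic porous-shell law.
    """
    regime = Regime(regime)
    s = np.asarray(s, dtype=float)
    _check_unit_interval(s, "s")
    if regime is Regime.LIQUID_FILM:
        out = s.copy()
    elif regime is Regime.CORE_REACTION:
        out = 1.0 - (1.0 - s) ** 3
    elif regime is Regime.POROUS_SHELL:
        flat = np.atleast_1d(s).ravel()
        u = np.empty_like(flat)
        for i, si in enumerate(flat):
            if si <= 0.0:
                u[i] = 1.0
            elif si >= 1.0:
                u[i] = 0.0
            else:
                u[i] = brentq(lambda v: _g_shell_of_u(v) - si, 0.0, 1.0,
                              xtol=1e-15, rtol=8.9e-16)
        out = (1.0 - u**3).reshape(s.shape)
    else:
        raise InvalidInputError("invert_g is defined for single regimes only")
    return out if out.ndim else float(out)


def tau(regime: Regime, spec: ParticleSpec, params: SCMParameters) -> float:
    """Complete-conversion time (s) for a single controlling regime."""
    regime = Regime(regime)
    rho, R = spec.density_rho, spec.radius_R
    if regime is Regime.CORE_REACTION:
        k, C = params.k_s, params.C_s
        if k <= 0 or C <= 0:
            raise InvalidInputError("core reaction requires k_s > 0 and C_s > 0")
        return rho * R / (k * C)
    if regime is Regime.POROUS_SHELL:
        k, C = params.D_e, params.C_s
        if k <= 0 or C <= 0:
            raise InvalidInputError("shell control requires D_e > 0 and C_s > 0")
        return rho * R**2 / (6.0 * k * C)
    if regime is Regime.LIQUID_FILM:
        k, C = params.k_l, params.C_l
        if k <= 0 or C <= 0:
            raise InvalidInputError("film control requires k_l > 0 and C_l > 0")
        return rho * R / (3.0 * k * C)
    raise InvalidInputError("tau is defined for single regimes only")


def forward_concentration(
    regime: Regime,
    spec: ParticleSpec,
    params: SCMParameters,
    times,
    volume_V: float,
    label: str = "",
) -> DissolutionSeries:
    """Simulate the dissolved-copper concentration curve C(t).

    C(t) = N0 * m_p * w_Cu * X(t/tau) / V, where m_p is the mass of one
    particle and X the regime's conversion law.  The curve is monotone
    non-decreasing and plateaus at the full dissolution of the N0
    apparent particles once t >= tau.
    """
    if volume_V <= 0:
        raise InvalidInputError("volume_V must be > 0")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise InvalidInputError("times must be >= 0")
    t_c = tau(regime, spec, params)
    s = np.clip(times / t_c, 0.0, 1.0)
    X = np.asarray(invert_g(s, regime))
    copper_mass = params.N0 * spec.copper_mass_per_particle
    conc = copper_mass * X / volume_V
    return DissolutionSeries(
        times=times,
        concentration=conc,
        volume_V=volume_V,
        initial_copper_mass=copper_mass,
        label=label or spec.species_label,
    )


def particle_count_from_mass(total_compound_mass: float, spec: ParticleSpec) -> float:
    """Number of particles in a given compound mass: m / (rho * 4/3 pi R^3)."""
    if total_compound_mass <= 0:
        raise InvalidInputError("mass must be > 0")
    return total_compound_mass / spec.particle_mass


def _resistance_terms(params: SCMParameters, resistances: frozenset) -> list:
    """Per-regime resistance terms of the quasi-steady flux, as functions of u=r/R.

    The dissolution flux out of one particle is
    W = 4 pi C_drive / [ 1/(k_s r^2) + (1/r - 1/R)/D_e + 1/(k_l R^2) ],
    i.e. the three transport stages act as resistances in series.  Each
    term below is the corresponding contribution to the denominator of
    dr/dt = -(C_drive/rho) / D(u), with r = u R.
    """
    terms = []
    if Regime.CORE_REACTION in resistances:
        if params.k_s <= 0:
            raise InvalidInputError("core_reaction resistance requires k_s > 0")
        terms.append(lambda u, R: 1.0 / params.k_s)
    if Regime.POROUS_SHELL in resistances:
        if params.D_e <= 0:
            raise InvalidInputError("porous_shell resistance requires D_e > 0")
        terms.append(lambda u, R: R * u * (1.0 - u) / params.D_e)
    if Regime.LIQUID_FILM in resistances:
        if params.k_l <= 0:
            raise InvalidInputError("liquid_film resistance requires k_l > 0")
        terms.append(lambda u, R: u * u / params.k_l)
    return terms


def ode_oracle(
    spec: ParticleSpec,
    params: SCMParameters,
    t_grid,
    resistances: Iterable[Regime],
) -> ConversionSeries:
    """Numerically integrate core shrinkage under any set of series resistances.

    The core-shrinkage law du/dt = -(C/rho R)/D(u) for u = r/R, with
    D(u) the sum of the selected stage resistances, is integrated in its
    inverse form dt/du = -(rho R/C) D(u): the trajectory t(u) is smooth
    on the whole of [0, 1] (whereas r(t) starts with infinite slope
    whenever the shell resistance acts alone, since that resistance
    vanishes at u = 1) and is then inverted by monotone interpolation to
    X(t) = 1 - u^3.  With a single resistance this reproduces the
    analytic law invert_g(t/tau); with several, the conversion lies
    below every single-resistance curve (each added resistance slows the
    flux).

    The driving concentration is C_s (core-surface saturation) whenever
    the shell or reaction stage participates, and C_l for a pure
    liquid-film calculation, matching the single-regime tau formulas.
    """
    res = frozenset(Regime(r) for r in resistances) - {Regime.MIXED}
    if not res:
        raise InvalidInputError("at least one resistance must be selected")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size and np.any(np.diff(t_grid) < 0):
        raise InvalidInputError("t_grid must be sorted")
    if res == {Regime.LIQUID_FILM}:
        C_drive = params.C_l
    else:
        C_drive = params.C_s
    if C_drive <= 0:
        raise InvalidInputError("driving concentration must be > 0")
    terms = _resistance_terms(params, res)
    rho, R = spec.density_rho, spec.radius_R
    scale = rho * R / C_drive

    def rhs(u, y):
        # t increases as the core shrinks: dt/du < 0
        return [-scale * sum(f(u, R) for f in terms)]

    # complete-conversion time, sets the absolute tolerance scale
    tau_total = sum(tau(r, spec, params) for r in SINGLE_REGIMES if r in res)
    u_eval = np.linspace(1.0, 0.0, 4001)
    sol = solve_ivp(
        rhs,
        (1.0, 0.0),
        [0.0],
        method="LSODA",
        t_eval=u_eval,
        rtol=1e-10,
        atol=1e-12 * tau_total,
    )
    if sol.status < 0 or sol.y.shape[1] != u_eval.size:
        raise RuntimeError(f"core-shrinkage integration failed: {sol.message}")
    t_of_u = sol.y[0]  # ascending along u_eval (u descending)
    t_of_u[0] = 0.0  # t(u=1) is exactly 0; dense output carries rounding noise
    keep = np.concatenate([[True], np.diff(t_of_u) > 0.0])
    # invert on the sqrt(t) scale: near t=0 the shell-controlled core
    # radius falls like sqrt(t), which is linear in this coordinate
    s_of_u = np.sqrt(np.maximum(t_of_u[keep], 0.0))
    interp = PchipInterpolator(s_of_u, u_eval[keep], extrapolate=False)
    u_at = interp(np.sqrt(np.maximum(t_grid, 0.0)))
    u_at = np.where(np.isnan(u_at), 0.0, u_at)  # beyond core exhaustion
    X = 1.0 - np.clip(u_at, 0.0, 1.0) ** 3
    return ConversionSeries(t_grid, np.clip(X, 0.0, 1.0),
                            meta={"resistances": sorted(r.value for r in res),
                                  "tau_total_s": float(tau_total)})


def mixed_control_time(X, spec: ParticleSpec, params: SCMParameters,
                       resistances: Iterable[Regime]):
    """Exact time to reach conversion X under series resistances.

    Because the stage resistances add, the times add too:
    t(X) = sum_i tau_i g_i(X) over the participating stages.  Used as an
    independent closed-form cross-check of :func:`ode_oracle`.
    """
    res = frozenset(Regime(r) for r in resistances) - {Regime.MIXED}
    if not res:
        raise InvalidInputError("at least one resistance must be selected")
    X = np.asarray(X, dtype=float)
    total = np.zeros_like(X)
    for r in SINGLE_REGIMES:
        if r in res:
            total = total + tau(r, spec, params) * np.asarray(g_regime(X, r))
    return total if total.ndim else float(total)
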