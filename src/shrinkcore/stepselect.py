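"""Rate-limiting-step determination by linearization of conversion data.

Each candidate regime's integrated law has the through-origin form
y = (1/tau) t with y = g_regime(X).  The transient phase of a measured
conversion series is linearized under all three laws; the regime whose
no-intercept regression has the highest adjusted R^2 is selected as the
rate-limiting step.

Adjusted R^2 for the no-intercept model is defined against the raw sum
of squares: R^2 = 1 - SS_res / sum(y^2), adj R^2 = 1 - (1 - R^2) n/(n-1)
(one parameter, no intercept), so that comparisons across regimes are
like-for-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    ConversionSeries,
    DegenerateFitError,
    InsufficientDataError,
    InvalidInputError,
    Regime,
    SINGLE_REGIMES,
)
from .scm import g_regime

__all__ = [
    "TransientWindow",
    "RegimeLinearization",
    "StepDeterminationResult",
    "extract_transient",
    "linearize_fit",
    "select_regime",
    "determine_step",
    "RateLimitingStepSelector",
]


@dataclass
class TransientWindow:
    """Indices of a conversion series belonging to the transient phase."""

    indices: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size < 3:
            raise InsufficientDataError("transient window needs >= 3 points")

    @property
    def n(self) -> int:
        return self.indices.size

    def apply(self, conv: ConversionSeries) -> tuple[np.ndarray, np.ndarray]:
        return conv.times[self.indices], conv.X[self.indices]


@dataclass(frozen=True)
class RegimeLinearization:
    """Through-origin fit of g_regime(X) against t for one candidate regime."""

    regime: Regime
    slope_inv_tau: float  # 1/s
    adjusted_R2: float
    standard_error: float  # residual SE on the g scale
    n_points: int


@dataclass(frozen=True)
class StepDeterminationResult:
    linearizations: dict  # Regime -> RegimeLinearization
    selected: Regime
    tie_flag: bool
    window: TransientWindow | None = None

    def to_rows(self) -> list[dict]:
        """Report rows (one per regime) mirroring the step-selection tables."""
        rows = []
        for regime in SINGLE_REGIMES:
            lin = self.linearizations[regime]
            rows.append({
                "step": regime.value,
                "slope_inv_tau_per_s": lin.slope_inv_tau,
                "adjusted_R2": lin.adjusted_R2,
                "standard_error": lin.standard_error,
                "n_points": lin.n_points,
                "selected": regime is self.selected,
            })
        return rows


def _robust_noise_sd(X: np.ndarray) -> float:
    """Noise SD estimate from the median absolute successive difference.

    For iid noise e, successive differences have SD sqrt(2)*sd(e); the
    median absolute value of a centred normal is 0.6745 of its SD.
    """
    d = np.abs(np.diff(X))
    if d.size == 0:
        return 0.0
    return float(np.median(d) / (np.sqrt(2.0) * 0.67449))


def extract_transient(
    conv: ConversionSeries,
    plateau_fraction: float = 0.95,
    enforce_monotone: bool = True,
) -> TransientWindow:
    """Select the transient-phase window of a conversion series.

    The window runs from the first sample to the first time X reaches
    ``plateau_fraction`` of the maximum observed X, excluding the
    stationary plateau that would bias a through-origin fit.  With
    ``enforce_monotone``, points that fall below the running maximum by
    more than twice the estimated noise SD are excluded — this guards
    against a late-time concentration decline (re-precipitation) leaking
    into the window.
    """
    if conv.n < 4:
        raise InsufficientDataError("need >= 4 points to extract a transient")
    if not 0 < plateau_fraction <= 1:
        raise InvalidInputError("plateau_fraction must be in (0, 1]")
    X = conv.X
    xmax = float(np.max(X))
    if xmax <= 0:
        raise InsufficientDataError("conversion series is identically zero")
    threshold = plateau_fraction * xmax
    end = int(np.argmax(X >= threshold))  # first crossing
    idx = np.arange(end + 1)
    excluded: list[int] = []
    if enforce_monotone:
        tol = 2.0 * _robust_noise_sd(X[idx])
        runmax = np.maximum.accumulate(X[idx])
        keep = X[idx] >= runmax - tol
        excluded = [int(i) for i in idx[~keep]]
        idx = idx[keep]
    if idx.size < 3:
        raise InsufficientDataError(
            f"only {idx.size} transient points survive the window criteria")
    return TransientWindow(idx, meta={
        "plateau_fraction": plateau_fraction,
        "threshold_X": threshold,
        "excluded_indices": excluded,
    })


def linearize_fit(times: np.ndarray, X: np.ndarray, regime: Regime) -> RegimeLinearization:
    """Least-squares through-origin fit of y = g_regime(X) on x = t.

    slope = sum(x y) / sum(x^2); residual standard error and the
    no-intercept adjusted R^2 are reported alongside.
    """
    times = np.asarray(times, dtype=float)
    X = np.asarray(X, dtype=float)
    if times.size != X.size or times.size < 3:
        raise InsufficientDataError("linearization needs >= 3 matched points")
    y = np.asarray(g_regime(X, regime), dtype=float)
    if not np.any(y > 0):
        raise DegenerateFitError("all conversions are zero; nothing to fit")
    sxx = float(np.dot(times, times))
    if sxx == 0.0:
        raise DegenerateFitError("all times are zero")
    slope = float(np.dot(times, y)) / sxx
    resid = y - slope * times
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(y, y))
    n = times.size
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * n / (n - 1)
    se = float(np.sqrt(ss_res / (n - 1)))
    return RegimeLinearization(Regime(regime), slope, adj_r2, se, n)


def select_regime(
    linearizations: dict,
    tie_tolerance: float = 0.005,
    window: TransientWindow | None = None,
) -> StepDeterminationResult:
    """Pick the regime with the best adjusted R^2; flag near-ties.

    On an exact tie the earliest regime in canonical enumeration order
    (liquid film, porous shell, core reaction) wins deterministically.
    """
    missing = [r for r in SINGLE_REGIMES if r not in linearizations]
    if missing:
        raise InvalidInputError(f"missing linearizations for {missing}")
    scores = [linearizations[r].adjusted_R2 for r in SINGLE_REGIMES]
    best = int(np.argmax(scores))
    ranked = sorted(scores, reverse=True)
    tie = bool(ranked[0] - ranked[1] < tie_tolerance)
    return StepDeterminationResult(
        linearizations=dict(linearizations),
        selected=SINGLE_REGIMES[best],
        tie_flag=tie,
        window=window,
    )


def determine_step(
    conv: ConversionSeries,
    plateau_fraction: float = 0.95,
    enforce_monotone: bool = True,
    tie_tolerance: float = 0.005,
) -> StepDeterminationResult:
    """Full step determination: window, three linearizations, selection."""
    window = extract_transient(conv, plateau_fraction, enforce_monotone)
    t_w, X_w = window.apply(conv)
    lins = {r: linearize_fit(t_w, X_w, r) for r in SINGLE_REGIMES}
    return select_regime(lins, tie_tolerance, window)


class RateLimitingStepSelector:
    """Estimator that identifies the rate-limiting dissolution step.

    scikit-learn-style interface: ``fit(t, X)`` takes times (s) and
    conversions in [0, 1]; fitted attributes carry the per-regime
    linearizations and the selected regime.

    Parameters
    ----------
    plateau_fraction : float, default 0.95
        Fraction of the maximum observed conversion that ends the
        transient window.
    enforce_monotone : bool, default True
        Exclude points falling below the running maximum by more than
        twice the estimated noise SD.
    tie_tolerance : float, default 0.005
        Adjusted-R^2 gap below which the selection is flagged ambiguous.

    Attributes
    ----------
    linearizations_ : dict of Regime -> RegimeLinearization
    selected_regime_ : Regime
    tie_flag_ : bool
    window_ : TransientWindow
    """

    def __init__(self, plateau_fraction: float = 0.95,
                 enforce_monotone: bool = True,
                 tie_tolerance: float = 0.005):
        self.plateau_fraction = plateau_fraction
        self.enforce_monotone = enforce_monotone
        self.tie_tolerance = tie_tolerance

    def get_params(self, deep: bool = True) -> dict:
        return {"plateau_fraction": self.plateau_fraction,
                "enforce_monotone": self.enforce_monotone,
                "tie_tolerance": self.tie_tolerance}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, t, X=None):
        """Fit from arrays (t, X) or from a ConversionSeries."""
        if isinstance(t, ConversionSeries):
            conv = t
        else:
            t = np.asarray(t, dtype=float).reshape(-1)
            conv = ConversionSeries(t, np.asarray(X, dtype=float).reshape(-1))
        res = determine_step(conv, self.plateau_fraction,
                             self.enforce_monotone, self.tie_tolerance)
        self.linearizations_ = res.linearizations
        self.selected_regime_ = res.selected
        self.tie_flag_ = res.tie_flag
        self.window_ = res.window
        self.result_ = res
        return self

    def predict(self, t=None):
        """Return the selected regime (constant over any input)."""
        if not hasattr(self, "selected_regime_"):
            raise AttributeError("call fit first")
        return self.selected_regime_
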