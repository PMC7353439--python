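"""Bacterial growth rates and the growth-inhibition indicator.

The exponential-phase growth rate mu is the slope of the least-squares
line through ln(CFU) against time over the exponential window.  The
biocidal effect of a copper-modified membrane is summarized by the
inhibition indicator

    I(%) = (mu_C - mu_B) / mu_C * 100

where mu_C is the control growth rate and mu_B the rate in the presence
of the modified membrane.  I is invariant under a common rescaling of
both rates (so the choice of ln over log10 is immaterial) and strictly
decreasing in mu_B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import (
    InsufficientDataError,
    InvalidInputError,
    _as_1d_float,
)

__all__ = [
    "GrowthCurve",
    "GrowthRateResult",
    "InhibitionResult",
    "growth_rate",
    "inhibition_rate",
    "GrowthRateEstimator",
]


@dataclass
class GrowthCurve:
    """A CFU/mL trajectory.

    Zeros in ``cfu`` are replaced by ``detection_floor`` (half the
    plating detection limit is the conventional choice) so that the log
    transform is defined; the replacement is flagged in ``meta``.
    """

    times_h: np.ndarray
    cfu: np.ndarray
    label: str = ""
    detection_floor: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_h = _as_1d_float(self.times_h, "times_h")
        self.cfu = _as_1d_float(self.cfu, "cfu")
        if self.times_h.size != self.cfu.size:
            raise InvalidInputError("times_h and cfu differ in length")
        if np.any(np.diff(self.times_h) <= 0):
            raise InvalidInputError("times_h must be strictly increasing")
        if np.any(self.cfu < 0):
            raise InvalidInputError("cfu must be >= 0")
        zeros = self.cfu == 0
        if np.any(zeros):
            if self.detection_floor <= 0:
                raise InvalidInputError("detection_floor must be > 0 to "
                                        "replace zero counts")
            self.cfu = np.where(zeros, self.detection_floor, self.cfu)
            self.meta["zeros_floored"] = int(zeros.sum())

    @property
    def n(self) -> int:
        return self.times_h.size


@dataclass(frozen=True)
class GrowthRateResult:
    mu: float  # 1/h
    se: float  # 1/h
    window: tuple  # (start index, stop index exclusive)
    r2: float
    n_points: int
    fallback: bool = False  # no window met the linearity rule


def _ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, its SE, and R^2 of an ordinary least-squares line."""
    n = t.size
    tc = t - t.mean()
    yc = y - y.mean()
    sxx = float(tc @ tc)
    if sxx == 0:
        raise InvalidInputError("degenerate time window")
    slope = float(tc @ yc) / sxx
    resid = yc - slope * tc
    ss_res = float(resid @ resid)
    ss_tot = float(yc @ yc)
    r2 = 1.0 if ss_tot <= 1e-300 else 1.0 - ss_res / ss_tot
    if n > 2:
        se = np.sqrt(ss_res / (n - 2) / sxx)
    else:
        se = np.nan
    return slope, float(se), float(r2)


def growth_rate(
    curve: GrowthCurve,
    window: tuple | None = None,
    min_points: int = 3,
    r2_threshold: float = 0.98,
    slope_tie_rel: float = 0.01,
) -> GrowthRateResult:
    """Exponential-phase growth rate from a CFU trajectory.

    With an explicit ``window`` (start, stop) the slope of ln(CFU) vs t
    is fitted there.  Otherwise every contiguous window of at least
    ``min_points`` points is scored; among windows whose log-linear fit
    has R^2 >= ``r2_threshold`` the maximal slope wins, with slopes
    within ``slope_tie_rel`` of the maximum treated as ties resolved in
    favour of the longest window.  If no window meets the linearity rule
    the maximum-slope ``min_points`` window is used and flagged.
    """
    if curve.n < 4:
        raise InsufficientDataError("need >= 4 points to estimate a growth rate")
    t = curve.times_h
    y = np.log(curve.cfu)
    if window is not None:
        i, j = window
        if j - i < min_points:
            raise InvalidInputError("window too short")
        slope, se, r2 = _ols_slope(t[i:j], y[i:j])
        return GrowthRateResult(slope, se, (i, j), r2, j - i)

    candidates = []  # (slope, length, i, j, se, r2)
    n = curve.n
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            slope, se, r2 = _ols_slope(t[i:j], y[i:j])
            candidates.append((slope, j - i, i, j, se, r2))
    feasible = [c for c in candidates if c[5] >= r2_threshold]
    fallback = not feasible
    if fallback:
        warnings.warn("no window satisfies the log-linearity rule; "
                      "falling back to the steepest minimal window")
        feasible = [c for c in candidates if c[1] == min_points]
    max_slope = max(c[0] for c in feasible)
    tol = slope_tie_rel * abs(max_slope)
    near = [c for c in feasible if c[0] >= max_slope - tol]
    best = max(near, key=lambda c: (c[1], c[0]))  # longest, then steepest
    return GrowthRateResult(best[0], best[4], (best[2], best[3]), best[5],
                            best[1], fallback)


@dataclass(frozen=True)
class InhibitionResult:
    mu_C: float
    mu_B: float
    I_percent: float
    se_I: float
    window_C: tuple | None = None
    window_B: tuple | None = None


def inhibition_rate(mu_C, mu_B) -> InhibitionResult:
    """Growth-inhibition indicator I(%) = (mu_C - mu_B)/mu_C * 100.

    Accepts floats or :class:`GrowthRateResult`; in the latter case the
    standard error of I is propagated from the two slope SEs by the
    delta method.
    """
    wc = wb = None
    se_C = se_B = 0.0
    if isinstance(mu_C, GrowthRateResult):
        wc, se_C, mu_C = mu_C.window, mu_C.se, mu_C.mu
    if isinstance(mu_B, GrowthRateResult):
        wb, se_B, mu_B = mu_B.window, mu_B.se, mu_B.mu
    if not mu_C > 0:
        raise InvalidInputError("control growth rate must be > 0 for I to be defined")
    I = (mu_C - mu_B) / mu_C * 100.0
    se_C = 0.0 if not np.isfinite(se_C) else se_C
    se_B = 0.0 if not np.isfinite(se_B) else se_B
    # dI/dmu_B = -100/mu_C ; dI/dmu_C = 100 mu_B / mu_C^2
    se_I = 100.0 * np.sqrt((se_B / mu_C) ** 2 + (mu_B * se_C / mu_C**2) ** 2)
    return InhibitionResult(mu_C, mu_B, I, float(se_I), wc, wb)


class GrowthRateEstimator:
    """scikit-learn-style estimator for the exponential-phase growth rate.

    ``fit(t, cfu)`` selects the exponential window of the log-linear fit
    (see :func:`growth_rate`) and exposes ``mu_``, ``se_``, ``window_``,
    ``r2_``.  ``predict(t)`` returns the fitted exponential CFU curve.
    """

    def __init__(self, window: tuple | None = None, min_points: int = 3,
                 r2_threshold: float = 0.98, slope_tie_rel: float = 0.01,
                 detection_floor: float = 1.0):
        self.window = window
        self.min_points = min_points
        self.r2_threshold = r2_threshold
        self.slope_tie_rel = slope_tie_rel
        self.detection_floor = detection_floor

    def get_params(self, deep: bool = True) -> dict:
        return {"window": self.window, "min_points": self.min_points,
                "r2_threshold": self.r2_threshold,
                "slope_tie_rel": self.slope_tie_rel,
                "detection_floor": self.detection_floor}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, t, cfu=None, label: str = ""):
        if isinstance(t, GrowthCurve):
            curve = t
        else:
            curve = GrowthCurve(np.asarray(t, dtype=float).reshape(-1),
                                np.asarray(cfu, dtype=float).reshape(-1),
                                label=label, detection_floor=self.detection_floor)
        res = growth_rate(curve, self.window, self.min_points,
                          self.r2_threshold, self.slope_tie_rel)
        self.mu_ = res.mu
        self.se_ = res.se
        self.window_ = res.window
        self.r2_ = res.r2
        self.fallback_ = res.fallback
        self.result_ = res
        i, _ = res.window
        self._t0 = curve.times_h[i]
        self._lnN0 = float(np.log(curve.cfu[i]))
        return self

    def predict(self, t):
        """Exponential extrapolation N(t) = N(t0) exp(mu (t - t0))."""
        if not hasattr(self, "mu_"):
            raise AttributeError("call fit first")
        t = np.asarray(t, dtype=float)
        return np.exp(self._lnN0 + self.mu_ * (t - self._t0))
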