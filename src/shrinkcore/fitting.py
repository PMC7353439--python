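"""Nonlinear least-squares fitting of dissolution curves.

Two models are fitted by minimizing the mean squared error between the
forward concentration curve and the measurements:

* shrinking-core fit: free parameters are the regime's transport
  constant (effective shell diffusivity D_e for porous-shell control)
  and the apparent particle number N0;
* Nernst-Brunner fit for the membrane-complexed species:
  C(t) = C_sat (1 - exp(-k t)) with k = D_e S / (delta V), free
  parameters (k, C_sat) — or (D_e, C_sat) when the geometry (S, delta,
  V) is known.

Both parameters span orders of magnitude, so optimization runs in log
space from several log-spaced starting points.  Confidence intervals
come from the linearized covariance at the optimum (Jacobian-based,
heteroscedasticity-robust by default) or from residual-resampling
bootstrap.

The saturation concentration C_s entering the shrinking-core tau is
degenerate with D_e (only the product is identifiable); the caller
fixes C_s (default 1 kg/m^3) and the reported D_e is the effective
value under that convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .types import (
    DissolutionSeries,
    InsufficientDataError,
    InvalidInputError,
    ParticleSpec,
    Regime,
    SCMParameters,
)
from .scm import forward_concentration, invert_g, tau

__all__ = [
    "SCMFit",
    "NernstBrunnerFit",
    "ShrinkingCoreFitter",
    "NernstBrunnerFitter",
    "fit_scm",
    "fit_nernst_brunner",
    "confidence_intervals",
    "nernst_brunner_curve",
]


def nernst_brunner_curve(t, k: float, C_sat: float):
    """First-order dissolution curve C(t) = C_sat (1 - exp(-k t))."""
    t = np.asarray(t, dtype=float)
    return C_sat * (-np.expm1(-k * t))


@dataclass(frozen=True)
class SCMFit:
    """Fitted shrinking-core parameters with alpha=0.05 confidence intervals."""

    regime: Regime
    D_e: float
    N0: float
    ci_De: float  # half-width
    ci_N0: float  # half-width
    mse: float
    r2_fit: float
    converged: bool
    ci_method: str = "covariance"
    alpha: float = 0.05
    n_points: int = 0


@dataclass(frozen=True)
class NernstBrunnerFit:
    k: float  # 1/s, lumped D_e S / (delta V)
    C_sat: float  # kg/m^3
    ci_k: float
    ci_C_sat: float
    mse: float
    r2_fit: float
    converged: bool
    D_e: float | None = None  # only when S, delta, V supplied
    ci_De: float | None = None
    ci_method: str = "covariance"
    alpha: float = 0.05
    n_points: int = 0


def _multistart_ls(residual, starts, max_nfev=200):
    """Run least_squares from each start (in log space); return the best."""
    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(residual, x0, method="lm",
                                         max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-30:
            best = sol
    if best is None:
        raise RuntimeError("all optimization starts failed")
    return best


def _numeric_jacobian(model, theta, n_out, rel_step=1e-6):
    """Forward-difference Jacobian of model(theta) wrt physical parameters."""
    theta = np.asarray(theta, dtype=float)
    J = np.empty((n_out, theta.size))
    f0 = model(theta)
    for j in range(theta.size):
        h = rel_step * abs(theta[j]) or rel_step
        tp = theta.copy()
        tp[j] += h
        J[:, j] = (model(tp) - f0) / h
    return J


def _covariance_halfwidths(J, resid, alpha, robust=True):
    """CI half-widths from the linearized covariance at the optimum.

    robust=True uses the HC3 leverage-adjusted sandwich estimator
    A^-1 (J' diag(r_i^2/(1-h_ii)^2) J) A^-1, appropriate when the noise
    variance scales with the signal and the design has few, high-leverage
    informative points; False uses the homoscedastic form A^-1 SSR/(n-p).
    Quantiles are Student-t with n-p degrees of freedom.
    """
    n, p = J.shape
    A = J.T @ J
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        warnings.warn("singular Jacobian; confidence intervals use a "
                      "pseudo-inverse and may be very wide")
        Ainv = np.linalg.pinv(A)
    dof = max(n - p, 1)
    if robust:
        leverage = np.clip(np.einsum("ij,jk,ik->i", J, Ainv, J), 0.0, 1.0 - 1e-6)
        r_adj = resid / (1.0 - leverage)
        cov = Ainv @ (J.T @ (r_adj[:, None] ** 2 * J)) @ Ainv
    else:
        ssr = float(resid @ resid)
        cov = Ainv * ssr / dof
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    q = stats.t.ppf(1.0 - alpha / 2.0, dof)
    return q * se


def _bootstrap_halfwidths(residual_builder, model, theta_opt, resid, alpha,
                          n_boot, rng):
    """Residual-resampling bootstrap percentile half-widths (physical scale)."""
    if n_boot < 2:
        warnings.warn("bootstrap with n_boot < 2 gives a degenerate interval")
    yhat = model(theta_opt)
    draws = []
    log0 = np.log(theta_opt)
    for _ in range(max(n_boot, 1)):
        y_star = yhat + rng.choice(resid, size=resid.size, replace=True)
        res_fn = residual_builder(y_star)
        try:
            sol = optimize.least_squares(res_fn, log0, method="lm", max_nfev=100)
            draws.append(np.exp(sol.x))
        except Exception:
            continue
    draws = np.asarray(draws)
    if draws.shape[0] < 2:
        return np.full(theta_opt.size, np.nan)
    lo = np.percentile(draws, 100 * alpha / 2, axis=0)
    hi = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
    return (hi - lo) / 2.0


class _CurveFitterBase:
    """Shared machinery: multi-start log-space LS fit plus CIs."""

    #: subclasses set: _param_names
    def _model(self, t, theta):  # physical parameters
        raise NotImplementedError

    def _starts(self, t, y):
        raise NotImplementedError

    def _fit_arrays(self, t, y):
        t = np.asarray(t, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.size != y.size:
            raise InvalidInputError("t and y differ in length")
        if t.size < 5:
            raise InsufficientDataError("need >= 5 points to fit")

        def residual(logtheta):
            return self._model(t, np.exp(logtheta)) - y

        starts = [np.log(np.asarray(s, dtype=float)) for s in self._starts(t, y)]
        sol = _multistart_ls(residual, starts)
        theta = np.exp(sol.x)
        resid = residual(sol.x)
        ssr = float(resid @ resid)
        n = t.size
        self.theta_ = theta
        self.mse_ = ssr / n
        sst = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - ssr / sst if sst > 0 else (1.0 if ssr == 0 else -np.inf)
        self.converged_ = bool(sol.success)
        self.t_, self.y_ = t, y
        self.resid_ = resid
        # starting costs, to audit that multi-start never made things worse
        self.start_costs_ = [float(0.5 * np.sum(residual(s) ** 2)) for s in starts]
        self.cost_ = float(sol.cost)
        self._set_cis()
        return self

    def _set_cis(self):
        alpha = self.alpha
        model = lambda th: self._model(self.t_, th)
        if self.ci_method == "bootstrap":
            rng = np.random.default_rng(self.random_state)
            builder = lambda y_star: (
                lambda logtheta: self._model(self.t_, np.exp(logtheta)) - y_star)
            hw = _bootstrap_halfwidths(builder, model, self.theta_, self.resid_,
                                       alpha, self.n_boot, rng)
        else:
            robust = self.ci_method != "covariance_iid"
            J = _numeric_jacobian(model, self.theta_, self.t_.size)
            self.jacobian_ = J
            hw = _covariance_halfwidths(J, self.resid_, alpha, robust=robust)
        self.ci_halfwidths_ = hw

    def predict(self, t):
        """Model concentration (kg/m^3) at times t (s) for the fitted parameters."""
        if not hasattr(self, "theta_"):
            raise AttributeError("call fit first")
        return self._model(np.asarray(t, dtype=float).reshape(-1), self.theta_)

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_keys}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_keys:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def score(self, t=None, y=None):
        return self.r2_


class ShrinkingCoreFitter(_CurveFitterBase):
    """Fit (D_e, N0) of the shrinking-core forward model to a dissolution curve.

    Parameters
    ----------
    particle : ParticleSpec
        Geometry/density of the dissolving species.
    regime : Regime, default porous shell
        Rate-limiting step (from step determination).  The fitted
        transport constant is D_e (m^2/s) for shell control, k_s or k_l
        (m/s) for reaction/film control; it is always exposed as
        ``De_`` for uniformity.
    C_s : float, default 1.0
        Core-surface saturation concentration, kg/m^3.  Degenerate with
        D_e (only the product enters tau); fix it and interpret D_e as
        effective under this convention.
    volume_V : float, default 1e-3
        Solution volume, m^3 (1 L).
    n_starts : int, default 5
        Log-spaced initial guesses for the characteristic time.
    ci_method : {"covariance", "covariance_iid", "bootstrap"}
    alpha : float, default 0.05

    Attributes
    ----------
    De_, N0_ : float
        Fitted parameters.
    ci_De_, ci_N0_ : float
        Confidence-interval half-widths at level alpha.
    mse_, r2_, converged_ : fit diagnostics.
    """

    _param_keys = ("particle", "regime", "C_s", "volume_V", "n_starts",
                   "ci_method", "alpha", "n_boot", "random_state")

    def __init__(self, particle: ParticleSpec, regime: Regime = Regime.POROUS_SHELL,
                 C_s: float = 1.0, volume_V: float = 1e-3, n_starts: int = 5,
                 ci_method: str = "covariance", alpha: float = 0.05,
                 n_boot: int = 200, random_state: int | None = 0):
        self.particle = particle
        self.regime = Regime(regime)
        self.C_s = C_s
        self.volume_V = volume_V
        self.n_starts = n_starts
        self.ci_method = ci_method
        self.alpha = alpha
        self.n_boot = n_boot
        self.random_state = random_state

    # -- forward model ---------------------------------------------------
    def _tau_of_constant(self, kappa: float) -> float:
        if kappa <= 0:  # log-parameter underflow during optimization
            return np.inf
        rho, R = self.particle.density_rho, self.particle.radius_R
        if self.regime is Regime.POROUS_SHELL:
            return rho * R**2 / (6.0 * kappa * self.C_s)
        if self.regime is Regime.CORE_REACTION:
            return rho * R / (kappa * self.C_s)
        if self.regime is Regime.LIQUID_FILM:
            return rho * R / (3.0 * kappa * self.C_s)
        raise InvalidInputError("fit requires a single regime")

    def _constant_of_tau(self, t_c: float) -> float:
        rho, R = self.particle.density_rho, self.particle.radius_R
        if self.regime is Regime.POROUS_SHELL:
            return rho * R**2 / (6.0 * t_c * self.C_s)
        if self.regime is Regime.CORE_REACTION:
            return rho * R / (t_c * self.C_s)
        return rho * R / (3.0 * t_c * self.C_s)

    def _model(self, t, theta):
        kappa, N0 = theta
        t_c = self._tau_of_constant(kappa)
        s = np.clip(t / t_c, 0.0, 1.0)
        X = np.asarray(invert_g(s, self.regime))
        return N0 * self.particle.copper_mass_per_particle * X / self.volume_V

    def _starts(self, t, y):
        plateau = float(np.max(y))
        if plateau <= 0:
            raise InsufficientDataError("concentration signal is identically zero")
        N0_init = plateau * self.volume_V / self.particle.copper_mass_per_particle
        t_pos = t[t > 0]
        tau_grid = np.geomspace(float(t_pos.min()), 10.0 * float(t.max()),
                                max(self.n_starts, 1))
        return [(self._constant_of_tau(tc), N0_init) for tc in tau_grid]

    def fit(self, t, y=None):
        """Fit from arrays (t seconds, C kg/m^3) or a DissolutionSeries."""
        if isinstance(t, DissolutionSeries):
            t, y = t.times, t.concentration
        self._fit_arrays(t, y)
        self.De_, self.N0_ = self.theta_
        self.ci_De_, self.ci_N0_ = self.ci_halfwidths_
        return self

    @property
    def tau_(self) -> float:
        return self._tau_of_constant(self.De_)

    def result(self) -> SCMFit:
        return SCMFit(self.regime, self.De_, self.N0_, self.ci_De_, self.ci_N0_,
                      self.mse_, self.r2_, self.converged_, self.ci_method,
                      self.alpha, self.t_.size)


class NernstBrunnerFitter(_CurveFitterBase):
    """Fit the first-order Nernst-Brunner dissolution law.

    C(t) = C_sat (1 - exp(-k t)), with k = D_e S / (delta V) when the
    dissolving area S, shell (active-layer) thickness delta and solution
    volume V are known; otherwise the lumped rate k alone is reported.

    Attributes
    ----------
    k_ : float           fitted rate constant, 1/s
    C_sat_ : float       fitted saturation concentration, kg/m^3
    De_ : float or None  back-calculated D_e = k delta V / S
    ci_k_, ci_C_sat_, ci_De_ : CI half-widths
    """

    _param_keys = ("S", "delta", "V", "n_starts", "ci_method", "alpha",
                   "n_boot", "random_state")

    def __init__(self, S: float | None = None, delta: float | None = None,
                 V: float | None = None, n_starts: int = 5,
                 ci_method: str = "covariance", alpha: float = 0.05,
                 n_boot: int = 200, random_state: int | None = 0):
        if (S is not None or delta is not None) and not (
                S and delta and V):
            raise InvalidInputError(
                "provide all of S, delta, V to resolve D_e, or none of them")
        self.S = S
        self.delta = delta
        self.V = V
        self.n_starts = n_starts
        self.ci_method = ci_method
        self.alpha = alpha
        self.n_boot = n_boot
        self.random_state = random_state

    def _model(self, t, theta):
        k, C_sat = theta
        return nernst_brunner_curve(t, k, C_sat)

    def _starts(self, t, y):
        C_init = float(np.max(y))
        if C_init <= 0:
            raise InsufficientDataError("concentration signal is identically zero")
        t_pos = t[t > 0]
        k_grid = np.geomspace(0.1 / float(t.max()), 10.0 / float(t_pos.min()),
                              max(self.n_starts, 1))
        return [(k, C_init) for k in k_grid]

    def fit(self, t, y=None):
        if isinstance(t, DissolutionSeries):
            t, y = t.times, t.concentration
        self._fit_arrays(t, y)
        self.k_, self.C_sat_ = self.theta_
        self.ci_k_, self.ci_C_sat_ = self.ci_halfwidths_
        if self.S is not None:
            geom = self.delta * self.V / self.S
            self.De_ = self.k_ * geom
            self.ci_De_ = self.ci_k_ * geom
        else:
            self.De_ = None
            self.ci_De_ = None
        return self

    def result(self) -> NernstBrunnerFit:
        return NernstBrunnerFit(self.k_, self.C_sat_, self.ci_k_, self.ci_C_sat_,
                                self.mse_, self.r2_, self.converged_,
                                self.De_, self.ci_De_, self.ci_method,
                                self.alpha, self.t_.size)


def fit_scm(series: DissolutionSeries, regime: Regime, spec: ParticleSpec,
            C_s: float = 1.0, **kwargs) -> SCMFit:
    """Functional wrapper around :class:`ShrinkingCoreFitter`."""
    est = ShrinkingCoreFitter(particle=spec, regime=regime, C_s=C_s,
                              volume_V=series.volume_V, **kwargs)
    return est.fit(series).result()


def fit_nernst_brunner(series: DissolutionSeries, S: float | None = None,
                       delta: float | None = None, V: float | None = None,
                       **kwargs) -> NernstBrunnerFit:
    """Functional wrapper around :class:`NernstBrunnerFitter`."""
    est = NernstBrunnerFitter(S=S, delta=delta, V=V, **kwargs)
    return est.fit(series).result()


def confidence_intervals(fitter, method: str = "covariance",
                         alpha: float = 0.05, n_boot: int = 200,
                         seed: int | None = 0) -> np.ndarray:
    """Recompute CI half-widths for a fitted estimator with another method."""
    if not hasattr(fitter, "theta_"):
        raise InvalidInputError("fitter must be fitted first")
    fitter.ci_method = method
    fitter.alpha = alpha
    fitter.n_boot = n_boot
    fitter.random_state = seed
    fitter._set_cis()
    if hasattr(fitter, "De_") and isinstance(fitter, ShrinkingCoreFitter):
        fitter.ci_De_, fitter.ci_N0_ = fitter.ci_halfwidths_
    elif isinstance(fitter, NernstBrunnerFitter):
        fitter.ci_k_, fitter.ci_C_sat_ = fitter.ci_halfwidths_
    return fitter.ci_halfwidths_
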