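# Methods

## Shrinking-core model

The package treats a dissolving copper species as a population of `N0`
identical spheres of initial radius `R` and density `rho`.  Dissolution
proceeds from a shrinking unreacted core of radius `r(t)`; the reacted
volume fraction is the conversion `X = 1 - (r/R)^3`.  Three serial
transport stages can limit the rate: diffusion through the liquid film
around the particle, diffusion through the porous product shell (for
membrane-incorporated copper, the polyamide active layer plays the role
of the shell), and the surface reaction at the core.  Under quasi-steady
transport each single-stage law integrates to `t/tau = g(X)` with the
`g` and `tau` listed in the README table.

Assumptions inherited from the classical treatment: spherical,
homogeneous particles of a single size; quasi-steady shell/film
transport; constant driving concentration (core-surface saturation
`C_s`, or bulk `C_l` for pure film control); constant particle density.
None of the three laws models oxygen depletion, pH/Eh shifts, or
re-precipitation of dissolved copper — a late-time concentration
decline can be *generated* as a data corruption (see below) and is
*excluded* from analysis windows, but is never mechanistically fitted.

A note on the conversion definition: written in terms of the core
radius the quantity `(r/R)^3` is the *unreacted* volume fraction; the
integrated laws close only for `X = 1 - (r/R)^3`, which is what the
package uses throughout.

### Ordering of the laws

`g_shell(X) <= g_rxn(X) <= g_film(X)` holds for `X <= 0.875`: early in
the transient, shell control accumulates dimensionless time slowest
(it starts quadratically, `g_shell ~ X^2/3`, while both other laws
start linearly).  The shell and reaction laws cross exactly at
`X = 0.875` (`u = r/R = 1/2`), where both equal `1/2`; beyond it the
shell law overtakes.  The film law dominates the shell law everywhere
(`g_film - g_shell = 3u^2(1-u) >= 0`).  This is why film and reaction
control are hard to tell apart from small-conversion data (both are
near-linear there) while shell control separates early.

### Numerical oracle

`ode_oracle` integrates the quasi-steady flux balance with any subset
of the three resistances in series,

    dr/dt = -(C_drive/rho) / [ 1/k_s + r^2 (1/r - 1/R)/D_e + r^2/(k_l R^2) ],

dropping the terms of unselected stages.  The integration runs in the
inverse form `dt/du` (`u = r/R`), which is polynomial and smooth on all
of [0, 1] — in the direct form the shell resistance vanishes at `u = 1`,
so shell-limited shrinkage starts with infinite slope and defeats
adaptive steppers.  The trajectory `t(u)` from LSODA (rtol 1e-10) is
inverted to `X(t)` with a monotone cubic interpolant on the `sqrt(t)`
scale, where the square-root start becomes linear.  Single-resistance
runs agree with the closed forms to ~3e-6 relative over
`X` in [0.01, 0.99]; the tests assert 1e-4.  For mixed control the
resistances (hence the single-stage times) add, so
`t(X) = sum_i tau_i g_i(X)` exactly; this closed form is used as an
independent cross-check of the oracle.  The driving concentration is
`C_s` whenever shell or reaction participates and `C_l` for a pure-film
calculation, matching the single-regime `tau` definitions (the
mixed-control cross-checks set `C_l = C_s`).

## Step determination

Measured concentrations map to conversion as
`X(t) = C(t) V / m_Cu,0` (clipped to [0, 1]); `m_Cu,0` is the
*dissolvable* copper mass.  For synthetic data that mass is
`N0 * m_particle * w_Cu` by construction, so `X` spans [0, 1].  For real
curves where only an unknown sub-population dissolves, supplying the
total loading leaves `X` far below 1; `ConversionSeries.rescaled_to_plateau`
renormalizes to the observed plateau so the per-particle laws apply.
Pre-clip conversions above `1 + 0.05` flag the series metadata as
inconsistent (the 5% margin admits ~2.5 sigma of the default
multiplicative noise at the plateau before warning).

The transient window runs from the first sample to the first time `X`
reaches `plateau_fraction` (default 0.95) of the maximum observed `X` —
the stationary plateau would otherwise bias a through-origin fit.  With
`enforce_monotone` (default), points falling below the running maximum
by more than twice the estimated noise SD are excluded; the noise SD is
estimated robustly as `median(|successive differences|)/(sqrt(2) * 0.6745)`.
This keeps a late-time re-precipitation decline out of the window.

Each candidate law is fitted through the origin (`y = g(X)`, `x = t`,
slope `= sum(xy)/sum(x^2) = 1/tau`).  For the no-intercept model the
package defines `R^2 = 1 - SS_res / sum(y^2)` and
`adj R^2 = 1 - (1 - R^2) n/(n-1)` (one parameter, no intercept), so the
three regimes are compared like-for-like.  The highest adjusted `R^2`
wins; a gap below `tie_tolerance` (default 0.005) raises an explicit
ambiguity flag rather than a silent choice, and an exact tie resolves
deterministically in enumeration order (film, shell, reaction).

## Parameter fitting

The shrinking-core fit minimizes the MSE between the forward model and
the measured concentrations with `(D_e, N0)` free (for shell control;
the analogous constant for the other regimes).  `C_s` enters `tau` only
through the product `D_e * C_s` and is therefore not separately
identifiable: the caller fixes it (default 1 kg/m^3) and the reported
`D_e` is the effective value under that convention.  Because both
parameters span orders of magnitude (1e-11 m^2/s, 1e12 particles), the
optimizer works on `(log D_e, log N0)` with Levenberg–Marquardt from 5
starting points whose characteristic times are log-spaced between the
first positive sample time and 10x the last — the forward model is flat
in `D_e` once `tau` falls below the sampling grid, so a single bad
start can stall.  `N0` starts at the plateau-implied count.  The
reported fit never has a higher cost than any start.

The Nernst–Brunner fit works the same way on
`C(t) = C_sat (1 - exp(-k t))` with free `(k, C_sat)`; when the
dissolving area `S`, layer thickness `delta` and volume `V` are known,
`D_e = k delta V / S` is reported as well.  The tabulated saturation
for the copper–oligomer membrane is quoted in mg; with the 1 L test
volume, mg and mg/L are numerically identical, and the package treats
the value as mass dissolved in the test volume.

### Confidence intervals

Default intervals come from the linearized covariance at the optimum
with the HC3 leverage-adjusted sandwich estimator,

    cov = A^-1 [ J' diag(r_i^2 / (1 - h_ii)^2) J ] A^-1,  A = J'J,

and Student-t quantiles with `n - p` degrees of freedom.  The plain
homoscedastic form `A^-1 SSR/(n-p)` (available as
`ci_method="covariance_iid"`) undercovers badly here — measurement
noise scales with the signal while the objective is unweighted MSE, and
the information about `D_e` is concentrated in a few high-leverage
transient points; in the package's own coverage simulation (200 fits at
2% noise) the plain form covered ~79% at nominal 95% versus ~95% for
the HC3/t default.  Residual-resampling bootstrap percentile intervals
are available as `ci_method="bootstrap"` (default 200 draws, seeded).

## Growth inhibition

`mu` is the ordinary least-squares slope of `ln(CFU)` against time over
the exponential window.  The indicator `I = (mu_C - mu_B)/mu_C * 100`
is invariant to a common rescaling of both rates, so the choice of
natural log over log10 is immaterial; natural log is used.  When no
window is given, every contiguous window of >= 3 points is scored and
the steepest window whose log-linear `R^2` is >= 0.98 wins; slopes
within 1% of the maximum count as ties and resolve to the longest
window (slightly longer windows damp the upward selection bias of
noisy 3-point windows).  If nothing meets the linearity rule the
steepest minimal window is used with a warning.  Zero counts are
replaced by a detection floor (half the plating detection limit is the
conventional choice) and flagged, since the log transform requires
positivity.  The SE of `I` is propagated from the two slope SEs by the
delta method; bootstrap over replicates is left to the caller.

## Synthetic data

The dissolution generator draws the clean curve from the forward model
(or the Nernst–Brunner closed form), applies multiplicative Gaussian
noise (`CV` default 2% — atomic-absorption error scales with signal)
plus an optional additive floor for near-zero readings, and optionally
a linear post-peak decline (a corruption fixture mimicking observed
late re-precipitation, not a mechanism).  Defaults mirror the release
protocol: 1 L volume, sampling dense in the first hour then day-scale
out to 240 h, Cu spheres of R = 12.5 nm at 8960 kg/m^3 (CuO: 25 nm,
6315 kg/m^3, copper mass fraction 63.546/79.545).  The ground-truth
`(D_e, N0)` default to the tabulated suspension values (2.39e-11 m^2/s,
1.17e12); since only `D_e * C_s` is identifiable, the scenario chooses
`C_s` to place complete conversion at 96 h, inside the protocol window
— without this the curve would saturate within minutes and carry no
kinetic information.  `transient_schedule` places points at equal
conversion increments for regime-recovery studies.

The growth generator produces lag/exponential/stationary trajectories
as logistic growth with a discrete lag: inoculum 1e7 CFU/mL, lag 4 h,
`mu_C = 0.5 /h`, carrying capacity 2e9 CFU/mL, lognormal noise
(CV 5%), 0–48 h every 2 h.  The capacity sits in the realistic
stationary range for E. coli in rich media (1–5e9 CFU/mL); at 1e9 the
exponential phase is so short that logistic bending biases the
log-linear slope by ~3% even on clean data, while at 2e9 the clean bias
is ~1.6%.  The treated culture grows at
`mu_B = (1 - I_target/100) mu_C` (default `I_target` 55%, the middle of
the reported membrane range).  Identical scenario + seed gives
byte-identical data.

What the generators do *not* emulate: particle size distributions,
agglomeration dynamics, oxygen- or pH-dependent kinetics, death-phase
CFU decline, plating error structure beyond lognormal noise.  Passing
recovery tests therefore demonstrate that the estimators are correct
and well-calibrated *under the stated noise model*, not that real
curves obey the model.

## Numerical choices and limitations

- Internal units are SI (s, m, kg, kg/m^3); files and the CLI use hours
  and mg/L, converted only at the boundary.
- `invert_g` for the shell law uses bracketed Brent root-finding on
  `u = (1-X)^(1/3)` (the cubic is monotone on [0, 1]) to machine
  tolerance; the other two laws invert in closed form.
- Through-origin linearization of a curve with all-zero conversions, or
  a window with fewer than 3 surviving points, raises a typed error
  rather than returning NaNs.
- The fit assumes a single rate-limiting step; mixed-control curves can
  be simulated via the oracle but not fitted (the linearization
  methodology is single-regime by construction).
- Problem sizes in the test-suite simulations (50–200 replicates,
  100-series recovery runs) were chosen as the smallest giving stable
  medians and coverage estimates; all complete in seconds.
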