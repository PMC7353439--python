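"""Nonlinear dissolution-curve fits: recovery, scaling, identifiability, CIs."""

import numpy as np
import pytest

import shrinkcore as sk
from shrinkcore import Regime


def shell_series(seed=None, noise_cv=0.0, N0=1.17e12, De=2.39e-11):
    sc = sk.DissolutionScenario(D_e=De, N0=N0, noise_cv=noise_cv,
                                seed=seed if seed is not None else 0)
    return sk.gen_dissolution(sc)


class TestShrinkingCoreFit:
    def test_noise_free_self_consistency(self):
        series, truth = shell_series(noise_cv=0.0)
        est = sk.ShrinkingCoreFitter(particle=sk.CU_NP, C_s=truth["C_s"],
                                     volume_V=1e-3).fit(series)
        assert est.De_ == pytest.approx(truth["D_e"], rel=1e-6)
        assert est.N0_ == pytest.approx(truth["N0"], rel=1e-6)
        assert est.mse_ == pytest.approx(0.0, abs=1e-25)
        assert est.converged_

    def test_predict_matches_forward_model(self):
        """The fitting objective and the forward simulator are the same
        curve: no drift between them at fixed parameters."""
        series, truth = shell_series(noise_cv=0.0)
        est = sk.ShrinkingCoreFitter(particle=sk.CU_NP, C_s=truth["C_s"],
                                     volume_V=1e-3).fit(series)
        params = sk.SCMParameters(D_e=est.De_, C_s=truth["C_s"], N0=est.N0_)
        fwd = sk.forward_concentration(Regime.POROUS_SHELL, sk.CU_NP, params,
                                       series.times, 1e-3)
        assert np.allclose(est.predict(series.times), fwd.concentration,
                           rtol=1e-12, atol=0)

    def test_doubling_N0_doubles_plateau_not_De(self):
        series1, t1 = shell_series(noise_cv=0.0)
        series2, t2 = shell_series(noise_cv=0.0, N0=2 * 1.17e12)
        e1 = sk.ShrinkingCoreFitter(particle=sk.CU_NP, C_s=t1["C_s"],
                                    volume_V=1e-3).fit(series1)
        e2 = sk.ShrinkingCoreFitter(particle=sk.CU_NP, C_s=t2["C_s"],
                                    volume_V=1e-3).fit(series2)
        assert e2.N0_ == pytest.approx(2 * e1.N0_, rel=1e-5)
        assert e2.De_ == pytest.approx(e1.De_, rel=1e-5)
        assert max(e2.predict(series2.times)) == pytest.approx(
            2 * max(e1.predict(series1.times)), rel=1e-5)

    def test_noisy_recovery_at_table_scale(self):
        """CV=2% noise, 50 seeds: median recovered De and N0 within 10%
        of the generating values."""
        des, n0s = [], []
        for seed in range(50):
            series, truth = shell_series(seed=seed, noise_cv=0.02)
            est = sk.ShrinkingCoreFitter(particle=sk.CU_NP, C_s=truth["C_s"],
                                         volume_V=1e-3).fit(series)
            des.append(est.De_)
            n0s.append(est.N0_)
        assert abs(np.median(des) / 2.39e-11 - 1) < 0.10
        assert abs(np.median(n0s) / 1.17e12 - 1) < 0.10

    def test_multistart_never_worse_than_starts(self):
        series, truth = shell_series(seed=11, noise_cv=0.02)
        est = sk.ShrinkingCoreFitter(particle=sk.CU_NP, C_s=truth["C_s"],
                                     volume_V=1e-3).fit(series)
        assert est.cost_ <= min(est.start_costs_) + 1e-30

    def test_jacobian_full_rank(self):
        """(De, N0) are jointly identifiable with C_s fixed."""
        series, truth = shell_series(seed=5, noise_cv=0.02)
        est = sk.ShrinkingCoreFitter(particle=sk.CU_NP, C_s=truth["C_s"],
                                     volume_V=1e-3).fit(series)
        # columns carry the units of 1/De and 1/N0 and differ by ~20
        # orders of magnitude; normalize before the rank check
        J = est.jacobian_
        Js = J / np.linalg.norm(J, axis=0)
        assert np.linalg.matrix_rank(Js) == 2

    def test_too_few_points_rejected(self):
        with pytest.raises(sk.InsufficientDataError):
            sk.ShrinkingCoreFitter(particle=sk.CU_NP).fit(
                np.array([0.0, 1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0, 3.0]))

    def test_functional_wrapper_returns_record(self):
        series, truth = shell_series(noise_cv=0.0)
        fit = sk.fit_scm(series, Regime.POROUS_SHELL, sk.CU_NP, C_s=truth["C_s"])
        assert isinstance(fit, sk.SCMFit)
        assert fit.regime is Regime.POROUS_SHELL
        assert fit.r2_fit == pytest.approx(1.0, abs=1e-10)


class TestNernstBrunnerFit:
    def nb_series(self, seed=0, noise_cv=0.0, k=1 / (48 * sk.HOUR),
                  C_sat=2.49e-3):
        sc = sk.DissolutionScenario(nb_k=k, nb_C_sat=C_sat, seed=seed,
                                    noise_cv=noise_cv)
        return sk.gen_dissolution(sc)

    def test_noise_free_exact_recovery(self):
        series, truth = self.nb_series()
        est = sk.NernstBrunnerFitter().fit(series)
        assert est.k_ == pytest.approx(truth["nb_k"], rel=1e-8)
        assert est.C_sat_ == pytest.approx(truth["nb_C_sat"], rel=1e-8)

    def test_infinite_time_limit_is_saturation(self):
        series, truth = self.nb_series()
        est = sk.NernstBrunnerFitter().fit(series)
        far = est.predict(np.array([1e12]))
        assert far[0] == pytest.approx(est.C_sat_, rel=1e-10)

    def test_noisy_saturation_recovery(self):
        """Truth C_sat = 2.49 mg in 1 L; CV=2%, 50 seeds; the median
        recovered C_sat stays within 10%."""
        cs = []
        for seed in range(50):
            series, _ = self.nb_series(seed=seed, noise_cv=0.02)
            cs.append(sk.NernstBrunnerFitter().fit(series).C_sat_)
        assert abs(np.median(cs) / 2.49e-3 - 1) < 0.10

    def test_geometry_resolves_diffusivity(self):
        """With S, delta, V given, D_e = k delta V / S."""
        series, truth = self.nb_series()
        S, delta, V = 1e-3, 1e-7, 1e-3  # membrane coupon area, PA thickness
        est = sk.NernstBrunnerFitter(S=S, delta=delta, V=V).fit(series)
        assert est.De_ == pytest.approx(truth["nb_k"] * delta * V / S, rel=1e-6)

    def test_partial_geometry_rejected(self):
        with pytest.raises(sk.InvalidInputError):
            sk.NernstBrunnerFitter(S=1e-3)


class TestConfidenceIntervals:
    def test_zero_noise_gives_null_intervals(self):
        series, truth = shell_series(noise_cv=0.0)
        est = sk.ShrinkingCoreFitter(particle=sk.CU_NP, C_s=truth["C_s"],
                                     volume_V=1e-3).fit(series)
        assert est.ci_De_ < 1e-6 * est.De_
        assert est.ci_N0_ < 1e-6 * est.N0_

    def test_bootstrap_single_draw_flagged(self):
        series, truth = shell_series(seed=2, noise_cv=0.02)
        est = sk.ShrinkingCoreFitter(particle=sk.CU_NP, C_s=truth["C_s"],
                                     volume_V=1e-3, ci_method="bootstrap",
                                     n_boot=1)
        with pytest.warns(UserWarning, match="degenerate"):
            est.fit(series)

    def test_bootstrap_brackets_truth_scale(self):
        series, truth = shell_series(seed=3, noise_cv=0.02)
        est = sk.ShrinkingCoreFitter(particle=sk.CU_NP, C_s=truth["C_s"],
                                     volume_V=1e-3).fit(series)
        cov_hw = est.ci_De_
        boot_hw = sk.confidence_intervals(est, method="bootstrap", n_boot=60,
                                          seed=0)[0]
        # same order of magnitude as the covariance interval
        assert 0.2 < boot_hw / cov_hw < 5.0

    def test_coverage_of_De_interval(self):
        """Nominal 95% CIs for De cover the truth in 90-99% of 200
        simulated fits at CV=2%."""
        cover = 0
        for seed in range(200):
            series, truth = shell_series(seed=seed, noise_cv=0.02)
            est = sk.ShrinkingCoreFitter(particle=sk.CU_NP, C_s=truth["C_s"],
                                         volume_V=1e-3).fit(series)
            cover += abs(est.De_ - truth["D_e"]) <= est.ci_De_
        assert 0.90 * 200 <= cover <= 0.99 * 200
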