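"""Conversion laws, characteristic times, forward model, particle counts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import shrinkcore as sk
from shrinkcore import Regime

REGIMES = list(sk.SINGLE_REGIMES)


class TestConversionLaw:
    @pytest.mark.parametrize("regime", REGIMES)
    def test_endpoints(self, regime):
        assert sk.g_regime(0.0, regime) == 0.0
        assert sk.g_regime(1.0, regime) == pytest.approx(1.0, abs=1e-15)

    def test_shell_law_at_half_radius_cubed(self):
        # u = (1-X)^(1/3) = 0.5 at X = 0.875: 1 - 3*0.25 + 2*0.125 = 0.5
        assert sk.g_regime(0.875, Regime.POROUS_SHELL) == pytest.approx(0.5, abs=1e-15)

    def test_reaction_law_at_half_radius_cubed(self):
        assert sk.g_regime(0.875, Regime.CORE_REACTION) == pytest.approx(0.5, abs=1e-15)

    @pytest.mark.parametrize("regime", REGIMES)
    def test_strictly_increasing(self, regime):
        X = np.linspace(0, 1, 1000)
        g = sk.g_regime(X, regime)
        assert np.all(np.diff(g) > 0)

    def test_shell_slowest_early(self):
        """Shell control accumulates dimensionless time slowest through
        the transient: g_shell <= g_rxn <= g_film for X below the
        crossing point X=0.875 (u=1/2), where g_shell meets g_rxn; the
        film law dominates both everywhere."""
        X = np.linspace(0.001, 0.875, 500)
        g_shell = sk.g_regime(X, Regime.POROUS_SHELL)
        g_rxn = sk.g_regime(X, Regime.CORE_REACTION)
        g_film = sk.g_regime(X, Regime.LIQUID_FILM)
        assert np.all(g_shell <= g_rxn + 1e-15)
        assert np.all(g_rxn <= g_film + 1e-15)
        X_all = np.linspace(0.001, 0.999, 500)
        assert np.all(sk.g_regime(X_all, Regime.POROUS_SHELL)
                      <= np.asarray(sk.g_regime(X_all, Regime.LIQUID_FILM)) + 1e-15)
        # beyond the crossing the shell law overtakes the reaction law
        assert sk.g_regime(0.99, Regime.POROUS_SHELL) > sk.g_regime(
            0.99, Regime.CORE_REACTION)

    @pytest.mark.parametrize("regime", REGIMES)
    def test_domain_errors(self, regime):
        with pytest.raises(sk.InvalidInputError):
            sk.g_regime(-0.1, regime)
        with pytest.raises(sk.InvalidInputError):
            sk.invert_g(1.2, regime)

    def test_mixed_rejected(self):
        with pytest.raises(sk.InvalidInputError):
            sk.g_regime(0.5, Regime.MIXED)


class TestInverse:
    @pytest.mark.parametrize("regime", REGIMES)
    def test_roundtrip_identity_on_grid(self, regime):
        X = np.linspace(0, 1, 1000)
        back = sk.invert_g(sk.g_regime(X, regime), regime)
        assert np.max(np.abs(back - X)) < 1e-10

    @pytest.mark.parametrize("regime, s, expected", [
        (Regime.CORE_REACTION, 0.5, 0.875),
        (Regime.POROUS_SHELL, 0.5, 0.875),
        (Regime.LIQUID_FILM, 0.5, 0.5),
    ])
    def test_known_midpoints(self, regime, s, expected):
        assert sk.invert_g(s, regime) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(s=st.floats(0.0, 1.0))
    def test_inverse_hits_forward(self, s):
        for regime in REGIMES:
            X = sk.invert_g(s, regime)
            assert sk.g_regime(X, regime) == pytest.approx(s, abs=1e-10)


class TestTau:
    def test_shell_formula_table_inputs(self, cu_particle):
        # rho R^2 / (6 De C_s) with the tabulated diffusivity
        p = sk.SCMParameters(D_e=2.39e-11, C_s=1.0)
        expected = 8960.0 * (12.5e-9) ** 2 / (6 * 2.39e-11 * 1.0)
        assert sk.tau(Regime.POROUS_SHELL, cu_particle, p) == pytest.approx(
            expected, rel=1e-12)

    def test_scalings(self, cu_particle):
        p1 = sk.SCMParameters(D_e=1e-11, C_s=1.0)
        p2 = sk.SCMParameters(D_e=2e-11, C_s=1.0)
        t1 = sk.tau(Regime.POROUS_SHELL, cu_particle, p1)
        t2 = sk.tau(Regime.POROUS_SHELL, cu_particle, p2)
        assert t1 / t2 == pytest.approx(2.0, rel=1e-12)
        big = sk.ParticleSpec("big", cu_particle.radius_R * 2,
                              cu_particle.density_rho, 1.0)
        assert sk.tau(Regime.POROUS_SHELL, big, p1) / t1 == pytest.approx(
            4.0, rel=1e-12)

    def test_dimensional_invariance(self, cu_particle):
        """tau_shell is invariant under R -> aR, De -> a^2 De."""
        a = 3.7
        p = sk.SCMParameters(D_e=1e-11, C_s=0.5)
        p_scaled = sk.SCMParameters(D_e=a**2 * 1e-11, C_s=0.5)
        scaled = sk.ParticleSpec("s", a * cu_particle.radius_R,
                                 cu_particle.density_rho, 1.0)
        assert sk.tau(Regime.POROUS_SHELL, cu_particle, p) == pytest.approx(
            sk.tau(Regime.POROUS_SHELL, scaled, p_scaled), rel=1e-12)

    def test_invalid_parameters(self, cu_particle):
        with pytest.raises(sk.InvalidInputError):
            sk.tau(Regime.POROUS_SHELL, cu_particle, sk.SCMParameters(D_e=0.0))
        with pytest.raises(sk.InvalidInputError):
            sk.tau(Regime.LIQUID_FILM, cu_particle,
                   sk.SCMParameters(k_l=1e-9, C_l=0.0))


class TestForwardConcentration:
    def test_zero_time_and_plateau(self, cu_particle, shell_params):
        t_c = sk.tau(Regime.POROUS_SHELL, cu_particle, shell_params)
        times = np.array([0.0, t_c, 2 * t_c])
        series = sk.forward_concentration(Regime.POROUS_SHELL, cu_particle,
                                          shell_params, times, 1e-3)
        plateau = (shell_params.N0 * cu_particle.density_rho
                   * (4 / 3) * np.pi * cu_particle.radius_R**3 / 1e-3)
        assert series.concentration[0] == 0.0
        assert series.concentration[1] == pytest.approx(plateau, rel=1e-12)
        assert series.concentration[2] == pytest.approx(plateau, rel=1e-12)

    @pytest.mark.parametrize("regime", REGIMES)
    def test_monotone_and_mass_conserving(self, cu_particle, shell_params, regime):
        params = sk.SCMParameters(D_e=2.39e-11, k_s=1e-9, k_l=1e-9,
                                  C_s=shell_params.C_s, C_l=shell_params.C_s,
                                  N0=1.17e12)
        t_c = sk.tau(regime, cu_particle, params)
        times = np.linspace(0, 2 * t_c, 200)
        series = sk.forward_concentration(regime, cu_particle, params, times, 1e-3)
        assert np.all(np.diff(series.concentration) >= -1e-18)
        budget = params.N0 * cu_particle.copper_mass_per_particle
        assert np.all(series.concentration * series.volume_V <= budget * (1 + 1e-12))

    def test_negative_volume_rejected(self, cu_particle, shell_params):
        with pytest.raises(sk.InvalidInputError):
            sk.forward_concentration(Regime.POROUS_SHELL, cu_particle,
                                     shell_params, [0.0, 1.0], -1.0)


class TestParticleCount:
    def test_hand_value_for_suspension_loading(self, cu_particle):
        # 2.5 g of Cu at rho=8960, R=12.5 nm -> ~3.4e16 particles, far above
        # the fitted apparent count (agglomeration)
        n = sk.particle_count_from_mass(2.5e-3, cu_particle)
        assert n == pytest.approx(2.5e-3 / (8960 * (4 / 3) * np.pi * (12.5e-9) ** 3),
                                  rel=1e-12)
        assert n == pytest.approx(3.4e16, rel=0.02)
        assert n > 1.17e12

    def test_linearity_and_cubic_scaling(self, cu_particle):
        n1 = sk.particle_count_from_mass(1e-3, cu_particle)
        assert sk.particle_count_from_mass(2e-3, cu_particle) == pytest.approx(
            2 * n1, rel=1e-12)
        double_R = sk.ParticleSpec("d", 2 * cu_particle.radius_R,
                                   cu_particle.density_rho, 1.0)
        assert sk.particle_count_from_mass(1e-3, double_R) == pytest.approx(
            n1 / 8, rel=1e-12)


class TestConversionFromConcentration:
    def test_hand_example(self):
        # 100 mg/L in 1 L against 2.5 g initial copper -> X = 0.04
        series = sk.DissolutionSeries(np.array([0.0, 3600.0]),
                                      np.array([0.0, 100 * sk.MG_PER_L]),
                                      volume_V=1e-3, initial_copper_mass=2.5e-3)
        conv = sk.conversion_from_concentration(series)
        assert conv.X[1] == pytest.approx(0.04, rel=1e-12)

    def test_zero_and_full_conversion(self):
        series = sk.DissolutionSeries(np.array([0.0, 1.0, 2.0]),
                                      np.array([0.0, 0.0, 2.5]),
                                      volume_V=1e-3, initial_copper_mass=2.5e-3)
        conv = sk.conversion_from_concentration(series)
        assert conv.X[0] == 0.0 and conv.X[1] == 0.0
        assert conv.X[2] == pytest.approx(1.0)

    def test_overshoot_warns_and_clips(self):
        series = sk.DissolutionSeries(np.array([0.0, 1.0]),
                                      np.array([0.0, 3.0]),
                                      volume_V=1e-3, initial_copper_mass=2.5e-3)
        with pytest.warns(sk.DataInconsistencyWarning):
            conv = sk.conversion_from_concentration(series)
        assert conv.X[1] == 1.0
        assert conv.meta["inconsistent_overshoot"] == pytest.approx(1.2)

    def test_zero_initial_mass_rejected(self):
        series = sk.DissolutionSeries(np.array([0.0, 1.0]), np.array([0.0, 0.1]),
                                      volume_V=1e-3, initial_copper_mass=0.0)
        with pytest.raises(sk.InvalidInputError):
            sk.conversion_from_concentration(series)


class TestSeriesValidation:
    def test_non_increasing_times_rejected(self):
        with pytest.raises(sk.InvalidInputError):
            sk.DissolutionSeries(np.array([0.0, 1.0, 1.0]), np.zeros(3), 1e-3, 1e-3)

    def test_negative_concentration_rejected(self):
        with pytest.raises(sk.InvalidInputError):
            sk.DissolutionSeries(np.array([0.0, 1.0]), np.array([0.0, -1.0]),
                                 1e-3, 1e-3)

    def test_rescaled_to_plateau(self):
        conv = sk.ConversionSeries(np.array([0.0, 1.0, 2.0]),
                                   np.array([0.0, 0.02, 0.04]))
        scaled = conv.rescaled_to_plateau()
        assert scaled.X[-1] == pytest.approx(1.0)
        assert scaled.meta["rescaled_by"] == pytest.approx(0.04)
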