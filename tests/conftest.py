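import numpy as np
import pytest

import shrinkcore as sk


@pytest.fixture
def cu_particle():
    return sk.CU_NP


@pytest.fixture
def shell_params():
    """Table-scale shell-control parameters with C_s placing tau at 96 h."""
    C_s = sk.saturation_for_timescale(sk.CU_NP, 2.39e-11, 96 * sk.HOUR)
    return sk.SCMParameters(D_e=2.39e-11, C_s=C_s, C_l=C_s, N0=1.17e12)


def scenario_for_regime(regime, seed=0, noise_cv=0.01, n_points=20, X_max=0.8,
                        tau_s=96 * sk.HOUR):
    """Transient-sampled scenario generating from a prescribed regime.

    The rate constant is set per regime so that complete conversion
    takes tau_s; sampling covers conversion up to X_max.
    """
    regime = sk.Regime(regime)
    schedule = sk.transient_schedule(regime, tau_s, n_points, X_max)
    return sk.DissolutionScenario(regime=regime, schedule=schedule,
                                  noise_cv=noise_cv, seed=seed,
                                  tau_target_s=tau_s)


@pytest.fixture
def regime_scenario_factory():
    return scenario_for_regime
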