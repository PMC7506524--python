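import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prsbrain import SimConfig, simulate_cohort
from prsbrain.pipeline import recovery_run

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

N_SEEDS = 100


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort for structural/IO tests."""
    cfg = SimConfig(n_subjects=60, n_cases=20, n_snps=120, n_ld_blocks=12,
                    n_timepoints=96, seed=7)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_results():
    """100 end-to-end runs at the default (planted-effect) study conditions."""
    return [recovery_run(SimConfig(seed=s)) for s in range(N_SEEDS)]


@pytest.fixture(scope="session")
def null_results():
    """100 end-to-end runs with every planted brain/behavior effect zero."""
    return [recovery_run(SimConfig(seed=s, planted_beta=0.0, emotion_beta=0.0))
            for s in range(N_SEEDS)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
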