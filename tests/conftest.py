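import numpy as np
import pytest

from gxebrain.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_subjects=100,
        n_bds=50,
        n_snps=150,
        n_causal_snps=10,
        n_probes=250,
        n_signal_probes=8,
        probe_effect_delta=0.12,
        n_measures=6,
        mri_missing_bds=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
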