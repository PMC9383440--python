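import numpy as np
import pytest

from brainmr import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort exercised by several module test files."""
    cfg = SimulationConfig(
        n_individuals=1500,
        n_snps=200,
        n_causal_x=30,
        n_causal_y=30,
        n_shared=6,
        n_causal_vol=30,
        n_pleiotropic_vol=3,
        n_regions=40,
        n_genes=60,
        n_signal_genes=6,
        causal_beta_xy=-0.15,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
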