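import numpy as np
import pytest

from binqtl.simulate import SimConfig, simulate_f2_population, simulate_observations


@pytest.fixture(scope="session")
def small_population():
    """One modest F2 population shared across read-only tests."""
    cfg = SimConfig(
        chrom_lengths_bp=(20_000_000, 20_000_000),
        n_markers_per_chrom=40,
        n_individuals=60,
        mean_depth=7.0,
        error_rate=0.01,
        seed=11,
    )
    truth = simulate_f2_population(cfg)
    obs = simulate_observations(truth)
    return truth, obs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
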