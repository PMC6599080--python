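import numpy as np
import pandas as pd
import pytest

from mycolight.synthetic import (SimulationConfig, build_world,
                                 simulate_phylogeny, simulate_trait)


@pytest.fixture(scope="session")
def tree64():
    """Pure-birth 64-tip tree shared by signal/regression tests."""
    return simulate_phylogeny(64, 1.0, 0.0, seed=424)


@pytest.fixture(scope="session")
def bm_trait64(tree64):
    trait, _ = simulate_trait(tree64, "BM", sigma2=100.0 / tree64.depth(),
                              seed=77, bounds=(-1e9, 1e9))
    return trait


@pytest.fixture(scope="session")
def small_world():
    """Small filtered world used by grid/pipeline tests."""
    cfg = SimulationConfig(n_species=100, n_cells=64, seed=31)
    return build_world(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
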