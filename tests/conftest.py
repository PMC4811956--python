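import numpy as np
import pandas as pd
import pytest

from radhist.io import split_xy
from radhist.simulate import (TableSimConfig, paper_like_table_config,
                              simulate_feature_tables)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_signal_table():
    """n=120 table with 3 informative (d=1.2) among 15 features."""
    cfg = TableSimConfig(n_train=120, n_valid=60, n_blocks=4, block_size=3,
                         n_noise=3, n_informative=3, effect_size_d=1.2, seed=7)
    train, valid = simulate_feature_tables(cfg)
    return cfg, train, valid


@pytest.fixture(scope="session")
def paper_like_cohorts():
    cfg = paper_like_table_config(seed=11)
    train, valid = simulate_feature_tables(cfg)
    return cfg, train, valid


@pytest.fixture(scope="session")
def tiny_volume_mask(rng):
    """A 12^3 volume with an off-center ellipsoidal mask and mixed texture."""
    shape = (12, 12, 12)
    g = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    mask = (((g[0] - 5.5) / 4) ** 2 + ((g[1] - 6) / 3.5) ** 2
            + ((g[2] - 5) / 4.5) ** 2) <= 1.0
    vol = rng.normal(0, 30, shape) + 10.0 * g[0]
    return vol, mask.astype(np.uint8)


def xy(table: pd.DataFrame):
    return split_xy(table)
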