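import numpy as np
import pytest

from fcmlink.preprocess import clr_transform, filter_taxa, to_relative
from fcmlink.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Compact synthetic study: 30 samples, 5 groups, 60 taxa, 4 drivers."""
    cfg = SimConfig(
        n_samples=30, p_taxa=60, n_groups=5, depth=4000, n_drivers=4, seed=42
    )
    return simulate_dataset(cfg, with_fcm=False)


@pytest.fixture(scope="session")
def small_design(small_dataset):
    """(Z, y, groups) for the compact study after the standard preprocessing."""
    ds = small_dataset
    table = filter_taxa(ds.table)
    Z = clr_transform(to_relative(table)).z
    y = ds.hnacc.loc[Z.index]
    groups = ds.meta.frame.loc[Z.index, "group_id"].to_numpy()
    return Z, y, groups


@pytest.fixture(scope="session")
def fcm_dataset():
    """Small study with cytometry clouds (independent driver dynamics)."""
    cfg = SimConfig(
        n_samples=12,
        p_taxa=40,
        n_groups=4,
        depth=4000,
        n_drivers=4,
        driver_factor_sd=0.0,
        seed=7,
    )
    return simulate_dataset(cfg, with_fcm=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
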