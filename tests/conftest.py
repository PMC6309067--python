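import numpy as np
import pytest

from mindrank.rebalance import LabeledDataset
from mindrank.synthetic_data import SimulationConfig, simulate_stage1, simulate_stage2
from mindrank.variant_features import assemble_variant_features


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A scaled-down simulation used by most unit tests (fast, planted signal)."""
    return SimulationConfig(
        seed=11, n_positive=60, n_negative=240, n_genes=80, n_decoy_peaks=10
    )


@pytest.fixture(scope="session")
def small_stage1(small_cfg):
    return simulate_stage1(small_cfg)


@pytest.fixture(scope="session")
def small_stage2(small_cfg, small_stage1):
    return simulate_stage2(small_cfg, small_stage1)


@pytest.fixture(scope="session")
def small_dataset(small_stage1) -> LabeledDataset:
    feats = assemble_variant_features(
        small_stage1.variants,
        small_stage1.score_tables,
        small_stage1.eqtl_table,
        small_stage1.mark_tracks,
    )
    return LabeledDataset(feats, small_stage1.labels)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
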