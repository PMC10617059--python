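import numpy as np
import pytest

from snfs.dataset import ExpressionDataset
from snfs.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A reduced blocked-covariance dataset: 1,000 genes in 10 blocks, the
    first two blocks (200 genes) shifted, 100 train / 200 test samples."""
    cfg = SimulationConfig(
        n_genes=1000, n_blocks=10, block_size=100, n_positive_blocks=5,
        rho=0.6, shift=0.5, n_shifted_genes=200, n_train=100, n_test=200, seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def toy_dataset():
    """Six genes x eight samples with hand-readable values."""
    rng = np.random.default_rng(11)
    values = rng.normal(size=(6, 8))
    values[0] = [0, 0, 0, 0, 1, 1, 1, 1]          # class indicator
    values[1] = 3.0                                # constant
    labels = ["a"] * 4 + ["b"] * 4
    return ExpressionDataset(
        values,
        [f"g{i}" for i in range(6)],
        [f"s{i}" for i in range(8)],
        labels,
    )
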