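import numpy as np
import pytest

from misc_impute.io_matrix import ExpressionMatrix, GeneList
from misc_impute.synthetic import SyntheticConfig, generate


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 cells with a mix of zeros and positives."""
    values = np.array(
        [
            [0.0, 5.0, 7.0, 2.0],
            [1.0, 0.0, 0.0, 4.0],
            [3.0, 6.0, 9.0, 0.0],
        ]
    )
    return ExpressionMatrix(["gA", "gB", "gC"], ["c1", "c2", "c3", "c4"], values,
                            unit="counts")


@pytest.fixture(scope="session")
def small_dataset():
    """A small seeded synthetic dataset shared by detector-level tests."""
    config = SyntheticConfig(
        n_genes=400, n_cells=80, n_housekeeping=40, group_count=2, seed=11
    )
    return generate(config)


@pytest.fixture
def hk_list(small_dataset) -> GeneList:
    return small_dataset.housekeeping
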