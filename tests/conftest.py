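import numpy as np
import pandas as pd
import pytest

from warburgph.core_io import CASE, CONTROL, ExpressionMatrix
from warburgph.simulate import cancer_like_spec, simulate_dataset


def make_matrix(values: np.ndarray, n_case: int, n_control: int,
                genes=None, paired: bool = False) -> ExpressionMatrix:
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"c{i}" for i in range(n_case)] + [f"n{i}" for i in range(n_control)]
    groups = {s: (CASE if s.startswith("c") else CONTROL) for s in samples}
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_groups=groups,
        paired=paired,
    )


@pytest.fixture(scope="session")
def cancer_dataset():
    """One planted cancer-like dataset shared across tests (seed 7)."""
    mat, truth = simulate_dataset(cancer_like_spec(seed=7))
    return mat, truth


@pytest.fixture()
def small_matrix():
    """4 genes x 6 samples (3 case / 3 control), deterministic values."""
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(6, 1, (4, 6)), 3, 3)
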