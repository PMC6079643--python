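import numpy as np
import pandas as pd
import pytest

from xylemnet.matrix import SectionSeriesMatrix, sample_id


def make_matrix(arr, genes=None, kind="vst", trees=None):
    """Build a SectionSeriesMatrix from a 2-D array.

    ``trees``: optional list of per-tree sample counts; default one tree
    holding all columns.
    """
    arr = np.asarray(arr)
    n_genes, n_samples = arr.shape
    genes = genes or [f"g{i + 1}" for i in range(n_genes)]
    if trees is None:
        trees = [n_samples]
    assert sum(trees) == n_samples
    sample_ids, meta_rows = [], []
    for t, n in enumerate(trees):
        for p in range(1, n + 1):
            sample_ids.append(sample_id(f"T{t + 1}", p))
            meta_rows.append({"tree": f"T{t + 1}", "position": p})
    values = pd.DataFrame(arr, index=genes, columns=sample_ids)
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    return SectionSeriesMatrix(values, meta, kind)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
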