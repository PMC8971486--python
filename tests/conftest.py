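import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from dreep.types import BulkPanel, CountMatrix, DrugResponsePanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_counts(array, gene_ids=None, cell_ids=None, labels=None, mito=None):
    """Small dense helper around the CountMatrix constructor."""
    a = np.asarray(array)
    genes = gene_ids or [f"g{i}" for i in range(a.shape[0])]
    cells = cell_ids or [f"c{i}" for i in range(a.shape[1])]
    meta = pd.DataFrame({"label": labels}) if labels is not None else None
    return CountMatrix(genes, cells, sp.csr_matrix(a), cell_meta=meta,
                       mito_fraction=mito)


@pytest.fixture
def small_counts():
    return make_counts([[1, 0, 4], [2, 3, 0], [0, 5, 6]])


@pytest.fixture
def random_counts(rng):
    a = rng.poisson(2.0, size=(50, 20))
    return make_counts(a)


@pytest.fixture
def tiny_panels():
    bulk = BulkPanel(["g0", "g1", "g2"], ["s0", "s1", "s2", "s3"],
                     np.arange(12, dtype=float).reshape(3, 4) / 4)
    resp = DrugResponsePanel(["d0", "d1"], ["s0", "s1", "s2", "s3"],
                             np.array([[1.0, 2.0, 3.0, 4.0],
                                       [4.0, 1.0, 3.0, 2.0]]))
    return bulk, resp
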