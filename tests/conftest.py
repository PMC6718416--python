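import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from preadapt.containers import CountMatrix, NormalizedMatrix
from preadapt.grn import GeneNetwork


def make_counts(dense, gene_ids=None, cell_ids=None) -> CountMatrix:
    dense = np.asarray(dense)
    g, c = dense.shape
    return CountMatrix(
        sp.csr_matrix(dense),
        gene_ids or [f"g{i:03d}" for i in range(g)],
        cell_ids or [f"c{i:03d}" for i in range(c)],
    )


def make_norm(values, gene_ids=None, cell_ids=None) -> NormalizedMatrix:
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    return NormalizedMatrix(
        values,
        gene_ids or [f"g{i:03d}" for i in range(g)],
        cell_ids or [f"c{i:03d}" for i in range(c)],
    )


def net_from_edges(edges, condition="A") -> GeneNetwork:
    canon = [tuple(sorted(e)) for e in edges]
    nodes = sorted({n for e in canon for n in e})
    df = pd.DataFrame(canon, columns=["gene_a", "gene_b"])
    df["confidence"] = 1.0
    df["rank"] = np.arange(1, len(df) + 1)
    return GeneNetwork(nodes=nodes, edges=df, condition=condition)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
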