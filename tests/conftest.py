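import numpy as np
import pandas as pd
import pytest

from emtnetctrl.deg import ExpressionStudy


def make_study(values_a, values_b, gene_ids=None, conditions=("condA", "condB")):
    """Build an ExpressionStudy from two per-condition value matrices."""
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    n_genes = a.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    cols_a = [f"{conditions[0]}_{j + 1}" for j in range(a.shape[1])]
    cols_b = [f"{conditions[1]}_{j + 1}" for j in range(b.shape[1])]
    values = pd.DataFrame(
        np.hstack([a, b]), index=pd.Index(gene_ids, name="gene_id"), columns=cols_a + cols_b
    )
    design = pd.DataFrame(
        {
            "condition": [conditions[0]] * a.shape[1] + [conditions[1]] * b.shape[1],
            "replicate": list(range(1, a.shape[1] + 1)) + list(range(1, b.shape[1] + 1)),
        },
        index=pd.Index(cols_a + cols_b, name="sample_id"),
    )
    return ExpressionStudy(values, design, conditions)


@pytest.fixture
def study_factory():
    return make_study


def random_digraph(rng, n, p):
    """Random directed simple graph as (nodes, edge list)."""
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return nodes, edges


@pytest.fixture
def digraph_factory():
    return random_digraph
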