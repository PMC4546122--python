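import numpy as np
import pandas as pd
import pytest

from embryovar import ExpressionDataset, attach_metadata


def make_dataset(values, embryo_of_cell, stage_of_embryo, gene_ids=None):
    """Small helper: build a dataset from a genes x cells array and layouts."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    cell_ids = [f"c{i}" for i in range(n_cells)]
    stages = tuple(dict.fromkeys(stage_of_embryo.values()))
    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "embryo_id": embryo_of_cell,
            "stage": [stage_of_embryo[e] for e in embryo_of_cell],
        }
    )
    ds = ExpressionDataset(
        values=pd.DataFrame(values, index=gene_ids, columns=cell_ids),
        stages=stages,
    )
    return attach_metadata(ds, meta, stages=stages)


@pytest.fixture
def two_embryo_dataset():
    """One stage, two embryos of two cells: the hand-computable example.

    Gene g0 has cells (1, 3) in embryo A (population SD 1) and (5, 9) in
    embryo B (population SD 2), so SDC = 1.5 and SDE = 0.5.
    """
    return make_dataset(
        [[1.0, 3.0, 5.0, 9.0], [4.0, 4.0, 4.0, 4.0]],
        ["A", "A", "B", "B"],
        {"A": "s1", "B": "s1"},
    )


@pytest.fixture
def two_stage_dataset():
    """Two stages x two embryos each, 3 genes with contrasting patterns."""
    rng = np.random.default_rng(7)
    vals = rng.uniform(1, 10, size=(3, 8))
    return make_dataset(
        vals,
        ["A", "A", "B", "B", "C", "C", "D", "D"],
        {"A": "s1", "B": "s1", "C": "s2", "D": "s2"},
    )
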