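import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryovar import (
    ExpressionDataset,
    attach_metadata,
    log_transform,
    read_expression_matrix,
    read_gene_list,
    write_expression_matrix,
    write_gene_list,
)
from embryovar.dataset import DatasetError, GeneList


@pytest.fixture
def small_matrix():
    return pd.DataFrame(
        [[0.0, 1.5], [2.0, 0.0], [3.25, 7.0]],
        index=["g1", "g2", "g3"],
        columns=["c1", "c2"],
    )


@pytest.mark.parametrize("fmt", ["tsv", "csv", "mtx-triplet"])
def test_matrix_round_trip(tmp_path, small_matrix, fmt):
    ds = ExpressionDataset(values=small_matrix)
    ext = "mtx" if fmt == "mtx-triplet" else fmt
    path = str(tmp_path / f"m.{ext}")
    write_expression_matrix(ds, path, format=fmt)
    back = read_expression_matrix(path, format=fmt)
    pd.testing.assert_frame_equal(back.values, ds.values)


def test_mtx_missing_entries_are_zero(tmp_path):
    (tmp_path / "genes.txt").write_text("g1\ng2\ng3\n")
    (tmp_path / "cells.txt").write_text("c1\nc2\n")
    (tmp_path / "m.mtx").write_text(
        "%%MatrixMarket matrix coordinate real general\n3 2 2\n1 1 5.0\n3 2 2.5\n"
    )
    ds = read_expression_matrix(str(tmp_path / "m.mtx"), format="mtx-triplet")
    assert (ds.values.to_numpy() == 0).sum() == 4
    assert ds.values.loc["g1", "c1"] == 5.0


def test_duplicate_gene_id_is_named_in_error(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("\tc1\ng1\t1.0\ng1\t2.0\n")
    with pytest.raises(DatasetError, match="g1"):
        read_expression_matrix(str(path), format="tsv")


def test_non_numeric_cell_is_located(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("\tc1\tc2\ng1\t1.0\toops\n")
    with pytest.raises(DatasetError, match="c2"):
        read_expression_matrix(str(path), format="tsv")


class TestAttachMetadata:
    def _meta(self, rows):
        return pd.DataFrame(rows, columns=["cell_id", "embryo_id", "stage"])

    def test_valid_attach(self, small_matrix):
        ds = ExpressionDataset(values=small_matrix)
        meta = self._meta([["c1", "E1", "4-cell"], ["c2", "E1", "4-cell"]])
        out = attach_metadata(ds, meta)
        assert out.cell_stage.loc["c1"] == "4-cell"
        assert out.embryos_of_stage("4-cell") == ["E1"]

    def test_missing_cell_listed(self, small_matrix):
        ds = ExpressionDataset(values=small_matrix)
        meta = self._meta([["c1", "E1", "4-cell"]])
        with pytest.raises(DatasetError, match="c2"):
            attach_metadata(ds, meta)

    def test_embryo_spanning_stages_rejected(self, small_matrix):
        ds = ExpressionDataset(values=small_matrix)
        meta = self._meta([["c1", "E1", "4-cell"], ["c2", "E1", "8-cell"]])
        with pytest.raises(DatasetError, match="E1"):
            attach_metadata(ds, meta)

    def test_row_order_invariant(self, small_matrix):
        ds = ExpressionDataset(values=small_matrix)
        rows = [["c1", "E1", "4-cell"], ["c2", "E2", "4-cell"]]
        a = attach_metadata(ds, self._meta(rows))
        b = attach_metadata(ds, self._meta(rows[::-1]))
        pd.testing.assert_series_equal(a.cell_stage, b.cell_stage)
        pd.testing.assert_series_equal(a.cell_embryo, b.cell_embryo)


@pytest.mark.parametrize("v,expected", [(0.0, 0.0), (1.0, 1.0), (3.0, 2.0)])
def test_log_transform_values(v, expected):
    ds = ExpressionDataset(
        values=pd.DataFrame([[v]], index=["g"], columns=["c"])
    )
    out = log_transform(ds)
    assert out.values.iloc[0, 0] == pytest.approx(expected)
    assert out.transform == "log2p1"


def test_log_transform_not_reapplicable():
    ds = log_transform(
        ExpressionDataset(values=pd.DataFrame([[1.0]], index=["g"], columns=["c"]))
    )
    with pytest.raises(DatasetError):
        log_transform(ds)


def test_negative_raw_values_rejected():
    with pytest.raises(DatasetError):
        ExpressionDataset(
            values=pd.DataFrame([[-1.0]], index=["g"], columns=["c"])
        )


@settings(max_examples=25, deadline=None)
@given(
    n_genes=st.integers(1, 6),
    n_cells=st.integers(1, 5),
    data=st.data(),
)
def test_round_trip_random_matrices(tmp_path_factory, n_genes, n_cells, data):
    vals = np.array(
        data.draw(
            st.lists(
                st.lists(
                    st.floats(0, 1e4, allow_nan=False, width=32),
                    min_size=n_cells, max_size=n_cells,
                ),
                min_size=n_genes, max_size=n_genes,
            )
        )
    )
    df = pd.DataFrame(
        vals,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"c{i}" for i in range(n_cells)],
    )
    tmp = tmp_path_factory.mktemp("rt")
    ds = ExpressionDataset(values=df)
    write_expression_matrix(ds, str(tmp / "m.tsv"), format="tsv")
    back = read_expression_matrix(str(tmp / "m.tsv"), format="tsv")
    np.testing.assert_allclose(back.values.to_numpy(), vals, rtol=1e-6)


def test_gene_list_io(tmp_path):
    gl = GeneList(name="essential", genes=frozenset({"TP53", "MYC"}))
    path = str(tmp_path / "essential.txt")
    write_gene_list(gl, path)
    back = read_gene_list(path)
    assert back.genes == gl.genes
    assert back.name == "essential"


def test_gene_list_comments_stripped(tmp_path):
    path = tmp_path / "cat.txt"
    path.write_text("# a catalogue\nGATA3  # trailing note\nSOX2\n\n")
    gl = read_gene_list(str(path))
    assert gl.genes == frozenset({"GATA3", "SOX2"})
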