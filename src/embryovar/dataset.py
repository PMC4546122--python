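"""Core containers and I/O for replicated single-cell expression data.

The central object is :class:`ExpressionDataset`: a genes x cells matrix of
RPKM-like values together with the two per-cell annotations every statistic
in this package needs — the developmental stage of the cell and the embryo
it was dissociated from.  Embryos are nested within stages (each embryo
belongs to exactly one stage), which is what makes them usable as biological
replicates when estimating inter-cellular variability.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_STAGE_ORDER = ("4-cell", "8-cell", "morula", "blastocyst")

__all__ = [
    "ExpressionDataset",
    "GeneList",
    "StageDesign",
    "DEFAULT_STAGE_ORDER",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_cell_metadata",
    "write_cell_metadata",
    "attach_metadata",
    "log_transform",
    "read_gene_list",
    "write_gene_list",
]


class DatasetError(ValueError):
    """Raised for malformed expression matrices or metadata."""


@dataclass(frozen=True)
class GeneList:
    """A named catalogue of gene identifiers (e.g. essential genes)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise DatasetError(f"gene list {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class StageDesign:
    """Replication layout: ordered stages, embryos per stage, cells per embryo."""

    stages: tuple[str, ...]
    embryos_per_stage: dict[str, tuple[str, ...]]
    cells_per_embryo: dict[str, int]

    def __post_init__(self) -> None:
        for stage in self.stages:
            embryos = self.embryos_per_stage.get(stage, ())
            if len(embryos) < 1:
                raise DatasetError(f"stage {stage!r} has no embryos")
            for emb in embryos:
                if self.cells_per_embryo.get(emb, 0) < 2:
                    raise DatasetError(
                        f"embryo {emb!r} has fewer than 2 cells"
                    )

    @property
    def n_cells(self) -> int:
        return sum(self.cells_per_embryo.values())


@dataclass(frozen=True)
class ExpressionDataset:
    """Genes x cells expression matrix with per-cell stage/embryo annotation.

    Parameters
    ----------
    values
        DataFrame, rows = gene ids, columns = cell ids, non-negative for
        ``transform="raw"``.
    cell_stage, cell_embryo
        Per-cell annotations (Series indexed by cell id); may be absent
        until :func:`attach_metadata` is called.
    stages
        Ordered stage labels (developmental order, not lexical).
    transform
        ``"raw"`` for RPKM-like values, ``"log2p1"`` after log transform.
    """

    values: pd.DataFrame
    cell_stage: pd.Series | None = None
    cell_embryo: pd.Series | None = None
    stages: tuple[str, ...] = DEFAULT_STAGE_ORDER
    transform: str = "raw"

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            dup = vals.index[vals.index.duplicated()][0]
            raise DatasetError(f"duplicate gene id: {dup!r}")
        if vals.columns.has_duplicates:
            dup = vals.columns[vals.columns.duplicated()][0]
            raise DatasetError(f"duplicate cell id: {dup!r}")
        arr = vals.to_numpy()
        if not np.isfinite(arr).all():
            raise DatasetError("expression matrix contains non-finite values")
        if self.transform == "raw" and (arr < 0).any():
            raise DatasetError("raw expression values must be >= 0")
        if self.cell_stage is not None:
            self._check_metadata()

    def _check_metadata(self) -> None:
        assert self.cell_stage is not None and self.cell_embryo is not None
        cells = set(self.values.columns)
        meta_cells = set(self.cell_stage.index)
        if cells != meta_cells:
            missing = sorted(cells - meta_cells)
            extra = sorted(meta_cells - cells)
            raise DatasetError(
                f"metadata/matrix cell mismatch: missing={missing}, extra={extra}"
            )
        # each embryo must map to exactly one stage
        emb2stage = pd.DataFrame(
            {"embryo": self.cell_embryo, "stage": self.cell_stage}
        )
        n_stages = emb2stage.groupby("embryo")["stage"].nunique()
        bad = n_stages[n_stages > 1]
        if len(bad):
            raise DatasetError(
                f"embryo(s) span multiple stages: {sorted(bad.index)}"
            )
        unknown = set(self.cell_stage.unique()) - set(self.stages)
        if unknown:
            raise DatasetError(
                f"stage label(s) not in declared stage order: {sorted(unknown)}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def has_metadata(self) -> bool:
        return self.cell_stage is not None

    def stages_present(self) -> list[str]:
        """Stage labels present in the data, in developmental order."""
        if self.cell_stage is None:
            raise DatasetError("dataset has no cell metadata attached")
        present = set(self.cell_stage.unique())
        return [s for s in self.stages if s in present]

    def cells_of_stage(self, stage: str) -> pd.Index:
        if self.cell_stage is None:
            raise DatasetError("dataset has no cell metadata attached")
        if stage not in set(self.cell_stage.unique()):
            raise DatasetError(f"stage {stage!r} absent from dataset")
        return self.cell_stage.index[self.cell_stage == stage]

    def embryos_of_stage(self, stage: str) -> list[str]:
        cells = self.cells_of_stage(stage)
        assert self.cell_embryo is not None
        return sorted(self.cell_embryo.loc[cells].unique())

    def cells_of_embryo(self, embryo: str) -> pd.Index:
        if self.cell_embryo is None:
            raise DatasetError("dataset has no cell metadata attached")
        return self.cell_embryo.index[self.cell_embryo == embryo]

    def subset_genes(self, genes) -> "ExpressionDataset":
        genes = [g for g in self.gene_ids if g in set(genes)]
        return replace(self, values=self.values.loc[genes])

    def design(self) -> StageDesign:
        if self.cell_stage is None:
            raise DatasetError("dataset has no cell metadata attached")
        assert self.cell_embryo is not None
        embryos_per_stage = {}
        cells_per_embryo = {}
        for stage in self.stages_present():
            embs = tuple(self.embryos_of_stage(stage))
            embryos_per_stage[stage] = embs
            for emb in embs:
                cells_per_embryo[emb] = len(self.cells_of_embryo(emb))
        return StageDesign(
            stages=tuple(self.stages_present()),
            embryos_per_stage=embryos_per_stage,
            cells_per_embryo=cells_per_embryo,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_delimited(path: str, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise DatasetError(
                f"non-numeric expression value at gene {row!r}, cell {col!r}"
            )
    return df.astype(float)


def _read_mtx_triplet(path: str) -> pd.DataFrame:
    """MatrixMarket-style triplet with genes.txt / cells.txt sidecars."""
    base = os.path.dirname(os.path.abspath(path))
    genes = _read_id_file(os.path.join(base, "genes.txt"), "gene")
    cells = _read_id_file(os.path.join(base, "cells.txt"), "cell")
    dense = np.zeros((len(genes), len(cells)))
    with open(path) as fh:
        header_done = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            parts = line.split()
            if not header_done:
                # dimensions line: n_genes n_cells n_entries
                nr, nc = int(parts[0]), int(parts[1])
                if nr != len(genes) or nc != len(cells):
                    raise DatasetError(
                        f"mtx dimensions {nr}x{nc} do not match sidecars "
                        f"{len(genes)}x{len(cells)}"
                    )
                header_done = True
                continue
            i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            dense[i - 1, j - 1] = v
    return pd.DataFrame(dense, index=genes, columns=cells)


def _read_id_file(path: str, kind: str) -> list[str]:
    with open(path) as fh:
        ids = [ln.strip() for ln in fh if ln.strip()]
    seen: set[str] = set()
    for gid in ids:
        if gid in seen:
            raise DatasetError(f"duplicate {kind} id: {gid!r}")
        seen.add(gid)
    return ids


def read_expression_matrix(path: str, format: str = "tsv") -> ExpressionDataset:
    """Read a genes x cells expression matrix (values only, no metadata).

    ``format`` is one of ``tsv``, ``csv`` (gene rows, header = cell ids) or
    ``mtx-triplet`` (coordinate triplets with ``genes.txt``/``cells.txt``
    sidecar files next to the matrix; absent entries are zero).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "tsv":
        df = _read_delimited(path, "\t")
    elif format == "csv":
        df = _read_delimited(path, ",")
    elif format == "mtx-triplet":
        df = _read_mtx_triplet(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return ExpressionDataset(values=df)


def write_expression_matrix(ds: ExpressionDataset, path: str, format: str = "tsv") -> None:
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        ds.values.to_csv(path, sep=sep)
    elif format == "mtx-triplet":
        base = os.path.dirname(os.path.abspath(path))
        with open(os.path.join(base, "genes.txt"), "w") as fh:
            fh.write("\n".join(ds.gene_ids) + "\n")
        with open(os.path.join(base, "cells.txt"), "w") as fh:
            fh.write("\n".join(ds.cell_ids) + "\n")
        arr = ds.values.to_numpy()
        nz = np.nonzero(arr)
        with open(path, "w") as fh:
            fh.write("%%MatrixMarket matrix coordinate real general\n")
            fh.write(f"{arr.shape[0]} {arr.shape[1]} {len(nz[0])}\n")
            for i, j in zip(*nz):
                fh.write(f"{i + 1} {j + 1} {arr[i, j]:.10g}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cell_metadata(path: str) -> pd.DataFrame:
    """Read a cell metadata TSV with columns cell_id, embryo_id, stage."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "embryo_id", "stage"}
    missing = required - set(meta.columns)
    if missing:
        raise DatasetError(f"metadata missing column(s): {sorted(missing)}")
    return meta


def write_cell_metadata(ds: ExpressionDataset, path: str) -> None:
    if ds.cell_stage is None:
        raise DatasetError("dataset has no cell metadata attached")
    meta = pd.DataFrame(
        {
            "cell_id": ds.cell_ids,
            "embryo_id": ds.cell_embryo.loc[ds.cell_ids].to_numpy(),
            "stage": ds.cell_stage.loc[ds.cell_ids].to_numpy(),
        }
    )
    meta.to_csv(path, sep="\t", index=False)


def attach_metadata(
    ds: ExpressionDataset,
    meta: pd.DataFrame,
    stages: tuple[str, ...] | None = None,
) -> ExpressionDataset:
    """Attach per-cell (embryo, stage) annotations to an expression matrix.

    ``meta`` must cover every cell in the matrix exactly once; an embryo may
    not span two stages.  Row order of ``meta`` is irrelevant.
    """
    if meta["cell_id"].duplicated().any():
        dups = sorted(meta["cell_id"][meta["cell_id"].duplicated()])
        raise DatasetError(f"duplicate cell id(s) in metadata: {dups}")
    meta = meta.set_index("cell_id")
    cells = set(ds.cell_ids)
    meta_cells = set(meta.index)
    if cells != meta_cells:
        missing = sorted(cells - meta_cells)
        extra = sorted(meta_cells - cells)
        raise DatasetError(
            f"metadata/matrix cell mismatch: missing={missing}, extra={extra}"
        )
    if stages is None:
        declared = set(meta["stage"].unique())
        if declared <= set(DEFAULT_STAGE_ORDER):
            stages = DEFAULT_STAGE_ORDER
        else:
            # unfamiliar labels: keep first-appearance order
            stages = tuple(dict.fromkeys(meta["stage"]))
    return replace(
        ds,
        cell_stage=meta["stage"].reindex(ds.cell_ids),
        cell_embryo=meta["embryo_id"].reindex(ds.cell_ids),
        stages=tuple(stages),
    )


def log_transform(ds: ExpressionDataset) -> ExpressionDataset:
    """Return a copy with values log2(v + 1) and transform tag ``log2p1``."""
    if ds.transform != "raw":
        raise DatasetError(
            f"dataset already transformed (transform={ds.transform!r})"
        )
    return replace(ds, values=np.log2(ds.values + 1.0), transform="log2p1")


def read_gene_list(path: str, name: str | None = None) -> GeneList:
    """Read a plain-text gene list: one id per line, '#' comments allowed."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return GeneList(name=name or os.path.splitext(os.path.basename(path))[0],
                    genes=frozenset(genes))


def write_gene_list(gl: GeneList, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {gl.name}\n")
        fh.write("\n".join(sorted(gl.genes)) + "\n")
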