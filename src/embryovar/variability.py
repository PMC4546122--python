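"""Inter-cellular (SDC) and inter-embryo (SDE) expression variability.

For a gene at one developmental stage with E replicate embryos, let
``sd_j`` be the population standard deviation (divisor N_j) of the gene's
expression over the N_j cells of embryo j.  Then

* ``SDC = (1/E) * sum_j sd_j``      — each embryo weighted equally,
* ``SDE = sqrt( (1/E) * sum_j (sd_j - SDC)^2 )`` — the population SD of the
  per-embryo SDs around their mean,
* ``CV``  — SD divided by mean, either within each embryo and averaged
  (structural analogue of the SDC) or pooled over the whole stage.

Population (1/N) divisors are used throughout; no Bessel correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import DatasetError, ExpressionDataset

__all__ = [
    "within_embryo_sd",
    "compute_sdc",
    "compute_sde",
    "compute_cv",
    "stage_mean",
    "variability_table",
]


def _embryo_matrices(ds: ExpressionDataset, stage: str) -> list[np.ndarray]:
    """Per-embryo genes x cells value blocks for one stage."""
    blocks = []
    for emb in ds.embryos_of_stage(stage):
        cells = ds.cells_of_embryo(emb)
        blocks.append(ds.values[cells].to_numpy())
    return blocks


def _pop_sd(block: np.ndarray) -> np.ndarray:
    return block.std(axis=1, ddof=0)


def within_embryo_sd(ds: ExpressionDataset, gene: str, embryo: str) -> float:
    """Population SD of one gene's expression over one embryo's cells."""
    cells = ds.cells_of_embryo(embryo)
    if len(cells) < 2:
        raise DatasetError(f"embryo {embryo!r} has fewer than 2 cells")
    return float(ds.values.loc[gene, cells].to_numpy().std(ddof=0))


def per_embryo_sds(ds: ExpressionDataset, stage: str) -> pd.DataFrame:
    """Genes x embryos matrix of within-embryo population SDs (audit trail)."""
    embs = ds.embryos_of_stage(stage)
    for emb in embs:
        if len(ds.cells_of_embryo(emb)) < 2:
            raise DatasetError(f"embryo {emb!r} has fewer than 2 cells")
    sds = np.column_stack([_pop_sd(b) for b in _embryo_matrices(ds, stage)])
    return pd.DataFrame(sds, index=ds.gene_ids, columns=embs)


def compute_sdc(ds: ExpressionDataset, stage: str) -> pd.Series:
    """Per-gene SDC at one stage: unweighted mean of within-embryo SDs."""
    sds = per_embryo_sds(ds, stage)
    return sds.mean(axis=1).rename("sdc")


def compute_sde(ds: ExpressionDataset, stage: str) -> pd.Series:
    """Per-gene SDE: population SD of the within-embryo SDs around the SDC.

    Undefined (NaN) when the stage has a single embryo.
    """
    sds = per_embryo_sds(ds, stage)
    if sds.shape[1] < 2:
        return pd.Series(np.nan, index=ds.gene_ids, name="sde")
    arr = sds.to_numpy()
    return pd.Series(arr.std(axis=1, ddof=0), index=ds.gene_ids, name="sde")


def compute_cv(
    ds: ExpressionDataset, stage: str, mode: str = "per_embryo_mean"
) -> pd.Series:
    """Per-gene coefficient of variation at one stage.

    ``per_embryo_mean``: within-embryo SD / within-embryo mean, averaged
    over embryos (the structural analogue of the SDC).  ``pooled``: SD and
    mean over all the stage's cells.  A zero mean anywhere it is needed
    makes the CV undefined (NaN), never silently infinite.
    """
    if mode == "per_embryo_mean":
        blocks = _embryo_matrices(ds, stage)
        ratios = []
        for b in blocks:
            m = b.mean(axis=1)
            sd = _pop_sd(b)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(m > 0.0, sd / np.where(m > 0.0, m, 1.0), np.nan)
            ratios.append(r)
        cv = np.vstack(ratios).mean(axis=0)  # NaN propagates by design
    elif mode == "pooled":
        cells = ds.cells_of_stage(stage)
        block = ds.values[cells].to_numpy()
        m = block.mean(axis=1)
        sd = _pop_sd(block)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(m > 0.0, sd / np.where(m > 0.0, m, 1.0), np.nan)
    else:
        raise ValueError(f"unknown CV mode {mode!r}")
    return pd.Series(cv, index=ds.gene_ids, name="cv")


def stage_mean(ds: ExpressionDataset, stage: str) -> pd.Series:
    """Per-gene arithmetic mean over all the stage's cells (pooled)."""
    cells = ds.cells_of_stage(stage)
    return ds.values[cells].mean(axis=1).rename("stage_mean")


def variability_table(
    ds: ExpressionDataset, cv_mode: str = "per_embryo_mean"
) -> pd.DataFrame:
    """Long-format per-gene, per-stage table of SDC, SDE, CV and stage mean.

    Columns: gene, stage, sdc, sde, cv, stage_mean, transform.
    """
    rows = []
    for stage in ds.stages_present():
        df = pd.DataFrame(
            {
                "gene": ds.gene_ids,
                "stage": stage,
                "sdc": compute_sdc(ds, stage).to_numpy(),
                "sde": compute_sde(ds, stage).to_numpy(),
                "cv": compute_cv(ds, stage, mode=cv_mode).to_numpy(),
                "stage_mean": stage_mean(ds, stage).to_numpy(),
            }
        )
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out["transform"] = ds.transform
    return out
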