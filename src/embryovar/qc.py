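"""Stage-aware gene quality filtering and advisory chromosome-level checks.

The gene filter retains a gene when the fraction of cells expressing it at
or above a small RPKM threshold (default 0.1) is at least ``min_fraction``
(default 0.75) within every stage (``scope="all_stages"``) or within at
least one stage (``scope="any_stage"``).  Both inequalities are closed and
fractions are compared exactly — "75% of N cells" means fraction >= 0.75,
with no rounding of cell counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import DatasetError, ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "filter_genes",
    "chromosome_distribution_check",
    "read_gene_chromosome_map",
]


def read_gene_chromosome_map(path: str) -> dict[str, str]:
    """Read a gene -> chromosome mapping.

    Accepts either a two-column TSV (gene_id, chromosome; '#' comments
    allowed) or a GTF, from which only gene_id and seqname are used.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 9 and fields[8]:  # GTF attribute column
                import re

                m = re.search(r'gene_id "([^"]+)"', fields[8])
                if m:
                    mapping[m.group(1)] = fields[0]
            elif len(fields) >= 2:
                mapping[fields[0]] = fields[1]
    if not mapping:
        raise DatasetError(f"no gene->chromosome entries parsed from {path}")
    return mapping


@dataclass(frozen=True)
class FilterReport:
    n_genes_in: int
    n_genes_retained: int
    pass_matrix: pd.DataFrame  # genes x stages, True where the gene passes
    threshold: float
    min_fraction: float
    scope: str

    def summary(self) -> dict:
        return {
            "n_genes_in": self.n_genes_in,
            "n_genes_retained": self.n_genes_retained,
            "threshold": self.threshold,
            "min_fraction": self.min_fraction,
            "scope": self.scope,
        }


def filter_genes(
    ds: ExpressionDataset,
    threshold: float = 0.1,
    min_fraction: float = 0.75,
    scope: str = "all_stages",
) -> tuple[ExpressionDataset, FilterReport]:
    """Drop genes expressed below ``threshold`` in too many cells per stage."""
    if ds.transform != "raw":
        raise DatasetError("filter_genes expects raw (untransformed) values")
    if scope not in ("all_stages", "any_stage"):
        raise ValueError(f"unknown scope {scope!r}")
    stages = ds.stages_present()
    for stage in stages:
        if len(ds.cells_of_stage(stage)) < 2:
            raise DatasetError(f"stage {stage!r} has fewer than 2 cells")

    frac = {}
    for stage in stages:
        cells = ds.cells_of_stage(stage)
        block = ds.values[cells].to_numpy()
        frac[stage] = (block >= threshold).mean(axis=1)
    pass_matrix = pd.DataFrame(frac, index=ds.gene_ids) >= min_fraction

    if scope == "all_stages":
        keep = pass_matrix.all(axis=1)
    else:
        keep = pass_matrix.any(axis=1)

    retained = ds.gene_ids[keep]
    if len(retained) == 0:
        logger.warning("gene filter retained no genes")
    filtered = replace(ds, values=ds.values.loc[retained])
    report = FilterReport(
        n_genes_in=ds.n_genes,
        n_genes_retained=len(retained),
        pass_matrix=pass_matrix,
        threshold=threshold,
        min_fraction=min_fraction,
        scope=scope,
    )
    return filtered, report


def chromosome_distribution_check(
    ds: ExpressionDataset,
    gene_to_chrom: dict[str, str],
    flag_threshold: float = 3.0,
) -> pd.DataFrame:
    """Per-cell, per-chromosome expression summaries with outlier flags.

    For each cell and chromosome, reports the median and quartiles of
    log2(v + 1) expression over the chromosome's genes, plus a z-score of
    the per-cell median against the across-cell distribution for that
    chromosome.  Entries with \\|z\\| > ``flag_threshold`` are flagged.  The
    check is advisory only — it never drops data.  An aneuploid chromosome
    present in a subset of cells shows up as flagged (cell, chromosome)
    rows.
    """
    mapped = [g for g in ds.gene_ids if g in gene_to_chrom]
    coverage = len(mapped) / max(ds.n_genes, 1)
    if coverage < 0.5:
        raise DatasetError(
            f"gene->chromosome mapping covers only {coverage:.0%} of genes (< 50%)"
        )
    n_unmapped = ds.n_genes - len(mapped)
    if n_unmapped:
        logger.info("chromosome check: %d unmapped genes skipped", n_unmapped)

    vals = ds.values.loc[mapped]
    if ds.transform == "raw":
        vals = np.log2(vals + 1.0)
    chroms = pd.Series({g: gene_to_chrom[g] for g in mapped})

    rows = []
    for chrom, genes in chroms.groupby(chroms).groups.items():
        block = vals.loc[list(genes)]
        med = block.median(axis=0)
        q1 = block.quantile(0.25, axis=0)
        q3 = block.quantile(0.75, axis=0)
        mu, sd = med.mean(), med.std(ddof=0)
        z = (med - mu) / sd if sd > 0 else med * 0.0
        for cell in vals.columns:
            rows.append(
                {
                    "cell": cell,
                    "chromosome": chrom,
                    "n_genes": len(genes),
                    "median": med[cell],
                    "q1": q1[cell],
                    "q3": q3[cell],
                    "zscore": z[cell],
                    "flagged": bool(abs(z[cell]) > flag_threshold),
                }
            )
    return pd.DataFrame(rows)
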