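"""Identification of stably expressed genes and their expression modes.

Pipeline stage 1.  Genes whose cell-level expression shows no significant
change in variability across developmental stages (Levene's test across
stages, BH-adjusted p > alpha) are clustered on their per-stage SDC
profiles into three variability groups; the group with the lowest mean SDC
is the stable set.  Stable genes are then classified per stage into three
absolute-expression modes (low / medium / high) by a three-component
Gaussian mixture on their stage-mean expression.  Catalogue
enrichment/depletion of any gene set against user-supplied gene lists uses
the two-sided Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, GeneList
from .mixture import MixtureFit, fit_gmm_1d, hcluster, mixture_boundaries, select_k
from .stats import FisherResult, bh_adjust, fisher_2x2, levene_many
from .variability import stage_mean

logger = logging.getLogger(__name__)

__all__ = [
    "StableGeneResult",
    "EnrichmentRow",
    "levene_across_stages",
    "identify_stable_genes",
    "classify_expression_modes",
    "stage_overlap_of_modes",
    "catalogue_enrichment",
]

MODE_NAMES = ("low", "medium", "high")


@dataclass(frozen=True)
class StableGeneResult:
    table: pd.DataFrame  # per gene: levene_stat/p/p_adj, per-stage sdc, cluster, is_stable
    alpha: float
    clustering: str
    levene_center: str

    @property
    def stable_genes(self) -> pd.Index:
        return self.table.index[self.table["is_stable"]]


@dataclass(frozen=True)
class EnrichmentRow:
    catalogue: str
    n_set: int
    n_catalogue: int  # after intersection with the universe
    n_universe: int
    overlap: int
    fisher: FisherResult


def levene_across_stages(
    ds: ExpressionDataset, center: str = "mean"
) -> pd.DataFrame:
    """Levene's test per gene, stages as groups, cells as observations.

    Returns a DataFrame (gene index) with levene_stat, levene_p and
    BH-adjusted levene_p_adj over all tested genes.
    """
    labels = ds.cell_stage.loc[ds.cell_ids].to_numpy()
    stat, p = levene_many(ds.values.to_numpy(), labels, center=center)
    return pd.DataFrame(
        {"levene_stat": stat, "levene_p": p, "levene_p_adj": bh_adjust(p)},
        index=ds.gene_ids,
    )


def identify_stable_genes(
    ds: ExpressionDataset,
    alpha: float = 0.05,
    clustering: str = "hierarchical",
    k: int = 3,
    levene_center: str = "mean",
    seed: int = 1,
    levene: pd.DataFrame | None = None,
    sdc_by_stage: pd.DataFrame | None = None,
) -> StableGeneResult:
    """Find the stably expressed genes.

    A gene is *stable* iff its BH-adjusted Levene p across stages exceeds
    ``alpha`` (no detectable change in variability) and its per-stage SDC
    profile falls in the lowest-variability of ``k`` clusters.  Clustering
    is agglomerative hierarchical (complete linkage) by default; the
    ``"mixture"`` variant fits a k-component Gaussian mixture to the
    per-gene mean SDC instead.
    """
    if len(ds.stages_present()) < 2:
        raise ValueError("need >= 2 stages to test variability changes")
    if levene is None:
        levene = levene_across_stages(ds, center=levene_center)
    if sdc_by_stage is None:
        from .variability import compute_sdc

        sdc_by_stage = pd.DataFrame(
            {s: compute_sdc(ds, s) for s in ds.stages_present()}
        )
    table = levene.copy()
    for s in sdc_by_stage.columns:
        table[f"sdc_{s}"] = sdc_by_stage[s]

    nonsig = table.index[table["levene_p_adj"] > alpha]
    if len(nonsig) < k:
        raise ValueError(
            f"only {len(nonsig)} Levene-non-significant genes; need >= {k}"
        )
    profiles = sdc_by_stage.loc[nonsig]
    if clustering == "hierarchical":
        res = hcluster(profiles.to_numpy(), k=k)
        raw_labels = res.labels
    elif clustering == "mixture":
        fit = fit_gmm_1d(profiles.mean(axis=1).to_numpy(), K=k, seed=seed)
        raw_labels = fit.assignments + 1
    else:
        raise ValueError(f"unknown clustering {clustering!r}")

    # renumber clusters so 1 = lowest mean SDC
    mean_sdc = profiles.mean(axis=1).to_numpy()
    cluster_means = {
        lab: mean_sdc[raw_labels == lab].mean() for lab in np.unique(raw_labels)
    }
    order = sorted(cluster_means, key=cluster_means.get)
    renumber = {lab: i + 1 for i, lab in enumerate(order)}
    labels = np.array([renumber[lab] for lab in raw_labels])

    table["stability_cluster"] = pd.Series(labels, index=nonsig).reindex(table.index)
    table["is_stable"] = (table["levene_p_adj"] > alpha) & (
        table["stability_cluster"] == 1
    )
    return StableGeneResult(
        table=table, alpha=alpha, clustering=clustering, levene_center=levene_center
    )


def classify_expression_modes(
    ds: ExpressionDataset,
    stable_genes,
    stage: str,
    seed: int = 1,
) -> tuple[pd.Series, MixtureFit, list[float]]:
    """Assign stable genes to low/medium/high expression modes at one stage.

    Fits a 3-component Gaussian mixture to the stage-mean expression of the
    stable genes and labels components by ascending mean.  If the fit is
    degenerate (fewer than 3 effective components in the data), falls back
    to BIC-selected K with a warning and labels the available components
    from "low" upward.

    Returns (per-gene mode labels, mixture fit, mode boundaries).
    """
    stable_genes = pd.Index(stable_genes)
    if len(stable_genes) < 10:
        raise ValueError(f"only {len(stable_genes)} stable genes; need >= 10")
    means = stage_mean(ds, stage).loc[stable_genes]
    x = means.to_numpy()
    if np.var(x) == 0.0 or len(np.unique(x)) < 3:
        logger.warning(
            "degenerate stage-mean distribution at %s; using BIC-selected K", stage
        )
        fit = select_k(x, k_min=1, k_max=min(3, len(np.unique(x))), seed=seed)
    else:
        fit = fit_gmm_1d(x, K=3, seed=seed)
    names = MODE_NAMES[: fit.K]
    labels = pd.Series(
        [names[a] for a in fit.assignments], index=stable_genes, name="mode"
    )
    return labels, fit, mixture_boundaries(fit)


def stage_overlap_of_modes(modes_per_stage: dict[str, pd.Series]) -> pd.DataFrame:
    """How consistently each expression mode is assigned across all stages.

    For each mode, reports the number of genes carrying the mode in every
    stage and two fractions with different denominators (the set of genes
    with the mode in at least one stage, and the mean per-stage count),
    since either normalisation is defensible.
    """
    stages = list(modes_per_stage)
    rows = []
    for mode in MODE_NAMES:
        per_stage_sets = [
            set(s.index[s == mode]) for s in modes_per_stage.values()
        ]
        in_all = set.intersection(*per_stage_sets) if per_stage_sets else set()
        in_any = set.union(*per_stage_sets) if per_stage_sets else set()
        mean_per_stage = np.mean([len(s) for s in per_stage_sets]) if stages else 0.0
        rows.append(
            {
                "mode": mode,
                "n_all_stages": len(in_all),
                "n_any_stage": len(in_any),
                "frac_of_any": len(in_all) / len(in_any) if in_any else np.nan,
                "frac_of_mean_per_stage": (
                    len(in_all) / mean_per_stage if mean_per_stage else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("mode")


def catalogue_enrichment(gene_set, catalogue: GeneList, universe) -> EnrichmentRow:
    """Two-sided Fisher enrichment/depletion of a gene set vs a catalogue.

    The catalogue is intersected with the analysis universe first; the 2x2
    table splits the universe by set membership and catalogue membership.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    cat = catalogue.genes & universe
    if not cat:
        logger.info("catalogue %s has no overlap with universe", catalogue.name)
        return EnrichmentRow(
            catalogue=catalogue.name,
            n_set=len(gene_set),
            n_catalogue=0,
            n_universe=len(universe),
            overlap=0,
            fisher=FisherResult(odds_ratio=np.nan, p_two_sided=1.0, direction="none"),
        )
    a = len(gene_set & cat)
    b = len(gene_set - cat)
    c = len(cat - gene_set)
    d = len(universe) - a - b - c
    return EnrichmentRow(
        catalogue=catalogue.name,
        n_set=len(gene_set),
        n_catalogue=len(cat),
        n_universe=len(universe),
        overlap=a,
        fisher=fisher_2x2(a, b, c, d),
    )


def enrichment_table(
    gene_set, catalogues: list[GeneList], universe
) -> pd.DataFrame:
    """Run catalogue_enrichment over several catalogues; tidy result table."""
    rows = []
    for cat in catalogues:
        row = catalogue_enrichment(gene_set, cat, universe)
        rows.append(
            {
                "catalogue": row.catalogue,
                "n_set": row.n_set,
                "n_catalogue": row.n_catalogue,
                "n_universe": row.n_universe,
                "overlap": row.overlap,
                "odds_ratio": row.fisher.odds_ratio,
                "p_two_sided": row.fisher.p_two_sided,
                "direction": row.fisher.direction,
            }
        )
    return pd.DataFrame(rows)
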