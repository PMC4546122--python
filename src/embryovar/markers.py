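"""Stage-specific variability markers and regulatory control states.

Pipeline stage 2.  A *variability marker* of stage X satisfies three
simultaneous criteria:

1. its SDC at X is strictly smaller than at every other stage (most
   homogeneous expression among cells at X),
2. its mean expression at X is strictly higher than at every other stage,
3. its Levene test for a change in variability across stages is
   significant (BH-adjusted p < alpha).

Criteria 1 + 2 can hold for at most one stage, so marker sets of distinct
stages are disjoint by construction; exact ties disqualify under the
default strict policy.  A one-way ANOVA cross-comparison flags which
markers a conventional mean-shift analysis would also have found.

*Control states* are discrete levels of expression variability at one
stage: components of a BIC-selected Gaussian mixture (K = 1..9) fit to the
stage's per-gene SDC values, labelled 1 (lowest variability) upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .mixture import MixtureFit, select_k
from .stats import anova_many, bh_adjust

__all__ = [
    "ControlStateResult",
    "detect_variability_markers",
    "anova_comparison",
    "identify_control_states",
]


@dataclass(frozen=True)
class ControlStateResult:
    stage: str
    fit: MixtureFit
    states: pd.Series  # per gene, 1 = lowest-variability state

    @property
    def n_states(self) -> int:
        return self.fit.K


def _pivot(vt: pd.DataFrame, column: str) -> pd.DataFrame:
    return vt.pivot(index="gene", columns="stage", values=column)


def detect_variability_markers(
    vt: pd.DataFrame,
    levene_p_adj: pd.Series,
    alpha: float = 0.05,
    tie_policy: str = "strict",
) -> pd.DataFrame:
    """Apply the three marker criteria to every gene and every stage.

    ``vt`` is the long-format variability table (gene, stage, sdc,
    stage_mean, ...); ``levene_p_adj`` the per-gene adjusted Levene p from
    the same transcriptome-wide family used for the stable-gene analysis.
    Returns one row per marker gene with its stage and per-criterion flags.
    Genes missing any stage are excluded.
    """
    if tie_policy != "strict":
        raise ValueError("only the strict tie policy is implemented")
    sdc = _pivot(vt, "sdc")
    mean = _pivot(vt, "stage_mean")
    stages = list(sdc.columns)
    complete = sdc.dropna().index.intersection(mean.dropna().index)
    n_dropped = len(sdc.index) - len(complete)
    sdc, mean = sdc.loc[complete], mean.loc[complete]
    levene_p_adj = levene_p_adj.reindex(complete)

    rows = []
    sdc_arr, mean_arr = sdc.to_numpy(), mean.to_numpy()
    for si, stage in enumerate(stages):
        others = [j for j in range(len(stages)) if j != si]
        c1 = (sdc_arr[:, [si]] < sdc_arr[:, others]).all(axis=1)
        c2 = (mean_arr[:, [si]] > mean_arr[:, others]).all(axis=1)
        c3 = (levene_p_adj < alpha).to_numpy()
        is_marker = c1 & c2 & c3
        for gi in np.nonzero(is_marker)[0]:
            gene = complete[gi]
            row = {
                "gene": gene,
                "marker_stage": stage,
                "levene_p_adj": levene_p_adj.iloc[gi],
                "c1_min_sdc": True,
                "c2_max_mean": True,
                "c3_levene": True,
            }
            for s in stages:
                row[f"sdc_{s}"] = sdc.loc[gene, s]
                row[f"mean_{s}"] = mean.loc[gene, s]
            rows.append(row)
    out = pd.DataFrame(
        rows,
        columns=["gene", "marker_stage", "levene_p_adj", "c1_min_sdc",
                 "c2_max_mean", "c3_levene"]
        + [f"sdc_{s}" for s in stages]
        + [f"mean_{s}" for s in stages],
    )
    out.attrs["n_genes_excluded_missing_stage"] = n_dropped
    return out


def anova_comparison(
    ds: ExpressionDataset, markers: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Flag which variability markers a standard ANOVA would also detect.

    Runs a one-way ANOVA (stages as groups, cells as observations) for each
    marker gene, BH-adjusts over the marker set only, and marks
    ``uniquely_variability`` = True where the adjusted ANOVA p >= alpha —
    the markers invisible to a mean-based approach.
    """
    if markers.empty:
        out = markers.copy()
        out["anova_p"] = pd.Series(dtype=float)
        out["anova_p_adj"] = pd.Series(dtype=float)
        out["uniquely_variability"] = pd.Series(dtype=bool)
        return out
    genes = markers["gene"].tolist()
    labels = ds.cell_stage.loc[ds.cell_ids].to_numpy()
    _, p = anova_many(ds.values.loc[genes].to_numpy(), labels)
    out = markers.copy()
    out["anova_p"] = p
    out["anova_p_adj"] = bh_adjust(p)
    out["uniquely_variability"] = out["anova_p_adj"] >= alpha
    return out


def identify_control_states(
    vt: pd.DataFrame,
    stage: str,
    seed: int = 1,
    k_min: int = 1,
    k_max: int = 9,
) -> ControlStateResult:
    """Discover the discrete variability (control) states at one stage.

    Fits Gaussian mixtures with K = ``k_min``..``k_max`` to the stage's
    per-gene SDC values, keeps the minimum-BIC model, and labels genes by
    maximum posterior with state 1 = lowest component mean.
    """
    sub = vt[vt["stage"] == stage]
    sdc = sub.set_index("gene")["sdc"].dropna()
    if len(sdc) < 50:
        raise ValueError(
            f"only {len(sdc)} genes with defined SDC at {stage!r}; need >= 50"
        )
    fit = select_k(sdc.to_numpy(), k_min=k_min, k_max=k_max, seed=seed)
    states = pd.Series(fit.assignments + 1, index=sdc.index, name="state")
    return ControlStateResult(stage=stage, fit=fit, states=states)
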