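"""Synthetic replicated single-cell expression data with planted structure.

The generator emulates the statistical design the analysis assumes: four
ordered developmental stages, two to three replicate embryos per stage,
a handful of cells per embryo, and log-scale expression built from
gene-by-stage means, an additive embryo random effect and cell-level
Gaussian noise whose SD encodes each gene's planted variability class:

``log2(x + 1) = mu_gs + b_gj + eps,  b_gj ~ N(0, embryo_sd^2),
eps ~ N(0, sigma_gs^2)``

Values are back-transformed to an RPKM-like scale (2^v - 1, floored at 0).
Planted gene classes:

* **stable** genes — sigma constant across stages and low, with a
  low / medium / high expression mode (trimodal stage means);
* **markers** of a stage — sigma halved and log-mean doubled at that stage;
* **state** genes — per-stage sigma drawn from a stage-specific mixture of
  variability levels (the planted control states);
* **shift** genes — sigma doubled at a random subset of stages (generic
  differential-variability background);
* **zero-inflated** genes — low expression with Bernoulli dropout masking.

For state and shift genes the stage means are positively coupled to the
stage sigmas (stages where a gene is more variable are also, on average,
more highly expressed), so a high mean and a low SDC coincide at the same
stage only for planted markers, as in real stage-regulated expression.

All randomness flows from the single mandatory ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .dataset import DEFAULT_STAGE_ORDER, ExpressionDataset, StageDesign, attach_metadata
from .mixture import select_k
from .variability import compute_cv, compute_sdc

__all__ = [
    "SyntheticConfig",
    "default_design",
    "generate_dataset",
    "generate_stage_population",
    "stable_recovery_config",
    "marker_recovery_config",
    "control_state_config",
    "sd_cv_benchmark",
]

# Planted variability-state mixtures per stage, on the SDC (log2) scale.
# Component 1 is shared across stages and coincides with the stable-gene
# sigma, so stable genes merge into the lowest control state; the number of
# components shrinks over development while the upper states widen.
DEFAULT_STATE_MIXTURES = {
    "4-cell": ((0.3, 0.8, 1.6, 3.0), (0.05, 0.08, 0.12, 0.2), (0.5, 0.25, 0.15, 0.1)),
    "8-cell": ((0.3, 1.0, 2.2), (0.05, 0.1, 0.15), (0.45, 0.35, 0.2)),
    "morula": ((0.3, 1.1, 2.4), (0.05, 0.1, 0.15), (0.4, 0.35, 0.25)),
    "blastocyst": ((0.35, 2.0), (0.06, 0.15), (0.5, 0.5)),
}


def default_design(
    stages=DEFAULT_STAGE_ORDER,
    embryos_per_stage=(3, 3, 2, 3),
    cells_per_embryo=(4, 8, 8, 10),
) -> StageDesign:
    """The study-sized replication layout: 4 stages, 3/3/2/3 embryos,
    4/8/8/10 cells per embryo by stage."""
    embryos = {}
    cells = {}
    for s, ne, nc in zip(stages, embryos_per_stage, cells_per_embryo):
        ids = tuple(f"{s}_E{i + 1}" for i in range(ne))
        embryos[s] = ids
        for e in ids:
            cells[e] = nc
    return StageDesign(stages=tuple(stages), embryos_per_stage=embryos,
                       cells_per_embryo=cells)


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for one synthetic dataset.  ``seed`` is mandatory."""

    seed: int
    n_genes: int = 8000
    design: StageDesign = field(default_factory=default_design)
    # stable genes
    frac_stable: float = 0.12
    stable_mode_props: tuple[float, float, float] = (0.3, 0.55, 0.15)
    stable_mode_logmeans: tuple[float, float, float] = (0.5, 4.0, 9.0)
    stable_sigma: float = 0.3
    stable_sigma_jitter: float = 0.04
    # markers: baseline sigma varies stage to stage (as for any real gene);
    # at the marker stage sigma drops to sdc_ratio * min(other stages) and
    # the log-mean rises to mean_fold * max(other stages)
    markers_per_stage: int = 10
    marker_base_logmean: float = 3.0
    marker_sigma_range: tuple[float, float] = (0.8, 1.6)
    marker_sdc_ratio: float = 0.5
    marker_mean_fold: float = 2.0
    # zero-inflated low-expression genes
    frac_zero_inflated: float = 0.05
    zero_inflation_p: float = 0.3
    zi_logmean: float = 1.5
    zi_sigma: float = 0.4
    # background: "states" draws per-stage sigma from the control-state
    # mixtures; "shift" doubles sigma at a random subset of stages
    background: str = "states"
    state_mixtures: dict = field(
        default_factory=lambda: dict(DEFAULT_STATE_MIXTURES)
    )
    shift_sigma_range: tuple[float, float] = (0.4, 0.8)
    shift_fold: float = 2.0
    mean_range: tuple[float, float] = (2.0, 8.0)
    mean_sigma_coupling: float = 2.0
    embryo_sd: float = 0.15

    def counts(self) -> dict[str, int]:
        n_stable = int(round(self.frac_stable * self.n_genes))
        n_markers = self.markers_per_stage * len(self.design.stages)
        n_zi = int(round(self.frac_zero_inflated * self.n_genes))
        n_bg = self.n_genes - n_stable - n_markers - n_zi
        if n_bg < 0:
            raise ValueError("more planted genes than n_genes")
        return {
            "stable": n_stable,
            "marker": n_markers,
            "zero_inflated": n_zi,
            "background": n_bg,
        }


def stable_recovery_config(seed: int, n_stable: int = 300, n_shift: int = 700,
                           design: StageDesign | None = None) -> SyntheticConfig:
    """Planted stable genes against a pure variability-shift background."""
    n = n_stable + n_shift
    return SyntheticConfig(
        seed=seed,
        n_genes=n,
        design=design or default_design(cells_per_embryo=(8, 8, 8, 8)),
        frac_stable=n_stable / n,
        markers_per_stage=0,
        frac_zero_inflated=0.0,
        background="shift",
    )


def marker_recovery_config(seed: int, n_genes: int = 1000,
                           markers_per_stage: int = 10) -> SyntheticConfig:
    """Planted stage markers against a variability-shift background."""
    return SyntheticConfig(
        seed=seed,
        n_genes=n_genes,
        design=default_design(cells_per_embryo=(8, 8, 8, 8)),
        frac_stable=0.0,
        markers_per_stage=markers_per_stage,
        frac_zero_inflated=0.0,
        background="shift",
    )


def control_state_config(seed: int, n_genes: int = 1000) -> SyntheticConfig:
    """Pure control-state background for per-stage mixture-K recovery."""
    return SyntheticConfig(
        seed=seed,
        n_genes=n_genes,
        design=default_design(cells_per_embryo=(8, 8, 8, 10)),
        frac_stable=0.0,
        markers_per_stage=0,
        frac_zero_inflated=0.0,
        background="states",
    )


def _draw_state_sigma(
    u: np.ndarray, means, sds, weights, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Map a per-gene uniform rank through a stage's state mixture."""
    edges = np.cumsum(weights) / np.sum(weights)
    comp = np.searchsorted(edges, u, side="right")
    comp = np.clip(comp, 0, len(means) - 1)
    sigma = np.asarray(means)[comp] + rng.normal(0, 1, size=len(u)) * np.asarray(sds)[comp]
    return np.maximum(sigma, 0.02), comp


def generate_dataset(cfg: SyntheticConfig) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Generate an RPKM-like dataset and its planted-truth table.

    Returns ``(dataset, truth)`` where ``truth`` is indexed by gene with a
    ``label`` column partitioning genes into classes
    (``stable:<mode>``, ``marker:<stage>``, ``state:<k>``, ``shift``,
    ``zero_inflated``) plus the per-stage planted sigma and log-mean.
    """
    rng = np.random.default_rng(cfg.seed)
    design = cfg.design
    stages = list(design.stages)
    counts = cfg.counts()
    n = cfg.n_genes

    genes = [f"G{i:05d}" for i in range(n)]
    labels = np.empty(n, dtype=object)
    mu = np.zeros((n, len(stages)))  # log2-scale stage means
    sigma = np.zeros((n, len(stages)))  # cell-level noise SD per stage
    zi_mask_gene = np.zeros(n, dtype=bool)

    idx = 0
    # stable genes
    n_stable = counts["stable"]
    props = np.asarray(cfg.stable_mode_props, dtype=float)
    props = props / props.sum()
    mode_counts = np.round(props * n_stable).astype(int)
    mode_counts[-1] = n_stable - mode_counts[:-1].sum()
    for mode, m_logmean, m_count in zip(
        ("low", "medium", "high"), cfg.stable_mode_logmeans, mode_counts
    ):
        for _ in range(m_count):
            g_mu = m_logmean + rng.normal(0, 0.3)
            g_sigma = max(
                cfg.stable_sigma + rng.normal(0, cfg.stable_sigma_jitter), 0.05
            )
            mu[idx, :] = max(g_mu, 0.1)
            sigma[idx, :] = g_sigma
            labels[idx] = f"stable:{mode}"
            idx += 1

    # markers
    n_stages = len(stages)
    for si, stage in enumerate(stages):
        for _ in range(cfg.markers_per_stage):
            base_mu = cfg.marker_base_logmean + rng.normal(0, 0.3)
            sig = rng.uniform(*cfg.marker_sigma_range, size=n_stages)
            others = [j for j in range(n_stages) if j != si]
            sig[si] = cfg.marker_sdc_ratio * sig[others].min()
            m = base_mu + cfg.mean_sigma_coupling * (sig - sig[others].mean())
            m[si] = cfg.marker_mean_fold * m[others].max()
            mu[idx, :] = np.maximum(m, 0.1)
            sigma[idx, :] = sig
            labels[idx] = f"marker:{stage}"
            idx += 1

    # zero-inflated low-expression genes
    for _ in range(counts["zero_inflated"]):
        mu[idx, :] = max(cfg.zi_logmean + rng.normal(0, 0.3), 0.2)
        sigma[idx, :] = cfg.zi_sigma
        labels[idx] = "zero_inflated"
        zi_mask_gene[idx] = True
        idx += 1

    # background genes
    n_bg = counts["background"]
    if n_bg:
        base_mu = rng.uniform(*cfg.mean_range, size=n_bg)
        if cfg.background == "states":
            u = rng.uniform(size=n_bg)
            comps_first = None
            for si, stage in enumerate(stages):
                means, sds, weights = cfg.state_mixtures[stage]
                sig, comp = _draw_state_sigma(u, means, sds, weights, rng)
                sigma[idx : idx + n_bg, si] = sig
                if comps_first is None:
                    comps_first = comp
            for j in range(n_bg):
                labels[idx + j] = f"state:{comps_first[j] + 1}"
        elif cfg.background == "shift":
            base_sigma = rng.uniform(*cfg.shift_sigma_range, size=n_bg)
            for j in range(n_bg):
                n_up = rng.integers(1, len(stages))
                up = rng.choice(len(stages), size=n_up, replace=False)
                sigma[idx + j, :] = base_sigma[j]
                sigma[idx + j, up] = base_sigma[j] * cfg.shift_fold
                labels[idx + j] = "shift"
        else:
            raise ValueError(f"unknown background {cfg.background!r}")
        # couple stage means to stage sigmas so upregulation and high
        # variability co-occur (markers are the deliberate exception)
        sig_block = sigma[idx : idx + n_bg, :]
        centered = sig_block - sig_block.mean(axis=1, keepdims=True)
        mu[idx : idx + n_bg, :] = np.maximum(
            base_mu[:, None] + cfg.mean_sigma_coupling * centered, 0.1
        )
        idx += n_bg

    assert idx == n

    # assemble cells
    cell_ids, cell_stage, cell_embryo = [], [], []
    for stage in stages:
        for emb in design.embryos_per_stage[stage]:
            for ci in range(design.cells_per_embryo[emb]):
                cell_ids.append(f"{emb}_c{ci + 1}")
                cell_stage.append(stage)
                cell_embryo.append(emb)
    n_cells = len(cell_ids)

    log_vals = np.zeros((n, n_cells))
    col = 0
    for si, stage in enumerate(stages):
        for emb in design.embryos_per_stage[stage]:
            nc = design.cells_per_embryo[emb]
            b = rng.normal(0, cfg.embryo_sd, size=n)
            eps = rng.normal(0, 1, size=(n, nc)) * sigma[:, [si]]
            log_vals[:, col : col + nc] = mu[:, [si]] + b[:, None] + eps
            col += nc

    raw = np.maximum(np.exp2(log_vals) - 1.0, 0.0)
    if zi_mask_gene.any():
        drop = rng.uniform(size=(int(zi_mask_gene.sum()), n_cells)) < cfg.zero_inflation_p
        raw[zi_mask_gene] = np.where(drop, 0.0, raw[zi_mask_gene])

    values = pd.DataFrame(raw, index=genes, columns=cell_ids)
    meta = pd.DataFrame(
        {"cell_id": cell_ids, "embryo_id": cell_embryo, "stage": cell_stage}
    )
    ds = attach_metadata(
        ExpressionDataset(values=values, stages=tuple(stages)), meta,
        stages=tuple(stages),
    )

    truth = pd.DataFrame({"label": labels}, index=pd.Index(genes, name="gene"))
    truth["class"] = [lab.split(":")[0] for lab in labels]
    for si, stage in enumerate(stages):
        truth[f"sigma_{stage}"] = sigma[:, si]
        truth[f"mu_{stage}"] = mu[:, si]
    return ds, truth


def generate_stage_population(
    seed: int,
    n_genes: int = 500,
    n_cells: int = 12,
    n_embryos: int = 2,
    two_populations: bool = False,
    shift_frac: float = 0.1,
    shift: float = 2.0,
    noise_sd: float = 0.6,
) -> ExpressionDataset:
    """One synthetic stage, optionally split into two cell sub-populations.

    With ``two_populations=True`` half the cells carry a ``shift`` log2-unit
    mean increase in a ``shift_frac`` fraction of genes — a planted
    sub-population for the subsampling heterogeneity analysis.  Returns a
    raw RPKM-like dataset.
    """
    rng = np.random.default_rng(seed)
    mu = rng.uniform(2.0, 8.0, n_genes)
    log_vals = mu[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_cells))
    if two_populations:
        genes = rng.choice(n_genes, max(1, int(shift_frac * n_genes)), replace=False)
        log_vals[np.ix_(genes, np.arange(n_cells // 2, n_cells))] += shift
    raw = np.maximum(np.exp2(log_vals) - 1.0, 0.0)
    per_embryo = n_cells // n_embryos
    cells = [f"E{i // per_embryo + 1}_c{i % per_embryo + 1}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "cell_id": cells,
            "embryo_id": [c.split("_")[0] for c in cells],
            "stage": "stage1",
        }
    )
    genes_idx = [f"G{i:05d}" for i in range(n_genes)]
    return attach_metadata(
        ExpressionDataset(
            values=pd.DataFrame(raw, index=genes_idx, columns=cells),
            stages=("stage1",),
        ),
        meta,
        stages=("stage1",),
    )


# ---------------------------------------------------------------------------
# SD vs CV simulation benchmark
# ---------------------------------------------------------------------------


def _majority_recall(true_labels: np.ndarray, pred: np.ndarray) -> dict:
    """Per-planted-level recall after majority-mapping predicted clusters."""
    recall = {}
    mapping = {}
    for c in np.unique(pred):
        members = true_labels[pred == c]
        vals, cnts = np.unique(members, return_counts=True)
        mapping[c] = vals[cnts.argmax()]
    mapped = np.array([mapping[c] for c in pred])
    for lev in np.unique(true_labels):
        mask = true_labels == lev
        recall[float(lev)] = float((mapped[mask] == lev).mean())
    return recall


def sd_cv_benchmark(
    seed: int,
    n_genes: int = 3000,
    levels: tuple[float, float, float] = (0.2, 0.8, 1.6),
    zero_inflation: float = 0.0,
    n_embryos: int = 3,
    cells_per_embryo: int = 8,
    base_logmean: float = 6.0,
    low_logmean: float = 2.0,
    frac_low_expression: float = 1 / 3,
) -> dict:
    """Head-to-head classification benchmark: SDC vs CV.

    Simulates one stage of genes planted at three variability levels
    (cell-level log-scale SDs), all at a common log-mean except — when
    ``zero_inflation`` > 0 — a low-expression fraction whose cells drop to
    zero with that probability.  Each statistic (SDC, CV) is computed on
    log2(x + 1) values and clustered by a BIC-selected Gaussian mixture
    (K = 1..5); agreement with the planted levels is scored by the adjusted
    Rand index.  Genes with an undefined CV form their own predicted
    cluster.

    Returns a dict with selected K, ARI and per-level recall per statistic.
    """
    if len(set(levels)) != len(levels):
        raise ValueError("variability levels must be distinct")
    rng = np.random.default_rng(seed)
    level_arr = np.asarray(levels, dtype=float)
    truth = np.tile(np.arange(len(levels)), n_genes // len(levels) + 1)[:n_genes]
    sigma = level_arr[truth]

    mu = np.full(n_genes, base_logmean)
    zi_genes = np.zeros(n_genes, dtype=bool)
    if zero_inflation > 0:
        n_low = int(round(frac_low_expression * n_genes))
        low_idx = rng.choice(n_genes, size=n_low, replace=False)
        mu[low_idx] = low_logmean
        zi_genes[low_idx] = True

    n_cells = n_embryos * cells_per_embryo
    log_vals = mu[:, None] + rng.normal(0, 1, size=(n_genes, n_cells)) * sigma[:, None]
    raw = np.maximum(np.exp2(log_vals) - 1.0, 0.0)
    if zi_genes.any():
        drop = rng.uniform(size=(int(zi_genes.sum()), n_cells)) < zero_inflation
        raw[zi_genes] = np.where(drop, 0.0, raw[zi_genes])

    genes = [f"G{i:05d}" for i in range(n_genes)]
    cells = [f"E{j + 1}_c{i + 1}" for j in range(n_embryos) for i in range(cells_per_embryo)]
    meta = pd.DataFrame(
        {
            "cell_id": cells,
            "embryo_id": [c.split("_")[0] for c in cells],
            "stage": "sim",
        }
    )
    ds = attach_metadata(
        ExpressionDataset(values=pd.DataFrame(raw, index=genes, columns=cells),
                          stages=("sim",)),
        meta,
        stages=("sim",),
    )
    from .dataset import log_transform

    ds_log = log_transform(ds)

    report = {}
    sdc = compute_sdc(ds_log, "sim").to_numpy()
    cv = compute_cv(ds_log, "sim").to_numpy()
    for name, stat in (("sdc", sdc), ("cv", cv)):
        defined = np.isfinite(stat)
        fit = select_k(stat[defined], k_min=1, k_max=5, seed=seed)
        pred = np.full(n_genes, -1)
        pred[defined] = fit.assignments
        report[name] = {
            "selected_K": fit.K,
            "ari": float(adjusted_rand_score(truth, pred)),
            "per_level_recall": _majority_recall(level_arr[truth], pred),
            "n_undefined": int((~defined).sum()),
        }
    report["levels"] = list(levels)
    report["zero_inflation"] = zero_inflation
    report["n_genes"] = n_genes
    return report
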