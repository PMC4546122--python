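"""Cell-subsampling heterogeneity profiles.

For every combination of ``r`` cells drawn from a stage (pooled across
embryos by default), the *variability profile* is the smoothed density of
the per-gene population SDs computed across the selected cells: it shows
what proportion of the transcriptome is expressed at which level of
inter-cellular variability in that particular group of cells.  Comparing
profiles across combinations quantifies how heterogeneous the stage's cell
population is — a homogeneous population yields overlapping profiles, while
distinct sub-populations produce clusters of divergent profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import gaussian_kde

from .dataset import DatasetError, ExpressionDataset

__all__ = [
    "CombinationProfile",
    "enumerate_combinations",
    "combination_profile",
    "make_grid",
    "profile_diversity",
    "stage_profiles",
]


@dataclass(frozen=True)
class CombinationProfile:
    stage: str
    cells: tuple[int, ...]  # sorted positional indices into the stage's cells
    gene_sds: np.ndarray  # per-gene population SD across the selected cells
    grid: np.ndarray
    density: np.ndarray  # KDE of gene_sds evaluated on grid


def enumerate_combinations(
    ds: ExpressionDataset, stage: str, r: int = 4, per_embryo: bool = False
):
    """Iterate over all sorted r-cell index tuples of a stage.

    Cells are pooled across the stage's embryos (indices refer to the
    stage's cell list); ``per_embryo=True`` instead enumerates within each
    embryo separately.  Yields exactly C(n, r) tuples in lexicographic
    order.
    """
    if per_embryo:
        cells = list(ds.cells_of_stage(stage))
        pos = {c: i for i, c in enumerate(cells)}
        for emb in ds.embryos_of_stage(stage):
            emb_cells = [pos[c] for c in ds.cells_of_embryo(emb)]
            if len(emb_cells) < r:
                raise DatasetError(
                    f"embryo {emb!r} has {len(emb_cells)} cells < r={r}"
                )
            yield from combinations(sorted(emb_cells), r)
        return
    n = len(ds.cells_of_stage(stage))
    if n < r:
        raise DatasetError(f"stage {stage!r} has {n} cells < r={r}")
    yield from combinations(range(n), r)


def make_grid(ds: ExpressionDataset, stage: str, r: int = 4, n_points: int = 512):
    """Shared density grid for a stage: [0, 1.1 * max per-gene SD over cells]."""
    cells = ds.cells_of_stage(stage)
    block = ds.values[cells].to_numpy()
    max_sd = float(block.std(axis=1, ddof=0).max())
    hi = 1.1 * max_sd if max_sd > 0 else 1.0
    return np.linspace(0.0, hi, n_points)


def combination_profile(
    ds: ExpressionDataset, stage: str, cells: tuple[int, ...], grid: np.ndarray
) -> CombinationProfile:
    """Variability profile of one r-cell combination.

    Per-gene population SD across the selected cells, smoothed by a
    Gaussian KDE with Silverman's rule-of-thumb bandwidth on the shared
    grid.  If every SD is identical (e.g. duplicated cells), the density
    degenerates to a spike at that value.
    """
    if len(cells) < 2:
        raise ValueError("need >= 2 cells in a combination")
    stage_cells = ds.cells_of_stage(stage)
    block = ds.values[stage_cells[list(cells)]].to_numpy()
    sds = block.std(axis=1, ddof=0)
    if np.ptp(sds) == 0.0:
        density = np.zeros_like(grid)
        idx = int(np.argmin(np.abs(grid - sds[0])))
        step = grid[1] - grid[0] if len(grid) > 1 else 1.0
        density[idx] = 1.0 / step  # unit-mass spike
    else:
        kde = gaussian_kde(sds, bw_method="silverman")
        # SDs are non-negative: reflect kernel mass that falls below zero,
        # then renormalise to exactly unit mass on the grid
        density = kde(grid) + kde(-grid)
        mass = np.trapezoid(density, grid)
        if mass > 0:
            density = density / mass
    return CombinationProfile(
        stage=stage,
        cells=tuple(sorted(cells)),
        gene_sds=sds,
        grid=grid,
        density=density,
    )


def stage_profiles(
    ds: ExpressionDataset,
    stage: str,
    r: int = 4,
    max_combinations: int = 50_000,
    seed: int = 1,
    n_grid: int = 512,
) -> list[CombinationProfile]:
    """All r-cell combination profiles of a stage on a shared grid.

    Exact enumeration by default; when C(n, r) exceeds ``max_combinations``
    a seeded uniform subsample of combinations is profiled instead.
    """
    n = len(ds.cells_of_stage(stage))
    total = comb(n, r)
    combos = list(enumerate_combinations(ds, stage, r=r))
    if total > max_combinations:
        rng = np.random.default_rng(seed)
        pick = rng.choice(total, size=max_combinations, replace=False)
        combos = [combos[i] for i in sorted(pick)]
    grid = make_grid(ds, stage, r=r, n_points=n_grid)
    return [combination_profile(ds, stage, c, grid) for c in combos]


def profile_diversity(
    profiles: list[CombinationProfile], cut: float = 0.5
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pairwise L1 distances between profiles and a descriptive grouping.

    Returns (distance matrix, single-linkage group labels at ``cut``,
    heterogeneity index).  The heterogeneity index is the mean pairwise L1
    distance between densities (integrated absolute difference via the
    trapezoid rule) — larger means a more heterogeneous cell population.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if p.grid.shape != grid.shape or not np.allclose(p.grid, grid):
            raise ValueError("profiles are on mismatched grids")
    dens = np.vstack([p.density for p in profiles])
    n = len(profiles)
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(dens[i + 1:] - dens[i])
        if diff.size:
            d = np.trapezoid(diff, grid, axis=1)
            dist[i, i + 1:] = d
            dist[i + 1:, i] = d
    from scipy.spatial.distance import squareform

    if np.any(dist > 0):
        Z = linkage(squareform(dist, checks=False), method="single")
        labels = fcluster(Z, t=cut, criterion="distance")
    else:
        labels = np.ones(n, dtype=int)
    index = float(dist[np.triu_indices(n, k=1)].mean())
    return dist, labels, index
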