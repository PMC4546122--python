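"""Statistical tests used throughout the pipeline.

All four procedures are implemented here directly — Levene's test for
heteroscedasticity (with the Brown–Forsythe median-centred variant), the
classical one-way fixed-effects ANOVA, Benjamini–Hochberg step-up FDR
adjustment, and the two-sided Fisher exact test on a 2x2 table — so that
every numerical choice (centring, divisor, two-sidedness rule) is explicit
and recorded in the result.

Vectorised ``*_many`` variants run the grouped tests for thousands of genes
at once on a genes x cells matrix; they are algebraically identical to the
scalar forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
from scipy import special

__all__ = [
    "TestResult",
    "FisherResult",
    "levene_test",
    "anova_oneway",
    "levene_many",
    "anova_many",
    "bh_adjust",
    "fisher_2x2",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: tuple[int, int]
    method: str


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # sample OR ad/bc; inf when bc == 0 and ad > 0; nan for 0/0
    p_two_sided: float
    direction: str  # "enrichment" (OR > 1), "depletion" (OR < 1), "none"


def _as_groups(groups) -> list[np.ndarray]:
    out = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("each group needs >= 2 one-dimensional observations")
        if not np.isfinite(arr).all():
            raise ValueError("non-finite observation in group")
        out.append(arr)
    if len(out) < 2:
        raise ValueError("need >= 2 groups")
    return out


def _f_oneway_groups(groups: list[np.ndarray], method: str) -> TestResult:
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n_total = int(ns.sum())
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df1, df2 = k - 1, n_total - k
    if ss_within <= 0.0:
        if ss_between <= 0.0:
            return TestResult(0.0, 1.0, (df1, df2), method)
        return TestResult(np.inf, 0.0, (df1, df2), method)
    f = (ss_between / df1) / (ss_within / df2)
    p = float(special.fdtrc(df1, df2, f))
    return TestResult(float(f), p, (df1, df2), method)


def levene_test(groups, center: str = "mean") -> TestResult:
    """Levene's test for equality of variances across groups.

    Transforms each observation to its absolute deviation from the group
    centre (mean for classic Levene, median for Brown–Forsythe) and applies
    a one-way ANOVA F test to the deviations.  Identical groups give
    statistic 0, p 1.
    """
    gs = _as_groups(groups)
    if center == "mean":
        zs = [np.abs(g - g.mean()) for g in gs]
    elif center == "median":
        zs = [np.abs(g - np.median(g)) for g in gs]
    else:
        raise ValueError(f"unknown center {center!r}")
    return _f_oneway_groups(zs, f"levene[{center}]")


def anova_oneway(groups) -> TestResult:
    """Classical one-way fixed-effects ANOVA F test on raw values."""
    return _f_oneway_groups(_as_groups(groups), "anova")


# ---------------------------------------------------------------------------
# vectorised per-gene forms
# ---------------------------------------------------------------------------


def _f_many(z: np.ndarray, labels: np.ndarray, method: str):
    """Row-wise one-way F test: z is genes x observations, labels per column."""
    uniq = np.unique(labels)
    k = len(uniq)
    n_total = z.shape[1]
    grand = z.mean(axis=1)
    ss_between = np.zeros(z.shape[0])
    ss_within = np.zeros(z.shape[0])
    for lab in uniq:
        sub = z[:, labels == lab]
        m = sub.mean(axis=1)
        ss_between += sub.shape[1] * (m - grand) ** 2
        ss_within += ((sub - m[:, None]) ** 2).sum(axis=1)
    df1, df2 = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    p = np.where(
        ss_within > 0.0,
        special.fdtrc(df1, df2, np.where(ss_within > 0.0, f, 1.0)),
        np.where(ss_between > 0.0, 0.0, 1.0),
    )
    f = np.where(ss_within > 0.0, f, np.where(ss_between > 0.0, np.inf, 0.0))
    return f, p, (df1, df2)


def levene_many(values: np.ndarray, labels, center: str = "mean"):
    """Levene's test per row of ``values`` (genes x cells), groups from labels.

    Returns (statistic, p_value) arrays.
    """
    labels = np.asarray(labels)
    z = np.empty_like(values, dtype=float)
    for lab in np.unique(labels):
        cols = labels == lab
        sub = values[:, cols]
        if center == "mean":
            c = sub.mean(axis=1)
        elif center == "median":
            c = np.median(sub, axis=1)
        else:
            raise ValueError(f"unknown center {center!r}")
        z[:, cols] = np.abs(sub - c[:, None])
    f, p, _ = _f_many(z, labels, f"levene[{center}]")
    return f, p


def anova_many(values: np.ndarray, labels):
    """One-way ANOVA per row of ``values``; returns (statistic, p_value)."""
    labels = np.asarray(labels)
    f, p, _ = _f_many(np.asarray(values, dtype=float), labels, "anova")
    return f, p


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj p_(i) = min over j >= i of ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and within [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------


def _log_hyper_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(A = a) for the hypergeometric table distribution with fixed margins."""
    n = r1 + r2
    return (
        lgamma(r1 + 1) - lgamma(a + 1) - lgamma(r1 - a + 1)
        + lgamma(r2 + 1) - lgamma(c1 - a + 1) - lgamma(r2 - c1 + a + 1)
        - (lgamma(n + 1) - lgamma(c1 + 1) - lgamma(n - c1 + 1))
    )


def fisher_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher exact test for the table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities (margins fixed) of
    every table at most as probable as the observed one; a small relative
    slack absorbs floating-point ties.  The odds ratio is the sample
    estimate ad/bc.
    """
    for x in (a, b, c, d):
        if not isinstance(x, (int, np.integer)) or x < 0:
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero 2x2 table")
    r1, r2 = a + b, c + d
    c1 = a + c
    lo, hi = max(0, c1 - r2), min(c1, r1)
    log_obs = _log_hyper_pmf(a, r1, r2, c1)
    support = np.arange(lo, hi + 1)
    log_pmf = np.array([_log_hyper_pmf(int(x), r1, r2, c1) for x in support])
    p = float(np.exp(log_pmf[log_pmf <= log_obs + 1e-7]).sum())
    p = min(p, 1.0)

    if b * c == 0:
        odds = np.nan if a * d == 0 else np.inf
    else:
        odds = (a * d) / (b * c)
    if np.isnan(odds) or odds == 1.0:
        direction = "none"
    elif odds > 1.0:
        direction = "enrichment"
    else:
        direction = "depletion"
    return FisherResult(odds_ratio=float(odds), p_two_sided=p, direction=direction)
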