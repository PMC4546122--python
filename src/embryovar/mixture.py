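"""Univariate Gaussian mixtures with BIC model selection, plus hierarchical
clustering.

The EM fitter is written directly for the 1-D case: with at most a few
thousand points and K <= 9 this is fast, fully deterministic given a seed,
and lets model-selection details (restart scheme, variance floor, BIC
parameter count, tie-breaks) be stated exactly.  Both equal-variance and
free-variance families are available; :func:`select_k` searches K and, by
default, both families, returning the minimum-BIC fit with ties broken
toward smaller K.

Hierarchical clustering wraps scipy's agglomerative linkage (complete
linkage, Euclidean distance by default) and cuts the dendrogram at k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import brentq

__all__ = [
    "MixtureFit",
    "fit_gmm_1d",
    "select_k",
    "mixture_boundaries",
    "HClustResult",
    "hcluster",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MixtureFit:
    K: int
    weights: np.ndarray  # simplex, components sorted by ascending mean
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    bic: float
    assignments: np.ndarray  # max-posterior component per point, 0-based
    posteriors: np.ndarray  # n x K, rows sum to 1
    variance_model: str
    n: int
    seed: int


def _log_density(x: np.ndarray, w: np.ndarray, mu: np.ndarray, var: np.ndarray):
    """n x K matrix of log(w_k * N(x | mu_k, var_k)) and per-point logsumexp."""
    z = (x[:, None] - mu[None, :]) ** 2 / var[None, :]
    log_comp = np.log(w[None, :]) - 0.5 * (_LOG_2PI + np.log(var[None, :]) + z)
    m = log_comp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
    return log_comp, lse


def _em_once(
    x: np.ndarray,
    mu0: np.ndarray,
    variance_model: str,
    var_floor: float,
    tol: float = 1e-8,
    max_iter: int = 500,
    w0: np.ndarray | None = None,
    var0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    K = len(mu0)
    n = len(x)
    w = np.full(K, 1.0 / K) if w0 is None else w0.copy()
    mu = mu0.copy()
    if var0 is None:
        var0 = np.full(K, max(x.var(), var_floor))
    var = var0.copy()
    x2 = x * x
    prev_ll = -np.inf
    for _ in range(max_iter):
        log_comp, lse = _log_density(x, w, mu, var)
        ll = float(lse.sum())
        resp = np.exp(log_comp - lse[:, None])
        nk = np.maximum(resp.sum(axis=0), 1e-300)
        w = nk / n
        sx = x @ resp
        mu = sx / nk
        sq = np.maximum(x2 @ resp - 2.0 * mu * sx + mu * mu * nk, 0.0)
        if variance_model == "equal":
            var = np.full(K, max(float(sq.sum() / n), var_floor))
        else:
            var = np.maximum(sq / nk, var_floor)
        if ll - prev_ll < tol * max(abs(ll), 1.0) and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
    _, lse = _log_density(x, w, mu, var)
    return w, mu, var, float(lse.sum())


def _em_burnin(
    x: np.ndarray,
    mu0: np.ndarray,  # (R, K) initial means, one row per restart
    variance_model: str,
    var_floor: float,
    n_iter: int = 40,
):
    """Run a fixed number of EM iterations for all restarts at once.

    Restarts are vectorised along the leading axis; the caller polishes the
    best restart to full convergence afterwards.  Returns (w, mu, var, ll)
    with per-restart leading dimension.
    """
    R, K = mu0.shape
    n = len(x)
    w = np.full((R, K), 1.0 / K)
    mu = mu0.copy()
    var = np.full((R, K), max(x.var(), var_floor))
    xc = x[None, :, None]
    for _ in range(n_iter):
        z = (xc - mu[:, None, :]) ** 2 / var[:, None, :]
        log_comp = (
            np.log(w[:, None, :])
            - 0.5 * (_LOG_2PI + np.log(var[:, None, :]) + z)
        )
        m = log_comp.max(axis=2, keepdims=True)
        lse = m[:, :, 0] + np.log(np.exp(log_comp - m).sum(axis=2))
        resp = np.exp(log_comp - lse[:, :, None])
        nk = np.maximum(resp.sum(axis=1), 1e-300)
        w = nk / n
        mu = (resp * xc).sum(axis=1) / nk
        sq = (resp * (xc - mu[:, None, :]) ** 2).sum(axis=1)
        if variance_model == "equal":
            var = np.repeat(
                np.maximum(sq.sum(axis=1, keepdims=True) / n, var_floor), K, axis=1
            )
        else:
            var = np.maximum(sq / nk, var_floor)
    z = (xc - mu[:, None, :]) ** 2 / var[:, None, :]
    log_comp = (
        np.log(w[:, None, :]) - 0.5 * (_LOG_2PI + np.log(var[:, None, :]) + z)
    )
    m = log_comp.max(axis=2, keepdims=True)
    lse = m[:, :, 0] + np.log(np.exp(log_comp - m).sum(axis=2))
    ll = lse.sum(axis=1)
    return w, mu, var, ll


def _n_params(K: int, variance_model: str) -> int:
    return (K - 1) + K + (1 if variance_model == "equal" else K)


def fit_gmm_1d(
    x,
    K: int,
    variance_model: str = "free",
    seed: int = 1,
    n_restarts: int = 10,
) -> MixtureFit:
    """Fit a K-component univariate Gaussian mixture by restarted EM.

    Initial means come from quantiles of the data plus seeded jitter; the
    best of ``n_restarts`` runs (highest log-likelihood) wins.  Component
    variances are floored at 1e-6 * var(x) to prevent degenerate spikes.
    BIC = -2 loglik + p log n with p = (K-1) + K + (1 or K).
    """
    x = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in input")
    n = len(x)
    if n < K:
        raise ValueError(f"need n >= K (n={n}, K={K})")
    data_var = x.var()
    if data_var == 0.0 and K > 1:
        raise ValueError("zero-variance input with K > 1")
    var_floor = max(1e-6 * data_var, 1e-12)
    rng = np.random.default_rng(seed)
    qs = np.quantile(x, (np.arange(K) + 0.5) / K)
    scale = np.sqrt(data_var) if data_var > 0 else 1.0

    R = max(1, n_restarts)
    mu0 = np.tile(qs, (R, 1))
    if R > 1:
        mu0[1:] += rng.normal(0.0, 0.25 * scale, size=(R - 1, K))
    # short vectorised burn-in over all restarts, then polish the best
    # restart to full convergence
    ws, mus, vars_, lls = _em_burnin(x, mu0, variance_model, var_floor)
    b = int(np.argmax(lls))
    w, mu, var, ll = _em_once(
        x, mus[b], variance_model, var_floor, w0=ws[b], var0=vars_[b]
    )

    order = np.argsort(mu, kind="mergesort")
    w, mu, var = w[order], mu[order], var[order]
    log_comp, lse = _log_density(x, w, mu, var)
    post = np.exp(log_comp - lse[:, None])
    assignments = post.argmax(axis=1)
    p = _n_params(K, variance_model)
    bic = -2.0 * ll + p * np.log(n)
    return MixtureFit(
        K=K,
        weights=w,
        means=mu,
        variances=var,
        loglik=ll,
        bic=float(bic),
        assignments=assignments,
        posteriors=post,
        variance_model=variance_model,
        n=n,
        seed=seed,
    )


def select_k(
    x,
    k_min: int = 1,
    k_max: int = 9,
    variance_model: str | None = None,
    seed: int = 1,
    n_restarts: int = 10,
) -> MixtureFit:
    """Fit K = k_min..k_max and return the minimum-BIC mixture.

    ``variance_model=None`` searches both the equal- and free-variance
    families and keeps the overall best.  BIC ties break toward smaller K;
    ``k_max`` is lowered with a warning when it exceeds n.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if k_max > n:
        warnings.warn(f"k_max={k_max} > n={n}; lowering k_max to {n}")
        k_max = n
    families = ("equal", "free") if variance_model is None else (variance_model,)
    degenerate = x.var() == 0.0
    best: MixtureFit | None = None
    for k in range(k_min, k_max + 1):
        if degenerate and k > 1:
            break
        for fam in families:
            fit = fit_gmm_1d(x, k, variance_model=fam, seed=seed, n_restarts=n_restarts)
            if best is None or fit.bic < best.bic - 1e-9:
                best = fit
    assert best is not None
    return best


def mixture_boundaries(fit: MixtureFit) -> list[float]:
    """Cut points between consecutive components of a 1-D mixture.

    Between each pair of adjacent (mean-sorted) components, the point where
    their posterior probabilities are equal, i.e. where the weighted
    component densities cross, located by root bisection between the means.
    Empty for K = 1.
    """
    if fit.K < 2:
        return []

    def log_wpdf(x: float, k: int) -> float:
        v = fit.variances[k]
        return (
            np.log(fit.weights[k])
            - 0.5 * (_LOG_2PI + np.log(v) + (x - fit.means[k]) ** 2 / v)
        )

    cuts = []
    for k in range(fit.K - 1):
        lo, hi = fit.means[k], fit.means[k + 1]
        f = lambda t: log_wpdf(t, k) - log_wpdf(t, k + 1)
        if f(lo) <= 0 or f(hi) >= 0:
            # densities do not cross between the means (heavy overlap);
            # fall back to the weighted midpoint
            cuts.append(float((lo + hi) / 2.0))
            continue
        cuts.append(float(brentq(f, lo, hi, xtol=1e-10)))
    return cuts


@dataclass(frozen=True)
class HClustResult:
    labels: np.ndarray  # cluster index per item, 1..k
    k: int
    linkage: str
    distance: str


def hcluster(
    vectors,
    k: int,
    linkage_method: str = "complete",
    distance: str = "euclidean",
) -> HClustResult:
    """Agglomerative hierarchical clustering cut at k clusters."""
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    n = arr.shape[0]
    if n < k:
        raise ValueError(f"need n >= k (n={n}, k={k})")
    if linkage_method not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    Z = linkage(arr, method=linkage_method, metric=distance)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return HClustResult(labels=labels, k=int(labels.max()), linkage=linkage_method,
                        distance=distance)
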