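"""InfoMax ICA and ICASSO run-stability analysis.

The engine performs spatial ICA: the input is the whitened ``K x voxels``
group matrix, voxels are the samples, and the recovered sources are spatial
maps.  InfoMax maximises the output entropy of a logistic nonlinearity by
natural-gradient ascent, which suits the super-Gaussian (spatially sparse)
sources that resting-state networks resemble.

ICASSO quantifies how repeatable each component is: ICA is rerun many times
under bootstrap resampling of the samples and/or fresh random initial
weights, all estimates are pooled and clustered by the absolute correlation
of their maps, and each cluster is summarised by its stability index Iq
(mean intra-cluster similarity minus mean similarity to outside estimates)
and a centrotype — the member most similar to the rest of its cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import skew

from .errors import CognetError, ValidationError
from .reduction import ReducedData

__all__ = ["IcaRun", "IcassoResult", "run_infomax", "run_icasso", "iq_index"]


@dataclass
class IcaRun:
    """A single InfoMax estimate on whitened data."""

    unmixing: np.ndarray      # (K, K)
    sources: np.ndarray       # (K, n_samples) spatial maps, skewness >= 0 rows
    converged: bool
    n_iter: int
    seed: int


@dataclass
class IcassoResult:
    """Pooled ICA estimates, their clustering and per-cluster stability."""

    centrotypes: np.ndarray       # (K, n_samples) one representative map per cluster
    iq: np.ndarray                # (K,) stability index per cluster, aligned rows
    similarity: np.ndarray        # (M, M) |corr| between all pooled maps
    assignments: np.ndarray       # (M,) cluster id in 0..K-1 per pooled estimate
    runs: list = field(default_factory=list, repr=False)
    n_failed: int = 0

    @property
    def k(self) -> int:
        return self.centrotypes.shape[0]


def _fix_sign(sources: np.ndarray, unmixing: np.ndarray | None = None):
    """Flip rows so every source map has nonnegative skewness (sign convention)."""
    flip = np.where(skew(sources, axis=1) < 0, -1.0, 1.0)
    sources = sources * flip[:, None]
    if unmixing is not None:
        unmixing = unmixing * flip[:, None]
    return sources, unmixing


def run_infomax(whitened, seed: int = 0, max_iter: int = 500, tol: float = 1e-6,
                lrate: float = 0.015, anneal: float = 0.9,
                block: int | None = None) -> IcaRun:
    """Natural-gradient InfoMax with a logistic nonlinearity.

    Parameters follow the classical runica recipe: data are visited in
    shuffled blocks, the unmixing matrix is updated by
    ``W += lrate * (block*I + (1 - 2*g(WX)) (WX)^T) W`` with
    ``g(u) = 1/(1+e^-u)``, and the learning rate is annealed whenever the
    direction of weight change reverses by more than 60 degrees.
    Convergence is declared when the maximum absolute weight change over a
    full pass drops below ``tol``.  Non-convergence at ``max_iter`` is
    flagged on the result, not raised.  Deterministic for a given seed.
    """
    Z = np.asarray(getattr(whitened, "whitened", whitened), dtype=float)
    if Z.ndim != 2:
        raise ValidationError("whitened data must be 2-D (components x samples)")
    K, N = Z.shape
    if K == 1:
        src, _ = _fix_sign(Z.copy())
        w = np.array([[1.0]]) if np.array_equal(src, Z) else np.array([[-1.0]])
        return IcaRun(unmixing=w, sources=src, converged=True, n_iter=0, seed=seed)

    rng = np.random.default_rng(seed)
    W = rng.normal(scale=1.0 / np.sqrt(K), size=(K, K))
    # guard against a near-singular random start
    while np.linalg.cond(W) > 1e6:
        W = rng.normal(scale=1.0 / np.sqrt(K), size=(K, K))
    if block is None:
        block = int(np.clip(np.floor(np.sqrt(N / 3.0)), 8, 512))
    eye = np.eye(K)
    prev_delta = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W_old = W.copy()
        perm = rng.permutation(N)
        for start in range(0, N - block + 1, block):
            idx = perm[start:start + block]
            u = W @ Z[:, idx]
            y = 1.0 / (1.0 + np.exp(-u))
            W = W + lrate * ((block * eye + (1.0 - 2.0 * y) @ u.T) / block) @ W
            if not np.all(np.isfinite(W)) or np.max(np.abs(W)) > 1e8:
                # blow-up: restart from a smaller learning rate
                lrate *= 0.5
                W = rng.normal(scale=1.0 / np.sqrt(K), size=(K, K))
                prev_delta = None
                break
        delta = W - W_old
        change = np.max(np.abs(delta))
        if prev_delta is not None:
            denom = np.linalg.norm(delta) * np.linalg.norm(prev_delta)
            if denom > 0:
                cos = float(np.sum(delta * prev_delta) / denom)
                if cos < 0.5:       # direction swung by more than 60 degrees
                    lrate *= anneal
        prev_delta = delta
        if change < tol:
            converged = True
            break
    sources = W @ Z
    sources, W = _fix_sign(sources, W)
    return IcaRun(unmixing=W, sources=sources, converged=converged, n_iter=it, seed=seed)


def iq_index(similarity: np.ndarray, cluster: np.ndarray | list) -> float:
    """Cluster stability index Iq.

    ``Iq = mean(similarity within the cluster, self-pairs excluded)
          - mean(similarity between cluster members and all non-members)``.

    A singleton cluster contributes intra-similarity 1 (only the self pair);
    when the cluster contains every estimate the extra-cluster term is 0 —
    hence a perfectly tight, perfectly separated cluster scores 1.
    """
    sim = np.asarray(similarity, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValidationError("similarity must be a square matrix")
    if not np.allclose(sim, sim.T, atol=1e-8):
        raise ValidationError("similarity must be symmetric")
    members = np.asarray(sorted(set(int(i) for i in cluster)), dtype=int)
    if members.size == 0:
        raise ValidationError("empty cluster")
    m = members.size
    n = sim.shape[0]
    outside = np.setdiff1d(np.arange(n), members)
    if m == 1:
        intra = 1.0
    else:
        sub = sim[np.ix_(members, members)]
        intra = float((sub.sum() - np.trace(sub)) / (m * (m - 1)))
    extra = float(sim[np.ix_(members, outside)].mean()) if outside.size else 0.0
    return intra - extra


def run_icasso(whitened: ReducedData | np.ndarray, n_runs: int = 100,
               resample: str = "bootstrap", seed: int = 0,
               max_iter: int = 500, tol: float = 1e-6) -> IcassoResult:
    """Repeated InfoMax with resampling, clustering and Iq stability.

    ``resample`` is one of ``bootstrap`` (resample the sample dimension with
    replacement, fixed initial weights), ``randinit`` (full data, fresh random
    initial weights per run), ``both``, or ``none`` (full data, fixed initial
    weights — every run identical, useful only as a sanity check).  Runs that
    fail to converge are
    excluded from pooling with a warning; more than 50% failures is an error.
    Estimated maps are always evaluated on the full data so they are
    comparable across runs.  Components are returned ordered by descending
    Iq, each row sign-fixed to nonnegative skewness.
    """
    if n_runs < 2:
        raise ValidationError("n_runs must be >= 2")
    if resample not in ("bootstrap", "randinit", "both", "none"):
        raise ValidationError(f"unknown resample mode {resample!r}")
    Z = np.asarray(getattr(whitened, "whitened", whitened), dtype=float)
    K, N = Z.shape
    rng = np.random.default_rng(seed)
    init_seeds = rng.integers(0, 2**31 - 1, size=n_runs)

    runs: list[IcaRun] = []
    maps = []
    n_failed = 0
    for r in range(n_runs):
        data = Z
        if resample in ("bootstrap", "both"):
            data = Z[:, rng.integers(0, N, size=N)]
        w_seed = int(init_seeds[r]) if resample in ("randinit", "both") else int(init_seeds[0])
        run = run_infomax(data, seed=w_seed, max_iter=max_iter, tol=tol)
        if not run.converged:
            n_failed += 1
            warnings.warn(f"ICASSO run {r} did not converge; excluded from pooling")
            continue
        full_sources, unmixing = _fix_sign(run.unmixing @ Z, run.unmixing)
        runs.append(IcaRun(unmixing=unmixing, sources=full_sources,
                           converged=True, n_iter=run.n_iter, seed=w_seed))
        maps.append(full_sources)
    if n_failed > n_runs // 2:
        raise CognetError(f"{n_failed}/{n_runs} ICASSO runs failed to converge")

    pooled = np.concatenate(maps, axis=0)                   # (M, N)
    sim = np.abs(np.corrcoef(pooled))
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    dist = squareform(1.0 - sim, checks=False)
    labels = fcluster(linkage(dist, method="average"), t=K, criterion="maxclust") - 1

    iqs = np.empty(K)
    cents = np.empty((K, N))
    for c in range(K):
        members = np.flatnonzero(labels == c)
        iqs[c] = iq_index(sim, members)
        within = sim[np.ix_(members, members)].sum(axis=1)
        cents[c] = pooled[members[int(np.argmax(within))]]
    order = np.argsort(-iqs, kind="stable")
    cents, _ = _fix_sign(cents[order])
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(K)
    return IcassoResult(centrotypes=cents, iq=iqs[order], similarity=sim,
                        assignments=relabel[labels], runs=runs, n_failed=n_failed)
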