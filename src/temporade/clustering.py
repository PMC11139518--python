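"""Fuzzy c-means clustering of standardized temporal expression profiles.

For one biological condition, each gene's profile is its per-time mean
log-normalized expression, row-standardized to mean 0 / sd 1 so clustering
groups *shapes* rather than expression levels.  A from-scratch fuzzy
c-means (Euclidean distance, fuzzifier m) assigns each gene a soft
membership over k temporal clusters; centroids are the membership^m-
weighted mean profiles.  m -> 1 approaches hard k-means behaviour, larger m
softens memberships.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .design import ExperimentalDesign

__all__ = [
    "TemporalProfileMatrix",
    "FuzzyClusterResult",
    "temporal_profiles",
    "fuzzy_cmeans",
    "estimate_fuzzifier",
    "select_k",
]

_COINCIDENCE_EPS = 1e-12


@dataclass
class TemporalProfileMatrix:
    values: np.ndarray          # genes x T
    gene_ids: tuple[str, ...]
    condition: str
    times: tuple[str, ...]
    standardized: bool = True

    @property
    def n_profiles(self) -> int:
        return self.values.shape[0]


@dataclass
class FuzzyClusterResult:
    memberships: np.ndarray     # genes x k, rows sum to 1
    centroids: np.ndarray       # k x T
    m: float
    k: int
    converged: bool
    n_iter: int
    objective: tuple[float, ...] = ()

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


def temporal_profiles(
    log_matrix: np.ndarray,
    gene_ids,
    design: ExperimentalDesign,
    condition: str,
    standardize: bool = True,
) -> TemporalProfileMatrix:
    """Per-time mean log expression for one condition, row-standardized.

    Constant (flat) profiles carry no shape information and are dropped
    with a warning when standardizing.
    """
    if condition not in design.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    X = np.asarray(log_matrix, dtype=float)
    cols = []
    for t in design.times:
        idx = design.sample_indices(condition, t)
        if not idx:
            raise ValueError(f"missing samples for cell ({condition!r}, {t!r})")
        cols.append(X[:, idx].mean(axis=1))
    P = np.column_stack(cols)
    gene_ids = tuple(gene_ids)
    if standardize:
        sd = P.std(axis=1, ddof=1)
        keep = sd > 0
        if (~keep).any():
            warnings.warn(
                f"dropping {int((~keep).sum())} flat profile(s) in condition {condition!r}"
            )
        P = (P[keep] - P[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
        gene_ids = tuple(g for g, k in zip(gene_ids, keep) if k)
    return TemporalProfileMatrix(P, gene_ids, condition, tuple(design.times),
                                 standardized=standardize)


def _memberships(X: np.ndarray, C: np.ndarray, m: float) -> np.ndarray:
    """u[g, c] = 1 / sum_c' (d_gc / d_gc')^(2/(m-1)); coincident profiles get
    membership 1 for their centroid."""
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    U = np.zeros_like(d2)
    coincident = d2.min(axis=1) < _COINCIDENCE_EPS
    if coincident.any():
        U[coincident, np.argmin(d2[coincident], axis=1)] = 1.0
    reg = ~coincident
    if reg.any():
        w = d2[reg] ** (-1.0 / (m - 1.0))
        U[reg] = w / w.sum(axis=1, keepdims=True)
    return U


def fuzzy_cmeans(
    profiles: TemporalProfileMatrix | np.ndarray,
    k: int,
    m: float = 2.0,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> FuzzyClusterResult:
    """Standard fuzzy c-means with Euclidean distance.

    Centroids are initialized from k profiles sampled without replacement
    with the given seed; iteration stops when the largest membership change
    drops below ``tol``.  The objective sum_{g,c} u^m d^2 is tracked and is
    non-increasing across iterations.
    """
    X = profiles.values if isinstance(profiles, TemporalProfileMatrix) else np.asarray(profiles, float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite profile values")
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, {n} profiles]")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if k == 1:
        U = np.ones((n, 1))
        C = X.mean(axis=0, keepdims=True)
        obj = float(((X - C) ** 2).sum())
        return FuzzyClusterResult(U, C, m, 1, True, 0, (obj,))

    rng = np.random.default_rng(seed)
    C = X[rng.choice(n, size=k, replace=False)].copy()
    U = _memberships(X, C, m)
    objective = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = U**m
        C = (W.T @ X) / W.sum(axis=0)[:, None]
        U_new = _memberships(X, C, m)
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        objective.append(float((U_new**m * d2).sum()))
        delta = np.abs(U_new - U).max()
        U = U_new
        if delta < tol:
            converged = True
            break
    return FuzzyClusterResult(U, C, m, k, converged, it, tuple(objective))


def estimate_fuzzifier(profiles: TemporalProfileMatrix | np.ndarray) -> float:
    """Data-driven fuzzifier from the dataset dimensions.

    Uses the Schwaemmle–Jensen relation between the minimal fuzzifier and
    (number of profiles N, dimensionality D), clipped to (1, 5].  The result
    is deterministic in the input shape.
    """
    X = profiles.values if isinstance(profiles, TemporalProfileMatrix) else np.asarray(profiles, float)
    N, D = X.shape
    if N < 2 or D < 2:
        raise ValueError("fuzzifier estimation needs >= 2 profiles and >= 2 time points")
    m = 1.0 + (1418.0 / N + 22.05) * D ** (-2.0) \
        + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)
    return float(min(max(m, 1.0 + 1e-6), 5.0))


def select_k(
    profiles: TemporalProfileMatrix | np.ndarray,
    k_range: tuple[int, int],
    m: float = 2.0,
    seed: int = 0,
) -> int:
    """Pick k at the elbow of minimum-centroid-distance vs k.

    The minimum pairwise centroid distance collapses once k exceeds the
    number of genuine profile groups (two centroids land in the same
    group), so the k with the largest drop ratio d(k)/d(k+1) is returned.
    Deterministic given the seed.
    """
    X = profiles.values if isinstance(profiles, TemporalProfileMatrix) else np.asarray(profiles, float)
    lo, hi = int(k_range[0]), int(k_range[1])
    if lo > hi:
        raise ValueError("empty k range")
    if lo < 2 or hi > X.shape[0] - 1:
        raise ValueError(f"k range [{lo}, {hi}] outside [2, {X.shape[0] - 1}]")
    if lo == hi:
        return lo
    dmin = {}
    for k in range(lo, hi + 1):
        C = fuzzy_cmeans(X, k, m=m, seed=seed).centroids
        d = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(axis=2))
        dmin[k] = float(d[np.triu_indices(k, 1)].min())
    # additive floor keeps the ratio meaningful once distances collapse
    # toward zero (beyond the true k, successive minima are all near zero)
    eps = 0.01 * max(dmin.values()) if max(dmin.values()) > 0 else 1.0
    best_k, best_r = lo, -np.inf
    for k in range(lo, hi):
        r = (dmin[k] + eps) / (dmin[k + 1] + eps)
        if r > best_r:
            best_r, best_k = r, k
    return best_k
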