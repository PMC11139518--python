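"""Unsupervised structure of the samples: PCA, hierarchical clustering on
principal components (HCPC), and the two heatmap matrices (sample-sample
correlations and gene-scaled expression).  Everything is returned as
plot-ready arrays/tables; no rendering happens here.

Samples are the observations throughout: PCA is run on the samples x genes
orientation of the log matrix, and HCPC applies Ward agglomeration to the
leading principal-component coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.cluster.vq import kmeans2
from scipy.stats import rankdata

__all__ = [
    "PCAResult",
    "HCPCResult",
    "run_pca",
    "run_hcpc",
    "correlation_matrix",
    "scaled_expression_matrix",
]


@dataclass
class PCAResult:
    """Scores (samples x K), loadings (genes x K), explained-variance
    fractions, plus the centering/scaling vectors needed to reconstruct the
    preprocessed input from all components."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    kept_gene_idx: np.ndarray  # genes retained (constant genes dropped when scaling)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class HCPCResult:
    k: int
    labels: np.ndarray            # per-sample cluster labels in 1..k
    linkage_matrix: np.ndarray    # scipy linkage semantics


def run_pca(
    log_matrix: np.ndarray,
    center: bool = True,
    scale: bool = True,
    K: int | None = None,
) -> PCAResult:
    """PCA of samples via SVD of the centered (optionally scaled) matrix.

    ``log_matrix`` is genes x samples.  Constant genes are dropped with a
    warning when ``scale`` is requested.  Deterministic sign convention:
    each loading vector is oriented so its largest-magnitude entry is
    positive.
    """
    X = np.asarray(log_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("log_matrix must be 2-D (genes x samples)")
    G, S = X.shape
    sd = X.std(axis=1, ddof=1) if S > 1 else np.zeros(G)
    kept = np.arange(G)
    if scale:
        const = sd == 0
        if const.all():
            raise ValueError("no variance: all genes are constant")
        if const.any():
            warnings.warn(f"dropping {int(const.sum())} constant gene(s) before scaling")
            kept = np.flatnonzero(~const)
            X = X[kept]
            sd = sd[kept]
    elif (sd == 0).all() and center:
        raise ValueError("no variance: all genes are constant")

    Y = X.T  # samples x genes
    mu = Y.mean(axis=0) if center else np.zeros(Y.shape[1])
    sc = sd if scale else np.ones(Y.shape[1])
    Z = (Y - mu) / np.where(sc == 0, 1.0, sc)

    max_k = min(Z.shape)
    if K is None:
        K = max_k
    if K > max_k:
        raise ValueError(f"K={K} exceeds min(genes, samples)={max_k}")

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    total_var = float(np.sum(s**2))
    if total_var == 0:
        raise ValueError("no variance: all genes are constant")
    # sign convention: dominant loading entry positive
    for j in range(len(s)):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :K] * s[:K]
    loadings = Vt[:K].T
    evf = (s[:K] ** 2) / total_var
    return PCAResult(scores, loadings, evf, mu, sc, kept)


def _auto_k(Z: np.ndarray, k_max: int) -> int:
    """Pick k maximizing the relative loss of within-cluster inertia between
    consecutive cuts: for Ward linkage the merge heights are the inertia
    increments, so the cut before the largest jump (max height ratio
    h(k)/h(k+1)) is chosen, k in [2, k_max]."""
    heights = Z[:, 2]
    n = Z.shape[0] + 1

    def h(k: int) -> float:  # cost of merging from k clusters to k-1
        return float(heights[n - k])

    best_k, best_q = 2, -np.inf
    for k in range(2, k_max + 1):
        denom = h(k + 1) if k + 1 <= n - 1 else None
        if denom is None:
            continue
        q = np.inf if denom == 0 else h(k) / denom
        if q > best_q:
            best_q, best_k = q, k
    return best_k


def run_hcpc(
    pca: PCAResult,
    k: int | str = "auto",
    n_components: int | None = None,
    consolidate: bool = False,
    seed: int = 0,
) -> HCPCResult:
    """Ward-linkage agglomeration of samples on leading PC coordinates.

    ``k="auto"`` selects the cut maximizing the relative within-inertia loss
    between consecutive k in [2, min(10, S-1)].  Optional consolidation
    refines the cut with k-means started from the cluster means (off by
    default).
    """
    if n_components is None:
        n_components = pca.n_components
    if n_components > pca.n_components:
        raise ValueError("n_components exceeds the number of PCA components")
    X = pca.scores[:, :n_components]
    S = X.shape[0]
    if S < 2:
        raise ValueError("HCPC needs at least 2 samples")
    Z = linkage(X, method="ward")
    if k == "auto":
        k_sel = _auto_k(Z, min(10, S - 1))
    else:
        k_sel = int(k)
        if k_sel < 1 or k_sel > S:
            raise ValueError(f"k={k_sel} outside [1, {S}]")
    labels = fcluster(Z, t=k_sel, criterion="maxclust") if k_sel > 1 else np.ones(S, int)
    if consolidate and 1 < k_sel < S:
        centers = np.vstack([X[labels == c].mean(axis=0) for c in range(1, k_sel + 1)])
        _, new = kmeans2(X, centers, minit="matrix", seed=seed)
        labels = new + 1
    return HCPCResult(k_sel, np.asarray(labels), Z)


def correlation_matrix(log_matrix: np.ndarray, method: str = "pearson") -> np.ndarray:
    """Sample-sample correlation matrix (symmetric, unit diagonal)."""
    X = np.asarray(log_matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("correlation needs at least 2 genes")
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 0, X)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = X.std(axis=0)
    if (sd == 0).any():
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance sample at column {j}: correlation undefined")
    C = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def scaled_expression_matrix(log_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardized expression (each gene: mean 0, sd 1 with the n-1
    denominator).  Returns (scaled matrix, indices of retained genes);
    constant genes are dropped with a warning."""
    X = np.asarray(log_matrix, dtype=float)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes constant: nothing to scale")
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} constant gene(s) from scaled matrix")
    Xk = X[keep]
    out = (Xk - Xk.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return out, np.flatnonzero(keep)
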