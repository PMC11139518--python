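"""Median-of-ratios size-factor normalization.

Library-size differences between samples are corrected with the classical
median-of-ratios estimator: a pseudo-reference sample is built from the
per-gene geometric mean across samples (genes containing any zero are
excluded, so the reference lives strictly in positive space), and each
sample's size factor is the median of its count ratios to that reference.
Normalized counts are raw counts divided by the sample's size factor;
downstream exploratory analyses work on ``log2(normalized + pseudocount)``.
"""

from __future__ import annotations

import numpy as np

from .design import CountMatrix

__all__ = ["size_factors", "normalize", "log_transform", "NormalizationError"]


class NormalizationError(ValueError):
    pass


def _as_array(counts) -> np.ndarray:
    if isinstance(counts, CountMatrix):
        return counts.counts
    return np.asarray(counts)


def size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Per-sample median-of-ratios size factors.

    For sample j: ``sf_j = median_g counts[g, j] / geomean_g`` over genes g
    with strictly positive counts in every sample.  Median of an even number
    of ratios is the midpoint of the two central values.
    """
    x = _as_array(counts).astype(float)
    if x.ndim != 2:
        raise NormalizationError("counts must be a 2-D genes x samples matrix")
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise NormalizationError(
            "size factors undefined: no gene has strictly positive counts "
            "in every sample"
        )
    ref = x[all_positive]
    geomean = np.exp(np.mean(np.log(ref), axis=1))
    ratios = ref / geomean[:, None]
    return np.median(ratios, axis=0)


def normalize(counts: CountMatrix | np.ndarray, sf: np.ndarray) -> np.ndarray:
    """Divide each sample column by its size factor."""
    x = _as_array(counts).astype(float)
    sf = np.asarray(sf, dtype=float)
    if sf.ndim != 1 or sf.shape[0] != x.shape[1]:
        raise NormalizationError(
            f"size factor length {sf.shape} does not match {x.shape[1]} samples"
        )
    if (sf <= 0).any():
        raise NormalizationError("size factors must be strictly positive")
    return x / sf[None, :]


def log_transform(normed: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """``log2(value + pseudocount)`` elementwise; monotone in the input."""
    x = np.asarray(normed, dtype=float)
    if pseudocount <= 0:
        raise NormalizationError("pseudocount must be positive")
    if (x < 0).any():
        raise NormalizationError("log transform input must be non-negative")
    return np.log2(x + pseudocount)
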