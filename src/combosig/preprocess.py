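"""Array preprocessing: background subtraction, quantile normalization,
log transform, additive batch centering, and PCA for design QC.

The intended order mirrors standard bead-array practice: per-sample
background subtraction on raw intensities, quantile normalization across
samples, log2 transform with a pseudo-offset, then per-gene batch
mean-centering on the log scale.  PCA (SVD on gene-centered data, no gene
scaling) is exposed to verify that samples group by treatment and that the
batch signal is gone after centering.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from dataclasses import dataclass

from .formats import ExpressionMatrix, FormatError, SampleAnnotation

__all__ = [
    "EPSILON",
    "background_subtract",
    "quantile_normalize",
    "log2_with_offset",
    "batch_center",
    "pca",
    "PCAResult",
]

#: positive floor applied after background subtraction (intensity units)
EPSILON = 1.0


def _require_scale(matrix: ExpressionMatrix, scale: str, op: str) -> None:
    if matrix.scale != scale:
        raise FormatError(f"{op} requires a {scale} matrix, got {matrix.scale}")


def background_subtract(matrix: ExpressionMatrix, percentile: float = 5.0) -> ExpressionMatrix:
    """Subtract each sample's given intensity percentile, flooring at EPSILON.

    The percentile acts as a per-sample background estimate; values that fall
    at or below it clamp to the floor rather than going non-positive.
    """
    _require_scale(matrix, "raw_intensity", "background_subtract")
    if not 0 <= percentile < 50:
        raise ValueError("background percentile must satisfy 0 <= p < 50")
    X = matrix.values
    bg = np.percentile(X, percentile, axis=0)
    out = np.maximum(X - bg[None, :], EPSILON)
    return matrix.with_values(out)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean empirical distribution.

    After normalization each column's sorted values equal the across-column
    mean of sorted values; ties within a column receive the mean of the
    reference values their rank span covers, so the map is well defined and
    idempotent.  A single-sample matrix is returned unchanged with a warning.
    """
    X = matrix.values
    n_genes, n_samples = X.shape
    if n_samples < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return matrix.with_values(X.copy())
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        uniq, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        # ranks the k-th unique value spans: [start_k, start_k + count_k)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        csum = np.concatenate([[0.0], np.cumsum(ref)])
        group_means = (csum[starts + counts] - csum[starts]) / counts
        out[:, j] = group_means[inverse]
    return matrix.with_values(out)


def log2_with_offset(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """value <- log2(value + offset); flips the scale flag to log2."""
    _require_scale(matrix, "raw_intensity", "log2_with_offset")
    if offset <= 0:
        raise ValueError("offset must be positive")
    return matrix.with_values(np.log2(matrix.values + offset), scale="log2")


def batch_center(matrix: ExpressionMatrix, annotation: SampleAnnotation) -> ExpressionMatrix:
    """Remove an additive per-gene batch shift by batch mean-centering.

    Per gene and batch the batch mean is subtracted and the gene's grand mean
    added back, so gene-level means are preserved.  Refuses designs where a
    batch is confounded 1:1 with a treatment arm (the batch term would absorb
    the arm effect).
    """
    annotation.check_pairing(matrix)
    batch = annotation.batch_of().reindex(matrix.sample_ids)
    arm = annotation.arm_of().reindex(matrix.sample_ids)
    for b in batch.unique():
        arms_in_b = set(arm[batch == b])
        if len(arms_in_b) == 1:
            (only_arm,) = arms_in_b
            if set(batch[arm == only_arm]) == {b}:
                raise ValueError(
                    f"batch {b!r} is confounded 1:1 with arm {only_arm!r}; "
                    "batch centering would remove the arm effect"
                )
    X = matrix.values.astype(float)
    grand = X.mean(axis=1, keepdims=True)
    out = X.copy()
    codes = batch.to_numpy()
    for b in np.unique(codes):
        cols = codes == b
        out[:, cols] += grand - X[:, cols].mean(axis=1, keepdims=True)
    return matrix.with_values(out)


@dataclass
class PCAResult:
    """SVD-based PCA on gene-centered data.

    ``loadings`` is genes × k (orthonormal columns), ``coordinates`` is
    samples × k, ``explained_variance_ratio`` the non-increasing per-component
    variance fractions.  Component signs are fixed by making each loading's
    largest-magnitude entry positive.
    """

    loadings: pd.DataFrame
    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca(matrix: ExpressionMatrix, k: int) -> PCAResult:
    X = matrix.values
    n_genes, n_samples = X.shape
    if k < 1 or k > min(n_genes, n_samples - 1):
        raise ValueError(f"k must satisfy 1 <= k <= min(genes, samples-1) = "
                         f"{min(n_genes, n_samples - 1)}")
    centered = X - X.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    total = float((S**2).sum())
    evr = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    load = U[:, :k]
    coords = (S[:k][None, :] * Vt[:k, :].T)
    for c in range(k):
        pivot = np.argmax(np.abs(load[:, c]))
        if load[pivot, c] < 0:
            load[:, c] = -load[:, c]
            coords[:, c] = -coords[:, c]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        loadings=pd.DataFrame(load, index=matrix.gene_ids, columns=comp_names),
        coordinates=pd.DataFrame(coords, index=matrix.sample_ids, columns=comp_names),
        explained_variance_ratio=evr,
    )
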