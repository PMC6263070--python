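"""Hierarchical clustering of genes or samples.

Defaults follow expression-heatmap convention: 1 − Pearson correlation as
the distance and average linkage, both configurable.  "Supervised"
clustering of a gene set (cluster samples on a set-restricted matrix) is
composed from :meth:`combosig.formats.ExpressionMatrix.subset_genes` plus
these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .formats import ExpressionMatrix

__all__ = ["ClusterTree", "correlation_distance", "euclidean_distance",
           "hierarchical_cluster", "cut_tree"]

LINKAGES = ("average", "complete", "single", "ward")


@dataclass
class ClusterTree:
    """Agglomerative merge history (scipy linkage encoding) plus leaf labels."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaves: list[str]
    linkage: str
    distance: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def merge_table(self) -> pd.DataFrame:
        """Merge history as a table sufficient to redraw the dendrogram."""
        return pd.DataFrame(
            self.merges, columns=["node_a", "node_b", "height", "n_members"]
        )


def _items(matrix: ExpressionMatrix, axis: str) -> tuple[np.ndarray, list[str]]:
    if axis == "genes":
        return matrix.values, matrix.gene_ids
    if axis == "samples":
        return matrix.values.T, matrix.sample_ids
    raise ValueError("axis must be 'genes' or 'samples'")


def correlation_distance(matrix: ExpressionMatrix, axis: str = "samples") -> pd.DataFrame:
    """d(i, j) = 1 − Pearson(i, j); symmetric, zero diagonal, range [0, 2]."""
    X, labels = _items(matrix, axis)
    if X.shape[0] < 2:
        raise ValueError(f"need >= 2 {axis} to compute distances")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance item(s) on axis {axis!r}: {', '.join(bad[:10])}")
    D = 1.0 - np.corrcoef(X)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=labels, columns=labels)


def euclidean_distance(matrix: ExpressionMatrix, axis: str = "samples") -> pd.DataFrame:
    X, labels = _items(matrix, axis)
    if X.shape[0] < 2:
        raise ValueError(f"need >= 2 {axis} to compute distances")
    sq = (X**2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    D = np.sqrt(np.clip(D2, 0.0, None))
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=labels, columns=labels)


def hierarchical_cluster(
    distances: pd.DataFrame,
    linkage: str = "average",
    distance_name: str = "correlation",
) -> ClusterTree:
    """Agglomerative clustering of a precomputed symmetric distance matrix."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    D = distances.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(
        merges=Z, leaves=list(distances.index), linkage=linkage, distance=distance_name
    )


def cut_tree(tree: ClusterTree, k: int) -> pd.Series:
    """Cut into exactly k flat clusters; labels are integers 1..k."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= {n}")
    labels = hierarchy.fcluster(tree.merges, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        # maxclust can undershoot on exactly tied heights; fall back to cutting
        # the merge history directly
        labels = hierarchy.cut_tree(tree.merges, n_clusters=k).ravel() + 1
    return pd.Series(labels, index=tree.leaves, name="cluster")
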