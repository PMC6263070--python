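"""Cohort immune-infiltration analysis.

A *module score* is the per-sample mean of z-scored expression over a gene
set; an *immune score* is the module score of a core immune gene set, an
*IFN score* that of an interferon set.  Cohorts are stratified into ordered
low/medium/high infiltration groups by clustering samples on the
immune-set-restricted matrix, and the association between a target module
and the immune score is tested against a gene-wise permutation null built by
re-drawing random same-size gene sets (an alternative sample-permutation
null is available behind ``unit="samples"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bonferroni_pairwise_t, oneway_f
from .formats import ExpressionMatrix
from .unsupervised import correlation_distance, cut_tree, euclidean_distance, hierarchical_cluster

__all__ = [
    "module_score",
    "stratify_infiltration",
    "score_group_tests",
    "spearman",
    "genewise_permutation_test",
    "PermutationResult",
    "GroupTestResult",
]

GROUP_ORDER_3 = ("low", "medium", "high")


def _zscore_rows(X: np.ndarray, gene_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    """Gene-wise z-scores across samples; zero-variance genes are dropped."""
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [gene_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene(s): {', '.join(dropped[:5])}"
            + ("..." if len(dropped) > 5 else "")
        )
    if not keep.any():
        raise ValueError("all member genes have zero variance; module score undefined")
    Xk = X[keep]
    z = (Xk - Xk.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return z, [g for g, k in zip(gene_ids, keep) if k]


def module_score(matrix: ExpressionMatrix, members: Iterable[str]) -> pd.Series:
    """Mean z-score of member genes, per sample (mean across samples ≈ 0)."""
    if matrix.shape[1] < 2:
        raise ValueError("module_score needs >= 2 samples")
    present = [g for g in members if g in matrix.frame.index]
    if not present:
        raise ValueError("gene set does not intersect the matrix")
    sub = matrix.frame.loc[present]
    z, _ = _zscore_rows(sub.to_numpy(), present)
    return pd.Series(z.mean(axis=0), index=matrix.sample_ids, name="module_score")


def stratify_infiltration(
    matrix: ExpressionMatrix,
    immune_core_set: Iterable[str],
    k: int = 3,
    linkage: str = "ward",
    distance: str = "euclidean",
) -> pd.Series:
    """Cluster samples on the immune-restricted matrix into k ordered groups.

    Groups are relabeled by ascending mean immune score; for k=3 the labels
    are low/medium/high, otherwise g1..gk.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > matrix.shape[1]:
        raise ValueError("k exceeds the number of samples")
    members = [g for g in immune_core_set if g in matrix.frame.index]
    if not members:
        raise ValueError("immune core set does not intersect the matrix")
    restricted = matrix.subset_genes(members)
    if distance == "euclidean":
        D = euclidean_distance(restricted, axis="samples")
    elif distance == "correlation":
        D = correlation_distance(restricted, axis="samples")
    else:
        raise ValueError("distance must be 'euclidean' or 'correlation'")
    tree = hierarchical_cluster(D, linkage=linkage, distance_name=distance)
    raw = cut_tree(tree, k)
    score = module_score(matrix, members)
    means = score.groupby(raw).mean().sort_values()
    names = GROUP_ORDER_3 if k == 3 else tuple(f"g{i + 1}" for i in range(k))
    mapping = {cluster: names[rank] for rank, cluster in enumerate(means.index)}
    labels = raw.map(mapping)
    return pd.Series(
        pd.Categorical(labels, categories=list(names), ordered=True),
        index=raw.index,
        name="infiltration_group",
    )


@dataclass
class GroupTestResult:
    """One-way ANOVA across groups plus Bonferroni-adjusted pairwise t tests."""

    f: float
    p: float
    pairwise: pd.DataFrame


def score_group_tests(scores: pd.Series, groups: pd.Series) -> GroupTestResult:
    scores, groups = scores.align(groups, join="inner")
    by_group = {str(g): scores[groups == g].to_numpy() for g in pd.unique(groups.dropna())}
    if len(by_group) < 2:
        raise ValueError("need >= 2 groups")
    if any(v.size < 2 for v in by_group.values()):
        small = [g for g, v in by_group.items() if v.size < 2]
        raise ValueError(f"singleton group(s): {', '.join(small)}")
    f, p = oneway_f(list(by_group.values()))
    pairwise = pd.DataFrame(bonferroni_pairwise_t(by_group))
    return GroupTestResult(f=f, p=p, pairwise=pairwise)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class PermutationResult:
    rho: float
    p: float
    n_perm: int
    sided: str
    unit: str

    def __post_init__(self) -> None:
        lo = 1.0 / (self.n_perm + 1)
        if not lo - 1e-12 <= self.p <= 1.0 + 1e-12:
            raise ValueError("permutation p outside [1/(n_perm+1), 1]")


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return stats.rankdata(X, axis=1)


def genewise_permutation_test(
    matrix: ExpressionMatrix,
    target_set: Iterable[str],
    immune_score: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    sided: str = "greater",
    exclude: Iterable[str] = (),
    unit: str = "genes",
) -> PermutationResult:
    """Association of a target module score with the immune score, against a
    gene-wise permutation null.

    The observed statistic is Spearman's rho between
    ``module_score(target_set)`` and ``immune_score``.  With
    ``unit="genes"`` (default) the null re-draws ``n_perm`` random gene sets
    of the same size from the background universe (all genes minus
    ``exclude``, normally the immune core set) and recomputes rho; with
    ``unit="samples"`` it permutes the immune score across samples instead.
    The add-one estimate ``p = (1 + #{null >= observed}) / (n_perm + 1)``
    never reports zero; at n_perm = 10,000 the smallest reportable p is
    1/10,001 < 0.001.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if sided not in ("greater", "less", "two-sided"):
        raise ValueError("sided must be 'greater', 'less' or 'two-sided'")
    if unit not in ("genes", "samples"):
        raise ValueError("unit must be 'genes' or 'samples'")
    immune_score = immune_score.reindex(matrix.sample_ids)
    if immune_score.isna().any():
        raise ValueError("immune_score must cover every sample in the matrix")
    target = [g for g in target_set if g in matrix.frame.index]
    if not target:
        raise ValueError("target set does not intersect the matrix")
    obs_score = module_score(matrix, target)
    rho_obs, _ = spearman(obs_score.to_numpy(), immune_score.to_numpy())

    rng = np.random.default_rng(seed)
    iy = stats.rankdata(immune_score.to_numpy())
    iy_c = iy - iy.mean()
    iy_norm = np.sqrt((iy_c**2).sum())

    if unit == "samples":
        null = np.empty(n_perm)
        x = obs_score.to_numpy()
        for i in range(n_perm):
            perm = rng.permutation(x.size)
            null[i] = spearman(x, immune_score.to_numpy()[perm])[0]
    else:
        excluded = set(exclude)
        background = [g for g in matrix.gene_ids if g not in excluded]
        Xb = matrix.frame.loc[background].to_numpy()
        sd = Xb.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn("dropping zero-variance background gene(s) from the null")
        Xb, sd = Xb[keep], sd[keep]
        m = len(target)
        if Xb.shape[0] < m:
            raise ValueError(
                f"background ({Xb.shape[0]} genes) smaller than target set ({m})"
            )
        Z = (Xb - Xb.mean(axis=1, keepdims=True)) / sd[:, None]
        null = np.empty(n_perm)
        chunk = max(1, int(5e6 // max(matrix.shape[1] * m, 1)))
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            keys = rng.random((b, Z.shape[0]))
            idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
            null_scores = Z[idx.ravel()].reshape(b, m, -1).mean(axis=1)
            rx = _rank_rows(null_scores)
            rx_c = rx - rx.mean(axis=1, keepdims=True)
            denom = np.sqrt((rx_c**2).sum(axis=1)) * iy_norm
            null[done : done + b] = (rx_c @ iy_c) / denom
            done += b

    tol = 1e-12
    if sided == "greater":
        exceed = int((null >= rho_obs - tol).sum())
    elif sided == "less":
        exceed = int((null <= rho_obs + tol).sum())
    else:
        exceed = int((np.abs(null) >= abs(rho_obs) - tol).sum())
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(rho=rho_obs, p=p, n_perm=n_perm, sided=sided, unit=unit)
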