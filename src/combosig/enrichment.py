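"""Per-sample gene-set enrichment scoring and preranked set testing.

The scorer is an unweighted Kolmogorov–Smirnov running-sum statistic: rank a
sample's genes by descending expression, walk the ranking adding
``+1/|S ∩ U|`` at set members and ``−1/|U ∖ S|`` elsewhere, and report the
running sum's maximum-magnitude deviation with its sign.  It is a deliberate,
documented simplification of kernel-based per-sample enrichment methods
(e.g. GSVA): scores depend only on within-sample ranks, lie in [−1, 1], and
are invariant to any strictly monotone transform of a sample's expression.
Numeric parity with the published GSVA package is explicitly not claimed.

When the maximum positive and maximum negative deviations tie in magnitude,
the one reached earliest in the ranking wins; this keeps the complement
antisymmetry score(S) = −score(U∖S) exact at balanced set sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import oneway_f
from .diffexpr import bh_fdr
from .formats import ExpressionMatrix, GeneSetCollection, SampleAnnotation

__all__ = [
    "EnrichmentProfile",
    "sample_enrichment_score",
    "enrichment_matrix",
    "groupwise_anova",
    "preranked_enrichment",
]


def _running_score(member_in_rank_order: np.ndarray) -> float:
    """Signed max-magnitude deviation of the KS running sum.

    ``member_in_rank_order`` is a boolean mask over the ranked universe.
    """
    n = member_in_rank_order.size
    nm = int(member_in_rank_order.sum())
    nb = n - nm
    if nm == 0:
        raise ValueError("gene set does not intersect the universe")
    if nb == 0:
        raise ValueError("gene set equals the universe")
    steps = np.where(member_in_rank_order, 1.0 / nm, -1.0 / nb)
    cs = np.cumsum(steps)
    return float(cs[np.argmax(np.abs(cs))])


def _null_magnitudes(positions: np.ndarray, n: int, nm: int) -> np.ndarray:
    """|max-deviation| for many random member-position draws at once.

    ``positions`` is (n_draws, nm), each row the (unsorted) 0-based ranks of
    a drawn member set.  The running sum attains its maximum at a member
    position and its minimum just before one, so only 2·nm candidates per
    draw need evaluating.
    """
    nb = n - nm
    pos = np.sort(positions, axis=1)
    k = np.arange(1, nm + 1)[None, :]
    at_member = k / nm - (pos + 1 - k) / nb
    before_member = (k - 1) / nm - (pos - (k - 1)) / nb
    return np.maximum(at_member.max(axis=1), -before_member.min(axis=1))


def _rank_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices ordering genes by descending value, ties by gene id."""
    return np.lexsort((gene_ids, -values))


def sample_enrichment_score(
    values: Sequence[float] | pd.Series,
    gene_ids: Sequence[str] | None = None,
    members: Iterable[str] = (),
) -> float:
    """Enrichment of ``members`` in one sample's expression ranking.

    ``values`` may be a Series indexed by gene id, or an array accompanied by
    ``gene_ids``.  Score 1 means every member sits at the very top of the
    ranking; −1 the very bottom.
    """
    if isinstance(values, pd.Series):
        gene_ids = np.asarray(values.index, dtype=str)
        vals = values.to_numpy(dtype=float)
    else:
        if gene_ids is None:
            raise ValueError("gene_ids required when values is not a Series")
        gene_ids = np.asarray(gene_ids, dtype=str)
        vals = np.asarray(values, dtype=float)
    member_set = set(members)
    order = _rank_order(vals, gene_ids)
    mask = np.fromiter((g in member_set for g in gene_ids[order]), bool, len(gene_ids))
    return _running_score(mask)


@dataclass
class EnrichmentProfile:
    """Gene-set × sample score matrix plus optional per-set group statistics."""

    scores: pd.DataFrame
    stats: pd.DataFrame | None = None


def enrichment_matrix(
    matrix: ExpressionMatrix, genesets: GeneSetCollection
) -> EnrichmentProfile:
    """Score every set in every sample (rows = sets, columns = samples)."""
    gene_ids = np.asarray(matrix.gene_ids, dtype=str)
    id_to_row = {g: i for i, g in enumerate(gene_ids)}
    X = matrix.values
    n_genes, n_samples = X.shape
    member_masks = {}
    for name, _, members in genesets:
        mask = np.zeros(n_genes, dtype=bool)
        rows = [id_to_row[g] for g in members if g in id_to_row]
        mask[rows] = True
        member_masks[name] = mask
    out = np.empty((len(genesets), n_samples))
    for j in range(n_samples):
        order = _rank_order(X[:, j], gene_ids)
        for i, name in enumerate(genesets.names):
            out[i, j] = _running_score(member_masks[name][order])
    scores = pd.DataFrame(out, index=genesets.names, columns=matrix.sample_ids)
    return EnrichmentProfile(scores=scores)


def groupwise_anova(
    profile: EnrichmentProfile, annotation: SampleAnnotation
) -> pd.DataFrame:
    """One-way across-arm ANOVA per gene set, BH-adjusted across sets."""
    arms = annotation.arms
    if len(arms) < 2:
        raise ValueError("need >= 2 arms")
    arm_cols = {a: annotation.samples_in_arm(a) for a in arms}
    if any(len(c) < 2 for c in arm_cols.values()):
        raise ValueError("need >= 2 samples per arm")
    rows = []
    for name in profile.scores.index:
        groups = [profile.scores.loc[name, cols].to_numpy() for cols in arm_cols.values()]
        f, p = oneway_f(groups)
        rows.append({"set": name, "F": f, "p": p})
    stats_frame = pd.DataFrame(rows).set_index("set")
    stats_frame["q"] = bh_fdr(np.clip(stats_frame["p"].to_numpy(), np.finfo(float).tiny, 1.0))
    profile.stats = stats_frame
    return stats_frame


def preranked_enrichment(
    gene_ids: Sequence[str],
    scores: Sequence[float],
    members: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Enrichment of ``members`` in an externally ranked gene list.

    ``gene_ids``/``scores`` define a strictly decreasing ranking (e.g. a
    combination signature's fold changes).  The null redraws ``n_perm``
    random same-size member sets from the list; the two-sided permutation
    p-value is ``(1 + #{|null| >= |observed|}) / (n_perm + 1)``, with the
    direction read from the observed score's sign.
    """
    gene_ids = np.asarray(gene_ids, dtype=str)
    scores = np.asarray(scores, dtype=float)
    if gene_ids.size != scores.size:
        raise ValueError("gene_ids and scores must have equal length")
    if np.any(np.diff(scores) >= 0):
        raise ValueError("scores must be strictly decreasing (a strict ranking)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    member_set = set(members)
    if len(member_set) > gene_ids.size:
        raise ValueError("gene set larger than the ranked list")
    mask = np.fromiter((g in member_set for g in gene_ids), bool, gene_ids.size)
    observed = _running_score(mask)
    n, nm = gene_ids.size, int(mask.sum())
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_perm, int(2e6 // max(n, 1))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n))
        positions = np.argpartition(keys, nm - 1, axis=1)[:, :nm]
        mags = _null_magnitudes(positions, n, nm)
        exceed += int((mags >= abs(observed) - 1e-12).sum())
        done += b
    p = (1 + exceed) / (n_perm + 1)
    return observed, p
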