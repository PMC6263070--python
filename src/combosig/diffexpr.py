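"""Gene-wise contrasts, multiple-testing control, and signature derivation.

The test statistic is a variance-shrinkage moderated t: each gene's pooled
variance is shrunk toward the across-gene mean variance with weight
``d0 / (d0 + df)`` (prior degrees of freedom ``d0``, default 4), and the
p-value uses ``df + d0`` degrees of freedom.  Replicate counts in treatment
screens are small enough that ordinary per-gene t statistics are dominated by
unstable variance estimates; borrowing strength across genes stabilizes them.

Signatures follow the usual double-threshold rule (fold change and BH-FDR);
a *synergy* set contains genes that pass the thresholds against **both**
single agents of a combination with a consistent direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats import ExpressionMatrix, SampleAnnotation

__all__ = [
    "DEResult",
    "Signature",
    "gene_stats",
    "bh_fdr",
    "derive_signature",
    "synergy_set",
    "top_fraction_genes",
]


@dataclass
class DEResult:
    """Per-gene statistics for one two-arm contrast (armA vs armB).

    ``table`` columns: log2fc (mean armA − mean armB), t, p, q.
    """

    table: pd.DataFrame
    arm_a: str
    arm_b: str

    @property
    def contrast(self) -> str:
        return f"{self.arm_a}_vs_{self.arm_b}"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class Signature:
    """Thresholded up/down gene sets for one contrast."""

    contrast: str
    up: tuple[str, ...]
    down: tuple[str, ...]
    fc_threshold: float
    fdr_threshold: float

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down sets must be disjoint")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.up + self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q(i) = min_{j >= i} p(j) * m / j over the sorted p-values, mapped back to
    the input order.  Requires every p in (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def gene_stats(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    arm_a: str,
    arm_b: str,
    d0: float = 4.0,
) -> DEResult:
    """Moderated-t contrast of arm_a vs arm_b on a log2 matrix.

    log2FC is the difference of arm means; the pooled per-gene variance is
    shrunk toward the across-gene mean variance before forming t.
    """
    if matrix.scale != "log2":
        raise ValueError("gene_stats requires a log2-scale matrix")
    if d0 < 0:
        raise ValueError("d0 must be non-negative")
    annotation.check_pairing(matrix)
    cols_a = annotation.samples_in_arm(arm_a)
    cols_b = annotation.samples_in_arm(arm_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"need >= 2 samples per arm; got {len(cols_a)} in {arm_a!r}, "
            f"{len(cols_b)} in {arm_b!r}"
        )
    A = matrix.frame[cols_a].to_numpy()
    B = matrix.frame[cols_b].to_numpy()
    na, nb = A.shape[1], B.shape[1]
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    lfc = mean_a - mean_b
    ss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + ((B - mean_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    s2 = ss / df
    s2_bar = s2.mean()
    s2_mod = (d0 * s2_bar + df * s2) / (d0 + df)
    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df + d0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {"log2fc": lfc, "t": t, "p": p, "q": bh_fdr(p)}, index=matrix.gene_ids
    )
    return DEResult(table=table, arm_a=arm_a, arm_b=arm_b)


def derive_signature(
    de: DEResult, fc_threshold: float = 2.0, fdr_threshold: float = 0.05
) -> Signature:
    """Double-threshold signature: |fold change| >= fc_threshold (linear
    scale) and q <= fdr_threshold."""
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    lg = math.log2(fc_threshold)
    tab = de.table
    passed = tab["q"] <= fdr_threshold
    up = tuple(tab.index[passed & (tab["log2fc"] >= lg)])
    down = tuple(tab.index[passed & (tab["log2fc"] <= -lg)])
    return Signature(de.contrast, up, down, fc_threshold, fdr_threshold)


def synergy_set(
    de_vs_single_a: DEResult,
    de_vs_single_b: DEResult,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    mode: str = "intersection",
) -> Signature:
    """Genes a combination regulates beyond both of its single agents.

    A gene qualifies iff it passes the signature thresholds in BOTH
    combination-vs-single contrasts with the same direction (``mode=
    "intersection"``, the conservative default); ``mode="union"`` admits
    genes passing either contrast, still excluding direction conflicts.
    """
    if de_vs_single_a.gene_ids != de_vs_single_b.gene_ids:
        raise ValueError("contrasts must share an identical gene universe")
    if de_vs_single_a.arm_a != de_vs_single_b.arm_a:
        raise ValueError(
            "both contrasts must compare the same combination arm "
            f"({de_vs_single_a.arm_a!r} vs {de_vs_single_b.arm_a!r})"
        )
    if mode not in ("intersection", "union"):
        raise ValueError("mode must be 'intersection' or 'union'")
    sig_a = derive_signature(de_vs_single_a, fc_threshold, fdr_threshold)
    sig_b = derive_signature(de_vs_single_b, fc_threshold, fdr_threshold)
    up_a, dn_a = set(sig_a.up), set(sig_a.down)
    up_b, dn_b = set(sig_b.up), set(sig_b.down)
    if mode == "intersection":
        up = up_a & up_b
        down = dn_a & dn_b
    else:
        up = (up_a | up_b) - (dn_a | dn_b)
        down = (dn_a | dn_b) - (up_a | up_b)
    order = {g: i for i, g in enumerate(de_vs_single_a.gene_ids)}
    contrast = f"{de_vs_single_a.arm_a}_vs_{de_vs_single_a.arm_b}+{de_vs_single_b.arm_b}"
    return Signature(
        contrast,
        tuple(sorted(up, key=order.get)),
        tuple(sorted(down, key=order.get)),
        fc_threshold,
        fdr_threshold,
    )


def top_fraction_genes(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    fraction: float = 0.10,
) -> list[str]:
    """Top fraction of genes ranked by across-arm one-way F statistic.

    Ties in F break by gene id (lexicographic) for determinism.  Returns
    ceil(fraction * n_genes) gene ids.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    annotation.check_pairing(matrix)
    arms = annotation.arms
    if len(arms) < 2:
        raise ValueError("need at least 2 arms")
    X = matrix.values
    cols = {arm: [matrix.sample_ids.index(s) for s in annotation.samples_in_arm(arm)]
            for arm in arms}
    ns = np.array([len(cols[a]) for a in arms])
    n = ns.sum()
    k = len(arms)
    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for a, n_a in zip(arms, ns):
        block = X[:, cols[a]]
        m = block.mean(axis=1)
        ssb += n_a * (m - grand) ** 2
        ssw += ((block - m[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    f = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), f)
    gene_ids = np.array(matrix.gene_ids)
    order = np.lexsort((gene_ids, -f))
    n_top = math.ceil(fraction * X.shape[0])
    return list(gene_ids[order[:n_top]])
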