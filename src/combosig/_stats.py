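"""Small shared statistics helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["oneway_f", "bonferroni_pairwise_t"]


def oneway_f(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects F with explicit degenerate handling.

    Returns (F, p).  If the between-group sum of squares is zero the test is
    reported as F=0, p=1 even when within-group variance is also zero
    (identical data carries no evidence of a group effect).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.size for g in groups])
    if (ns < 2).any():
        raise ValueError("every group needs at least 2 members")
    n = ns.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    if ssb == 0.0:
        return 0.0, 1.0
    if ssw == 0.0:
        return np.inf, 0.0
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p


def bonferroni_pairwise_t(groups: dict[str, np.ndarray]) -> list[dict]:
    """All pairwise two-sided Student t tests, each p multiplied by the
    number of pairs and capped at 1."""
    names = list(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    out = []
    for a, b in pairs:
        ga, gb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        t, p = stats.ttest_ind(ga, gb, equal_var=True)
        if np.isnan(p):  # zero variance in both groups, equal means
            t, p = 0.0, 1.0
        out.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "p_raw": float(p),
                "p_adj": min(1.0, float(p) * m),
            }
        )
    return out
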