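"""Expression-split survival analysis: Kaplan–Meier estimation, the
two-group logrank test with an O/E hazard ratio, and a per-gene prognosis
scan across endpoints (OS, RFS, DMFS).

Conventions: the product-limit estimator treats events before censorings at
tied times; the hazard ratio is the ratio of observed/expected event ratios
(the logrank machinery's own HR, avoiding a Cox optimizer) with the
95% CI ``exp(log HR ± 1.96·sqrt(1/E_A + 1/E_B))``; expression splits use the
median with ties going to the low group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .formats import ExpressionMatrix, SurvivalTable

__all__ = [
    "KMCurve",
    "LogrankResult",
    "HazardUndefinedError",
    "median_split",
    "km_estimate",
    "logrank_test",
    "prognosis_scan",
]


class HazardUndefinedError(ValueError):
    """Raised when a group's observed or expected events are zero, leaving
    the O/E hazard ratio undefined."""


def median_split(scores: pd.Series) -> pd.Series:
    """Label samples 'high' (score > median) or 'low' (score <= median)."""
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("need >= 2 samples to split")
    vals = scores.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise ValueError("all scores equal: no split exists")
    med = float(np.median(vals))
    return pd.Series(np.where(vals > med, "high", "low"), index=scores.index, name="group")


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``event_times`` are the distinct times with >= 1 event; ``survival`` the
    estimate just after each; ``at_risk`` and ``n_events`` the corresponding
    risk-set sizes and event counts; ``censor_times`` the censored times.
    S(0) = 1 implicitly precedes the first entry.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    def at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(table: SurvivalTable) -> KMCurve:
    if len(table) == 0:
        raise ValueError("empty survival table")
    time = table.times
    event = table.events
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    etimes = np.unique(time[event == 1])
    surv = np.empty(etimes.size)
    at_risk = np.empty(etimes.size, dtype=int)
    d_i = np.empty(etimes.size, dtype=int)
    s = 1.0
    for i, t in enumerate(etimes):
        n_i = int((time >= t).sum())  # events precede censorings at tied times
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_i
        surv[i], at_risk[i], d_i[i] = s, n_i, d
    return KMCurve(
        event_times=etimes,
        survival=surv,
        at_risk=at_risk,
        n_events=d_i,
        censor_times=np.sort(time[event == 0]),
    )


@dataclass
class LogrankResult:
    chi2: float
    p: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    hr: float
    ci: tuple[float, float]

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi-square statistic must be non-negative")
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")


def logrank_test(table_a: SurvivalTable, table_b: SurvivalTable) -> LogrankResult:
    """Two-group logrank test of A vs B with O/E hazard ratio.

    At each distinct pooled event time the expected events in A follow the
    hypergeometric mean d·n_A/n with variance
    d·(n_A/n)·(1 − n_A/n)·(n − d)/(n − 1); the statistic is
    (O_A − E_A)² / ΣV on 1 df.  HR = (O_A/E_A)/(O_B/E_B) > 1 means A fares
    worse.
    """
    if len(table_a) == 0 or len(table_b) == 0:
        raise ValueError("both groups must be nonempty")
    ta, ea = table_a.times, table_a.events
    tb, eb = table_b.times, table_b.events
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    etimes = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_a = float(ea.sum())
    o_b = float(eb.sum())
    e_a = 0.0
    var = 0.0
    for t in etimes:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        n = n1 + n2
        d = int(((ta == t) & (ea == 1)).sum() + ((tb == t) & (eb == 1)).sum())
        e_a += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    e_b = (o_a + o_b) - e_a
    if var <= 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o_a - e_a) ** 2 / var
        p = float(stats.chi2.sf(chi2, 1))
    if min(o_a, o_b, e_a, e_b) <= 0:
        raise HazardUndefinedError(
            "a group has zero observed or expected events; O/E hazard ratio undefined "
            f"(O_A={o_a}, E_A={e_a:.3g}, O_B={o_b}, E_B={e_b:.3g})"
        )
    hr = (o_a / e_a) / (o_b / e_b)
    half = 1.96 * np.sqrt(1.0 / e_a + 1.0 / e_b)
    ci = (float(hr * np.exp(-half)), float(hr * np.exp(half)))
    return LogrankResult(
        chi2=float(chi2),
        p=max(p, np.finfo(float).tiny),
        observed=(o_a, o_b),
        expected=(float(e_a), float(e_b)),
        hr=float(hr),
        ci=ci,
    )


def _split_table(table: SurvivalTable, labels: pd.Series) -> tuple[SurvivalTable, SurvivalTable]:
    frame = table.frame.set_index("patient_id")
    high = frame.loc[frame.index.isin(labels.index[labels == "high"])].reset_index()
    low = frame.loc[frame.index.isin(labels.index[labels == "low"])].reset_index()
    return SurvivalTable(high), SurvivalTable(low)


def prognosis_scan(
    matrix: ExpressionMatrix,
    tables: dict[str, SurvivalTable],
    genes: list[str] | None = None,
    combine: bool = False,
) -> pd.DataFrame:
    """Median-split logrank scan: per gene (or one combined mean-z score)
    and per endpoint, test high vs low expression; BH q across genes within
    each endpoint.

    Rows where the hazard ratio is undefined (a degenerate split) carry NaN
    statistics and are excluded from the BH adjustment.
    """
    genes = list(genes) if genes is not None else matrix.gene_ids
    missing = [g for g in genes if g not in matrix.frame.index]
    if missing:
        raise ValueError(f"gene(s) not in matrix: {', '.join(missing[:10])}")
    rows = []
    for endpoint, table in tables.items():
        ids = [pid for pid in table.frame["patient_id"] if pid in matrix.frame.columns]
        if not ids:
            raise ValueError(
                f"endpoint {endpoint!r}: no overlap between matrix samples and patients"
            )
        sub_table = SurvivalTable(
            table.frame[table.frame["patient_id"].isin(ids)].copy()
        )
        if combine:
            from .immune import module_score

            score = module_score(matrix, genes)[ids]
            units = [("combined", score)]
        else:
            units = [(g, matrix.frame.loc[g, ids]) for g in genes]
        nan_row = {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                   "chi2": np.nan, "p": np.nan}
        for name, score in units:
            if np.ptp(score.to_numpy(dtype=float)) == 0:
                rows.append({"gene": name, "endpoint": endpoint, **nan_row})
                continue
            labels = median_split(score)
            high, low = _split_table(sub_table, labels)
            try:
                res = logrank_test(high, low)
            except (HazardUndefinedError, ValueError):
                rows.append({"gene": name, "endpoint": endpoint, **nan_row})
                continue
            rows.append(
                {
                    "gene": name,
                    "endpoint": endpoint,
                    "hr": res.hr,
                    "ci_low": res.ci[0],
                    "ci_high": res.ci[1],
                    "chi2": res.chi2,
                    "p": res.p,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for endpoint in out["endpoint"].unique():
        sel = (out["endpoint"] == endpoint) & out["p"].notna()
        if sel.any():
            out.loc[sel, "q"] = bh_fdr(out.loc[sel, "p"].to_numpy())
    return out
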