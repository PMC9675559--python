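"""Survival estimation and the hypothesis tests of the analysis.

Kaplan-Meier product-limit curves and the multi-group log-rank test are
implemented directly (observed-minus-expected sums with hypergeometric
variance at tied event times, the canonical formulation with no tie
correction options).  Group-comparison tests (t / Mann-Whitney /
ANOVA+Tukey / Kruskal-Wallis+Dunn) and Pearson's chi-square delegate to
scipy/statsmodels; Dunn's rank-based post hoc is computed here with BH
adjustment.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KMCurve",
    "LogRankResult",
    "kaplan_meier",
    "logrank_test",
    "compare_groups",
    "chisq_independence",
]


@dataclass
class KMCurve:
    """Product-limit estimate: S(0) = 1, non-increasing step function."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time
    n_events: np.ndarray  # events at each event time

    def survival_at(self, t: float) -> float:
        """S(t) of the step function (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


def _as_arrays(
    times: Sequence[float], events: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-D and matched in length")
    if len(t) == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0 or 1")
    return t, e


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations leave the risk set without producing a step.
    """
    t, e = _as_arrays(times, events)
    event_times = np.unique(t[e == 1])
    survival = np.empty(len(event_times))
    at_risk = np.empty(len(event_times), dtype=int)
    n_events = np.empty(len(event_times), dtype=int)
    s = 1.0
    for i, et in enumerate(event_times):
        n = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n
        survival[i] = s
        at_risk[i] = n
        n_events[i] = d
    return KMCurve(event_times, survival, at_risk, n_events)


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
) -> LogRankResult:
    """Multi-group log-rank test.

    At each distinct event time the observed events per group are compared
    with their hypergeometric expectation given the risk sets; the
    chi-square statistic inverts the covariance of the first G-1 groups'
    observed-minus-expected sums, with df = G - 1.
    """
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must match times in length")
    labels = sorted(pd.unique(g))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = {lab: int((g == lab).sum()) for lab in labels}
    empty = [lab for lab, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"group(s) with zero subjects: {empty}")

    G = len(labels)
    group_idx = np.array([labels.index(x) for x in g])
    event_times = np.unique(t[e == 1])
    observed = np.zeros(G)
    expected = np.zeros(G)
    cov = np.zeros((G, G))
    for et in event_times:
        at_risk = t >= et
        n = int(at_risk.sum())
        d = int(((t == et) & (e == 1)).sum())
        if n <= 1:
            continue
        n_i = np.bincount(group_idx[at_risk], minlength=G).astype(float)
        d_i = np.bincount(
            group_idx[(t == et) & (e == 1)], minlength=G
        ).astype(float)
        observed += d_i
        expected += d * n_i / n
        frac = n_i / n
        hyper = d * (n - d) / (n - 1)
        cov += hyper * (np.diag(frac) - np.outer(frac, frac))

    diff = (observed - expected)[: G - 1]
    v = cov[: G - 1, : G - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(v) @ diff)
    chi2 = max(chi2, 0.0)
    df = G - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi2, df, p)


def _dunn_posthoc(
    values: np.ndarray, group_idx: np.ndarray, labels: list[str]
) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with tie correction and BH."""
    N = len(values)
    ranks = stats.rankdata(values)
    mean_ranks = np.array(
        [ranks[group_idx == i].mean() for i in range(len(labels))]
    )
    sizes = np.bincount(group_idx, minlength=len(labels))
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        se = np.sqrt(
            (N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "statistic": float(z),
                "p_raw": float(2.0 * stats.norm.sf(abs(z))),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    return table


def compare_groups(
    values: Sequence[float],
    groups: Sequence[str],
    method: str,
) -> dict:
    """Omnibus group comparison with pairwise post hoc for >= 3 groups.

    method: 't' or 'mann-whitney' (exactly 2 groups), 'anova-tukey' or
    'kruskal-dunn' (>= 2 groups; pairwise table emitted for >= 3).
    Returns {'method', 'statistic', 'p', 'pairwise' (DataFrame or None)}.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = sorted(pd.unique(g))
    samples = [v[g == lab] for lab in labels]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if method in ("t", "mann-whitney") and len(labels) != 2:
        raise ValueError(f"method {method!r} requires exactly 2 groups, got {len(labels)}")
    if method in ("t", "anova-tukey") and any(len(s) < 2 for s in samples):
        raise ValueError("parametric methods need >= 2 values per group")

    pairwise = None
    if method == "t":
        stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=True)
    elif method == "mann-whitney":
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
    elif method == "anova-tukey":
        stat, p = stats.f_oneway(*samples)
        if len(labels) >= 3:
            tukey = pairwise_tukeyhsd(v, g)
            frame = pd.DataFrame(
                tukey.summary().data[1:], columns=tukey.summary().data[0]
            )
            pairwise = frame.rename(
                columns={"group1": "group_a", "group2": "group_b", "p-adj": "p_adj"}
            )[["group_a", "group_b", "meandiff", "p_adj"]]
    elif method == "kruskal-dunn":
        stat, p = stats.kruskal(*samples)
        if len(labels) >= 3:
            group_idx = np.array([labels.index(x) for x in g])
            pairwise = _dunn_posthoc(v, group_idx, labels)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"method": method, "statistic": float(stat), "p": float(p), "pairwise": pairwise}


def chisq_independence(
    table: Sequence[Sequence[float]] | np.ndarray,
    correction: bool = False,
) -> tuple[float, int, float]:
    """Pearson's chi-square test of independence on a contingency table.

    No continuity correction by default; an all-zero row or column is an
    error.  Returns (chi2, df, p).
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("contingency table has an all-zero row or column")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=correction)
    return float(chi2), int(df), float(p)
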