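"""QRS comparison statistics between normal and abnormal simulations.

Abnormal QRS complexes are compared with the normal-activation simulation
lead by lead using Pearson's correlation coefficient over the QRS window.
The most affected lead is the one with the lowest CC; by default that
minimum-lead CC also serves as the per-simulation summary QRS-CC
(alternatively the CC of all leads concatenated).  Group differences are
tested with the Mann-Whitney U test (non-normal data) and unpaired
t-tests (Welch and pooled variants).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sources import PotentialTraces

__all__ = ["ComparisonResult", "qrs_cc", "compare_groups", "GroupComparison"]


@dataclass
class ComparisonResult:
    """Per-lead and summary QRS correlation of one simulation."""

    lead_labels: list
    lead_cc: np.ndarray  # NaN for excluded (zero-variance) leads
    most_affected_lead: str
    most_affected_cc: float
    summary_cc: float
    qrs_duration_ms: float = np.nan
    excluded_leads: list = field(default_factory=list)
    window: tuple = (np.nan, np.nan)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "summary_cc": self.summary_cc,
                "most_affected_lead": self.most_affected_lead,
                "most_affected_cc": self.most_affected_cc,
                "qrs_duration_ms": self.qrs_duration_ms,
            }
        )


def qrs_cc(
    normal: PotentialTraces,
    abnormal: PotentialTraces,
    window: tuple[float, float],
    qrs_duration_ms: float = np.nan,
    summary: str = "min_lead",
) -> ComparisonResult:
    """Per-lead Pearson CC of abnormal vs normal QRS over ``window``.

    Leads with zero variance in either trace are excluded and flagged.
    ``summary="min_lead"`` (default) reports the most-affected-lead CC;
    ``summary="concatenated"`` the CC of all valid leads concatenated.
    Traces of unequal duration on the same grid are aligned by holding the
    final sample (potentials are constant once activation is complete).
    """
    if normal.labels != abnormal.labels:
        raise ValueError("traces must share channels")
    normal, abnormal = _align(normal, abnormal)
    t0, t1 = window
    a = normal.window(t0, t1)
    b = abnormal.window(t0, t1)
    if len(a.times) != len(b.times) or len(a.times) < 3:
        raise ValueError("window must cover both traces on a shared grid")

    n_leads = len(normal.labels)
    cc = np.full(n_leads, np.nan)
    excluded = []
    for i in range(n_leads):
        x, y = a.values[i], b.values[i]
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            excluded.append(normal.labels[i])
            continue
        cc[i] = sps.pearsonr(x, y).statistic
    if np.all(np.isnan(cc)):
        raise ValueError("no lead with non-zero variance in the window")

    k = int(np.nanargmin(cc))
    if summary == "min_lead":
        summary_cc = float(cc[k])
    elif summary == "concatenated":
        valid = ~np.isnan(cc)
        summary_cc = float(
            sps.pearsonr(a.values[valid].ravel(), b.values[valid].ravel()).statistic
        )
    else:
        raise ValueError(f"unknown summary mode {summary!r}")
    return ComparisonResult(
        lead_labels=list(normal.labels),
        lead_cc=cc,
        most_affected_lead=normal.labels[k],
        most_affected_cc=float(cc[k]),
        summary_cc=summary_cc,
        qrs_duration_ms=qrs_duration_ms,
        excluded_leads=excluded,
        window=(t0, t1),
    )


def _align(a: PotentialTraces, b: PotentialTraces):
    """Pad the shorter trace set with its final value (shared t0 and dt)."""
    if len(a.times) == len(b.times):
        return a, b
    if a.times[0] != b.times[0] or a.dt_ms != b.dt_ms:
        raise ValueError("traces must share the time-grid origin and step")
    short, long_ = (a, b) if len(a.times) < len(b.times) else (b, a)
    pad = np.repeat(short.values[:, -1:], len(long_.times) - len(short.times), axis=1)
    padded = PotentialTraces(
        long_.times, np.hstack([short.values, pad]), short.labels, short.metadata
    )
    return (padded, b) if short is a else (a, padded)


@dataclass
class GroupComparison:
    """Two-sample test results for summary-CC groups."""

    mannwhitney_u: float
    mannwhitney_p: float
    t_welch: float
    t_welch_p: float
    t_pooled: float
    t_pooled_p: float
    normality_p: tuple  # Shapiro-Wilk p per group (descriptive)
    medians: tuple
    n: tuple


def compare_groups(group_a, group_b, method: str = "auto") -> GroupComparison:
    """Mann-Whitney U (mid-rank ties) and unpaired t-tests between groups.

    ``method`` selects the U-test p-value computation ("auto", "exact",
    "asymptotic"), as in :func:`scipy.stats.mannwhitneyu`.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    u = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    tw = sps.ttest_ind(a, b, equal_var=False)
    tp = sps.ttest_ind(a, b, equal_var=True)

    def shapiro_p(x):
        if len(x) < 3 or np.ptp(x) == 0.0:
            return np.nan
        return float(sps.shapiro(x).pvalue)

    return GroupComparison(
        mannwhitney_u=float(u.statistic),
        mannwhitney_p=float(u.pvalue),
        t_welch=float(tw.statistic),
        t_welch_p=float(tw.pvalue),
        t_pooled=float(tp.statistic),
        t_pooled_p=float(tp.pvalue),
        normality_p=(shapiro_p(a), shapiro_p(b)),
        medians=(float(np.median(a)), float(np.median(b))),
        n=(len(a), len(b)),
    )
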