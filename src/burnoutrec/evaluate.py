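"""Outcome analyses for two-stage intervention trials.

Reusable versions of the study's statistics: paired t tests on pre/post
scores, Spearman correlation of score changes with participation order
(the optimization signal: later participants should improve more as the
knowledge base matures), and a one-way ANOVA with Scheffé post hoc on
satisfaction across consecutive-hundred participant groups.

All tests are two-sided.  Degenerate inputs (zero-variance differences)
return flagged results instead of infinities; significance thresholds
are never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import TrialResult

__all__ = [
    "PairedTestResult",
    "CorrelationResult",
    "GroupTrendResult",
    "paired_change_test",
    "order_correlation",
    "grouped_satisfaction_trend",
    "summarize_trial",
]


@dataclass(frozen=True)
class PairedTestResult:
    mean_pre: float
    mean_post: float
    t: float
    p: float
    df: int
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class GroupTrendResult:
    group_means: dict
    F: float
    p: float
    #: Scheffé contrasts: {(group_a, group_b): p_value}
    posthoc: dict
    degenerate: bool = False


def paired_change_test(
    pre: Sequence[float], post: Sequence[float]
) -> PairedTestResult:
    """Two-sided paired t test on ``pre - post``.

    A zero-variance difference vector is degenerate: t is reported as 0
    when the scores are identical and the result is flagged rather than
    returning an infinite statistic.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"length mismatch: {pre.shape} vs {post.shape}")
    n = pre.size
    if n < 2:
        raise ValueError("paired test needs n >= 2")
    diff = pre - post
    if np.ptp(diff) == 0:
        # constant differences: no within-pair variance to test against
        t = 0.0 if diff[0] == 0 else float(np.sign(diff[0]) * np.inf)
        p = 1.0 if diff[0] == 0 else 0.0
        return PairedTestResult(
            mean_pre=float(pre.mean()),
            mean_post=float(post.mean()),
            t=t,
            p=p,
            df=n - 1,
            degenerate=True,
        )
    res = stats.ttest_rel(pre, post)
    return PairedTestResult(
        mean_pre=float(pre.mean()),
        mean_post=float(post.mean()),
        t=float(res.statistic),
        p=float(res.pvalue),
        df=n - 1,
    )


def order_correlation(
    order: Sequence[float], change: Sequence[float]
) -> CorrelationResult:
    """Spearman correlation of participation order with a score change."""
    order = np.asarray(order, dtype=float)
    change = np.asarray(change, dtype=float)
    if order.shape != change.shape:
        raise ValueError("order and change must have equal length")
    if order.size < 3:
        raise ValueError("correlation needs n >= 3")
    if np.ptp(change) == 0 or np.ptp(order) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.spearmanr(order, change)
    return CorrelationResult(
        rho=float(res.statistic), p=float(res.pvalue), n=order.size
    )


def _scheffe_posthoc(
    groups: dict, msw: float, df_within: int, k: int
) -> dict:
    """Scheffé simultaneous pairwise contrasts from the ANOVA mean square."""
    names = list(groups)
    out: dict = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ga, gb = groups[a], groups[b]
            se2 = msw * (1.0 / len(ga) + 1.0 / len(gb))
            f_pair = (ga.mean() - gb.mean()) ** 2 / se2 / (k - 1)
            out[(a, b)] = float(stats.f.sf(f_pair, k - 1, df_within))
    return out


def grouped_satisfaction_trend(
    satisfaction: Sequence[float], group: Sequence
) -> GroupTrendResult:
    """One-way ANOVA with Scheffé post hoc across participant groups."""
    satisfaction = np.asarray(satisfaction, dtype=float)
    group = np.asarray(group)
    if satisfaction.shape != group.shape:
        raise ValueError("satisfaction and group must have equal length")
    labels = pd.unique(group)
    groups = {g: satisfaction[group == g] for g in labels}
    for g, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    k = len(groups)
    n_total = satisfaction.size
    means = {g: float(v.mean()) for g, v in groups.items()}
    if np.ptp(satisfaction) == 0:
        return GroupTrendResult(
            group_means=means,
            F=0.0,
            p=1.0,
            posthoc={},
            degenerate=True,
        )
    res = stats.f_oneway(*groups.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_within = n_total - k
    msw = ssw / df_within
    posthoc = _scheffe_posthoc(groups, msw, df_within, k) if msw > 0 else {}
    return GroupTrendResult(
        group_means=means,
        F=float(res.statistic),
        p=float(res.pvalue),
        posthoc=posthoc,
    )


def _hundred_group(order: int) -> int:
    return (order - 1) // 100 + 1


def summarize_trial(trial: TrialResult) -> dict:
    """Full outcome report for one closed-loop trial.

    Covers the pre/post paired tests per stage, per-program reductions
    and satisfaction, order correlations of stage changes, and the
    grouped satisfaction trend (consecutive-hundred groups), together
    with normality descriptives (skewness, kurtosis) for the change
    scores.
    """
    t = trial.table
    s1 = t[t["stage"] == 1].sort_values("order")
    s2 = t[t["stage"] == 2].sort_values("order")
    report: dict = {"n_participants": int(t["participant_id"].nunique())}

    for label, frame in (("stage1", s1), ("stage2", s2)):
        test = paired_change_test(frame["pre_total"], frame["post_total"])
        change = frame["post_total"] - frame["pre_total"]
        report[label] = {
            "paired_t": test.__dict__,
            "skewness": float(stats.skew(change)),
            "kurtosis": float(stats.kurtosis(change, fisher=False)),
        }
        try:
            corr = order_correlation(frame["order"], change)
            report[label]["order_correlation"] = corr.__dict__
        except ValueError:
            report[label]["order_correlation"] = None

    by_program = {}
    for prog, frame in t.groupby("program"):
        by_program[prog] = {
            "n_stages": int(len(frame)),
            "mean_total_reduction": float(frame["reduction_total"].mean()),
            "mean_satisfaction": float(frame["satisfaction"].mean()),
            "valid_fraction": float(frame["valid"].mean()),
        }
    report["by_program"] = by_program
    report["valid_records"] = int(t["valid"].sum())

    groups = s1["order"].map(_hundred_group)
    if groups.nunique() >= 2 and all(
        (groups == g).sum() >= 2 for g in groups.unique()
    ):
        for label, frame in (("stage1", s1), ("stage2", s2)):
            g = frame["order"].map(_hundred_group)
            trend = grouped_satisfaction_trend(frame["satisfaction"], g)
            report[label]["satisfaction_trend"] = {
                "group_means": {int(k): v for k, v in trend.group_means.items()},
                "F": trend.F,
                "p": trend.p,
                "posthoc": {f"{a}-{b}": p for (a, b), p in trend.posthoc.items()},
            }
    return report
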