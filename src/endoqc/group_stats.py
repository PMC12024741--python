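"""Normality-gated group comparisons with mean +/- SD summaries.

The gate: Shapiro-Wilk at ``alpha`` on each group (unpaired) or on the
paired differences; normal data get a t-test (Welch by default for
unpaired), non-normal data a Wilcoxon test (rank-sum unpaired, signed-rank
paired).  All p-values are two-sided and t statistics are reported as |t|.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
from scipy import stats as _scipy_stats

T_TEST = "t_test"
PAIRED_T_TEST = "paired_t_test"
WILCOXON_SIGNED_RANK = "wilcoxon_signed_rank"
WILCOXON_RANK_SUM = "wilcoxon_rank_sum"


@dataclass(slots=True)
class Summary:
    mean: float
    sd: float
    text: str


@dataclass(slots=True)
class GroupComparison:
    label: str
    test_used: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    summary_a: Summary
    summary_b: Summary
    normality_p_a: float | None = None
    normality_p_b: float | None = None
    normality_p_diff: float | None = None
    degenerate: bool = False


def shapiro_wilk(values: Sequence[float]) -> float:
    """Two-sided Shapiro-Wilk normality p-value.

    Requires 3 <= n <= 5000 and non-zero variance.
    """
    n = len(values)
    if n < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {n}")
    if n > 5000:
        raise ValueError(f"Shapiro-Wilk supports n <= 5000, got {n}")
    if len(set(values)) == 1:
        raise ValueError("Shapiro-Wilk undefined for zero-variance data")
    return float(_scipy_stats.shapiro(np.asarray(values, dtype=float)).pvalue)


def summarize(values: Sequence[float], precision: int = 2, percent: bool = False) -> Summary:
    """Mean and sample SD, rendered as ``mean +/- sd`` text.

    ``percent=True`` renders fractions on the x100 scale with % signs.
    """
    if len(values) < 2:
        raise ValueError("need >= 2 values to summarize")
    mean = statistics.fmean(values)
    sd = statistics.stdev(values)
    if percent:
        text = f"{mean * 100:.{precision}f}% ± {sd * 100:.{precision}f}%"
    else:
        text = f"{mean:.{precision}f} ± {sd:.{precision}f}"
    return Summary(mean=mean, sd=sd, text=text)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    alpha: float = 0.05,
    label: str = "",
    *,
    equal_var: bool = False,
) -> GroupComparison:
    """Compare two groups with the normality-gated test choice.

    Unpaired: both Shapiro-Wilk p >= alpha -> two-sample t-test (Welch
    unless ``equal_var``), else Wilcoxon rank-sum.  Paired: Shapiro-Wilk on
    the differences gates between the paired t-test and the Wilcoxon
    signed-rank test (zeros dropped, exact null for n <= 25).  When all
    paired differences are zero the result is flagged degenerate with p=1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and len(a) != len(b):
        raise ValueError(f"paired comparison requires equal n, got {len(a)} vs {len(b)}")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 observations per group")
    summary_a = summarize(a)
    summary_b = summarize(b)
    common = dict(
        label=label,
        n_a=len(a),
        n_b=len(b),
        summary_a=summary_a,
        summary_b=summary_b,
    )

    if paired:
        diff = a - b
        if np.all(diff == 0):
            return GroupComparison(
                test_used=PAIRED_T_TEST,
                statistic=0.0,
                p_value=1.0,
                degenerate=True,
                **common,
            )
        if np.ptp(diff) == 0:
            # constant non-zero differences: t statistic diverges
            return GroupComparison(
                test_used=PAIRED_T_TEST,
                statistic=math.inf,
                p_value=0.0,
                degenerate=True,
                **common,
            )
        p_norm = shapiro_wilk(diff)
        if p_norm >= alpha:
            res = _scipy_stats.ttest_rel(a, b)
            return GroupComparison(
                test_used=PAIRED_T_TEST,
                statistic=abs(float(res.statistic)),
                p_value=float(res.pvalue),
                normality_p_diff=p_norm,
                **common,
            )
        res = _scipy_stats.wilcoxon(diff, zero_method="wilcox", correction=True, method="auto")
        return GroupComparison(
            test_used=WILCOXON_SIGNED_RANK,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            normality_p_diff=p_norm,
            **common,
        )

    p_a = shapiro_wilk(a) if np.ptp(a) > 0 else 0.0
    p_b = shapiro_wilk(b) if np.ptp(b) > 0 else 0.0
    if p_a >= alpha and p_b >= alpha:
        res = _scipy_stats.ttest_ind(a, b, equal_var=equal_var)
        return GroupComparison(
            test_used=T_TEST,
            statistic=abs(float(res.statistic)),
            p_value=float(res.pvalue),
            normality_p_a=p_a,
            normality_p_b=p_b,
            **common,
        )
    res = _scipy_stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return GroupComparison(
        test_used=WILCOXON_RANK_SUM,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p_a=p_a,
        normality_p_b=p_b,
        **common,
    )
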