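"""Two-group comparison with normality-gated test selection.

The convention throughout the package: assess normality of each group
with the Shapiro-Wilk test at alpha = 0.05; when both groups look
normal use Student's t (paired t for paired designs), otherwise use the
Mann-Whitney U test (Wilcoxon signed-rank when paired). The result
records which branch ran.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TestResult", "compare_groups"]

SHAPIRO_ALPHA = 0.05


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def _looks_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0:  # Shapiro undefined for constant input
        return True
    return stats.shapiro(x).pvalue >= SHAPIRO_ALPHA


def compare_groups(
    values_a,
    values_b,
    paired: bool = False,
    alternative: str = "two-sided",
) -> TestResult:
    """Compare two groups, choosing the test by a Shapiro-Wilk gate.

    Unpaired: Student's t when both groups pass normality, else
    Mann-Whitney U. Paired: the gate runs on the differences; paired t
    when normal, else the exact Wilcoxon signed-rank test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >=3 values per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired groups must have equal length")
        diffs = a - b
        if _looks_normal(diffs):
            res = stats.ttest_rel(a, b, alternative=alternative)
            name = "paired t"
        else:
            res = stats.wilcoxon(a, b, alternative=alternative, method="exact")
            name = "wilcoxon signed-rank"
        return TestResult(name, float(res.statistic), float(res.pvalue), len(a), len(b))
    if _looks_normal(a) and _looks_normal(b):
        res = stats.ttest_ind(a, b, alternative=alternative)
        name = "student t"
    else:
        res = stats.mannwhitneyu(a, b, alternative=alternative)
        name = "mann-whitney u"
    return TestResult(name, float(res.statistic), float(res.pvalue), len(a), len(b))
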