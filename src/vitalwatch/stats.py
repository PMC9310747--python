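"""Group-comparison statistics.

Frequencies of patients with abnormal-vital-sign episodes are compared
between groups with Pearson's chi-square test (no continuity correction;
the correction is a 2x2 device and the tables here are 2x3), and
abnormality durations with the Kruskal-Wallis rank test with tie
correction.  No multiple-comparison correction is applied: the analysis is
exploratory and hypothesis-generating by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    degrees_of_freedom: Optional[int] = None


def chi_square_test(table: np.ndarray) -> TestResult:
    """Pearson chi-square on a 2 x k contingency table, df = k - 1.

    Raises if any expected cell count is zero (the statistic is undefined).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    expected = sps.contingency.expected_freq(table)
    if (expected == 0).any():
        raise ValueError("zero expected cell count; table is degenerate")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(chi2), p_value=float(p), degrees_of_freedom=int(dof))


def kruskal_wallis_test(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H across >= 2 non-empty groups (chi-square approximation).

    When every observation is identical the statistic is 0 and p is 1 (the
    rank test carries no information).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, p_value=1.0, degrees_of_freedom=len(arrays) - 1)
    h, p = sps.kruskal(*arrays)
    return TestResult(statistic=float(h), p_value=float(p), degrees_of_freedom=len(arrays) - 1)


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and (25th, 75th) percentiles with linear interpolation."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)
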