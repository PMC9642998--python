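"""Statistical procedures for incidence tables, summary measurements and
subpopulation comparisons.

The toolbox mirrors the statistics applied throughout a sick-sinus-syndrome
screening study: per-genotype event incidences, chi-square tests on 2x2
incidence tables, unpaired Student's t-tests reconstructed from published
mean/dispersion/n summaries, two-sided Wilcoxon rank-sum tests for comparing
parameter distributions between model subpopulations, and boxplot notch
intervals (median confidence bands) for the same comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "IncidenceTable",
    "SummaryStat",
    "incidence_percent",
    "chi2_2x2",
    "ttest_from_summary",
    "wilcoxon_rank_sum",
    "notch_interval",
]


@dataclass(frozen=True)
class IncidenceTable:
    """A 2x2 event-incidence contingency table.

    Rows are groups (e.g. wild-type vs mutant); columns are
    (event, no-event) counts.
    """

    counts: tuple[tuple[int, int], tuple[int, int]]
    group_labels: tuple[str, str] = ("group_a", "group_b")

    def __post_init__(self) -> None:
        flat = [c for row in self.counts for c in row]
        if any(c < 0 for c in flat):
            raise ValueError("counts must be non-negative")
        if any(sum(row) == 0 for row in self.counts):
            raise ValueError("each group (row) must have at least one subject")

    @classmethod
    def from_events(
        cls,
        events_a: int,
        total_a: int,
        events_b: int,
        total_b: int,
        labels: tuple[str, str] = ("group_a", "group_b"),
    ) -> "IncidenceTable":
        """Build the table from (events, total) per group."""
        return cls(
            (
                (events_a, total_a - events_a),
                (events_b, total_b - events_b),
            ),
            labels,
        )


@dataclass(frozen=True)
class SummaryStat:
    """Published summary of one sample: mean, dispersion (SD or SEM), n."""

    mean: float
    dispersion: float
    kind: Literal["sd", "sem"]
    n: int

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.n < 2:
            raise ValueError("summary statistics require n >= 2")
        if self.kind not in ("sd", "sem"):
            raise ValueError(f"unknown dispersion kind: {self.kind!r}")

    @property
    def sd(self) -> float:
        """Sample standard deviation (SEM is converted by multiplying sqrt(n))."""
        if self.kind == "sd":
            return self.dispersion
        return self.dispersion * math.sqrt(self.n)


def incidence_percent(k: int, n: int) -> float:
    """Event incidence as a percentage, rounded half-up to one decimal.

    Matches the convention of published incidence tables, e.g. 4 affected
    fish out of 7 -> 57.1.
    """
    if n <= 0:
        raise ValueError("total count n must be positive")
    if not 0 <= k <= n:
        raise ValueError("event count k must satisfy 0 <= k <= n")
    raw = 100.0 * k / n
    # round-half-up at one decimal (Python's round() is banker's rounding)
    return math.floor(raw * 10 + 0.5) / 10


def chi2_2x2(table: IncidenceTable, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test (1 df) on a 2x2 incidence table.

    Yates continuity correction is applied only when ``correction`` is True.
    The default is the uncorrected statistic, which is the variant consistent
    with the significance calls of the incidence tables this package targets.

    Returns ``(statistic, p)``.
    """
    arr = np.asarray(table.counts, dtype=float)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a row or column sum is zero")
    stat, p, dof, _ = _sps.chi2_contingency(arr, correction=correction)
    assert dof == 1
    return float(stat), float(p)


def ttest_from_summary(a: SummaryStat, b: SummaryStat) -> tuple[float, int, float]:
    """Unpaired two-tailed pooled-variance Student's t-test from summaries.

    SEM dispersions are converted to SDs before pooling. Returns
    ``(t, df, p)`` with df = n_a + n_b - 2.
    """
    res = _sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    df = a.n + b.n - 2
    return float(res.statistic), df, float(res.pvalue)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact p by enumeration of rank assignments when the smaller sample has
    at most 10 observations and there are no ties across the pooled sample;
    otherwise the normal approximation with midranks, tie-corrected variance
    and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(x.size, y.size) <= 10 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = _sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def notch_interval(values: Sequence[float]) -> tuple[float, float]:
    """Boxplot notch interval: q50 +/- 1.57 (q75 - q25) / sqrt(n).

    An approximate 95% confidence band for the median; non-overlap of the
    notches of two groups indicates a median difference at roughly the 0.05
    level. Quartiles use linear interpolation between order statistics.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("notch interval of an empty sample is undefined")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    half = 1.57 * (q75 - q25) / math.sqrt(v.size)
    return float(q50 - half), float(q50 + half)
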