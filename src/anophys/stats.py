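"""Statistical layer: mean +/- SEM summaries, normality, group comparisons.

Values are summarised as mean +/- SEM with n the number of cells;
normality is assessed with the Shapiro-Wilk test (reported, never used to
auto-switch tests); comparisons use the two-sided paired t test or the
Mann-Whitney U test, chosen explicitly per comparison.  No
multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "summarize_groups",
    "compare_paired",
    "compare_groups",
]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float
    shapiro_p: float | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.label}: {self.mean:.1f} +/- {self.sem:.1f} (n={self.n})"


@dataclass(frozen=True)
class TestResult:
    p: float
    statistic: float
    test: str
    undefined: bool = False


def summarize(values, label: str = "") -> GroupSummary:
    """Mean, SEM (SD/sqrt(n)) and Shapiro-Wilk p (n >= 3, non-degenerate)."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarise an empty group")
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else 0.0
    shapiro_p = None
    if x.size >= 3 and np.ptp(x) > 0:
        shapiro_p = float(sps.shapiro(x).pvalue)
    return GroupSummary(label=label, n=int(x.size), mean=mean, sem=sem,
                        shapiro_p=shapiro_p)


def summarize_groups(groups: dict[str, list[float]]) -> pd.DataFrame:
    """Mean +/- SEM table over labelled groups."""
    rows = []
    for label, values in groups.items():
        s = summarize(values, label)
        rows.append({"label": s.label, "n": s.n, "mean": s.mean,
                     "sem": s.sem, "shapiro_p": s.shapiro_p})
    return pd.DataFrame(rows)


def compare_paired(a, b) -> TestResult:
    """Two-sided paired t test; zero-variance differences are flagged."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    if np.ptp(diff) == 0:
        return TestResult(p=math.nan, statistic=math.nan, test="paired-t",
                          undefined=True)
    res = sps.ttest_rel(a, b)
    return TestResult(p=float(res.pvalue), statistic=float(res.statistic),
                      test="paired-t")


def compare_groups(a, b, exact_max_n: int = 8) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when both groups are small (n <= 8) and
    tie-free; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = ("exact"
              if (a.size <= exact_max_n and b.size <= exact_max_n and not has_ties)
              else "asymptotic")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(p=float(min(res.pvalue, 1.0)),
                      statistic=float(res.statistic),
                      test=f"mann-whitney-{method}")
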