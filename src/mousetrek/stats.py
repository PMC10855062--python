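"""Group-level summaries: mean ± SEM tables and two-group comparisons.

Values are reported as mean ± SEM per group and compared with Student's
t-test (pooled variance, df = n1 + n2 - 2; Welch's correction behind a
flag) or the two-sample Kolmogorov-Smirnov test.  Multi-group procedures
(Dunnett-style comparisons) are out of scope here — the sweeps that needed
them involve network training this package does not perform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupSummary:
    n: int
    mean: float
    sem: float


@dataclass
class ComparisonResult:
    metric: str
    test: str
    statistic: float
    p_value: float
    df: float | None
    groups: dict[str, GroupSummary]
    degenerate: bool = False  # both groups constant: statistic undefined


def sem(values: np.ndarray) -> float:
    """Standard error of the mean, SD(ddof=1)/sqrt(n)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def summarize(values: np.ndarray) -> GroupSummary:
    values = np.asarray(values, dtype=float)
    return GroupSummary(n=len(values), mean=float(values.mean()), sem=sem(values))


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    test: str = "t_test",
    group_col: str = "group",
    value_col: str = "value",
    metric_col: str = "metric",
    welch: bool = False,
) -> ComparisonResult:
    """Two-group comparison of one metric in a tidy (animal, group, metric,
    value) table.

    With zero variance in both groups and differing means the t statistic is
    unbounded; the result is flagged ``degenerate`` with an infinite
    statistic and p = 0 (maximal separation) rather than raising.
    """
    sub = table[table[metric_col] == metric]
    groups = sorted(sub[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups for metric {metric!r}, got {groups}")
    a = sub.loc[sub[group_col] == groups[0], value_col].to_numpy(dtype=float)
    b = sub.loc[sub[group_col] == groups[1], value_col].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 animals per group")
    summaries = {groups[0]: summarize(a), groups[1]: summarize(b)}

    if test == "t_test":
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                return ComparisonResult(
                    metric, test, 0.0, 1.0, float(len(a) + len(b) - 2),
                    summaries, degenerate=True,
                )
            return ComparisonResult(
                metric, test, float("inf"), 0.0, float(len(a) + len(b) - 2),
                summaries, degenerate=True,
            )
        res = stats.ttest_ind(a, b, equal_var=not welch)
        df = float(res.df) if hasattr(res, "df") else float(len(a) + len(b) - 2)
        return ComparisonResult(
            metric, test, float(res.statistic), float(res.pvalue), df, summaries
        )
    if test == "ks":
        res = stats.ks_2samp(a, b)
        return ComparisonResult(
            metric, test, float(res.statistic), float(res.pvalue), None, summaries
        )
    raise ValueError(f"unknown test {test!r}")


def group_table(rows: list[dict]) -> pd.DataFrame:
    """Build a tidy group table from row dicts, checking uniqueness."""
    df = pd.DataFrame(rows)
    required = {"animal_id", "group", "metric", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"rows need keys {sorted(required)}")
    dup = df.duplicated(subset=["animal_id", "metric"])
    if dup.any():
        raise ValueError("duplicate (animal, metric) entries")
    return df
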