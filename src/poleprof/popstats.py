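"""Population summaries and the group-comparison testing policy.

The branching rule mirrors the original analysis: per-group normality is
assessed (Shapiro-Wilk at alpha = 0.05, an implementation convention since
the original normality test is unstated); if every group passes, a
parametric test is used (two-sample t-test for two groups, one-way ANOVA for
three or more), otherwise the nonparametric counterpart (two-sample
Kolmogorov-Smirnov, or Kruskal-Wallis for three or more groups).  No
multiple-testing correction is applied across metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = ["GroupComparison", "compare_groups", "population_summary"]

NORMALITY_ALPHA = 0.05


@dataclass
class GroupComparison:
    metric: str
    groups: dict[str, np.ndarray]
    test_used: str           # t_test | anova | ks_2sample | kruskal_wallis
    statistic: float
    p_value: float
    n_per_group: dict[str, int] = field(default_factory=dict)
    normality: dict[str, bool] = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_groups(values_by_group: dict[str, np.ndarray], alpha: float = 0.05,
                   metric: str = "metric") -> GroupComparison:
    """Apply the normality-gated two-branch testing policy to named groups."""
    if len(values_by_group) < 2:
        raise ConfigurationError("need at least 2 groups to compare")
    clean = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < 3:
            raise ConfigurationError(f"group {name!r} has fewer than 3 values")
        clean[name] = arr

    normality = {}
    for name, arr in clean.items():
        if np.ptp(arr) == 0:
            normality[name] = False  # Shapiro undefined on constant data
        else:
            normality[name] = bool(stats.shapiro(arr).pvalue >= NORMALITY_ALPHA)
    parametric = all(normality.values())

    samples = list(clean.values())
    if len(clean) == 2:
        if parametric:
            res = stats.ttest_ind(*samples)
            test = "t_test"
        else:
            res = stats.ks_2samp(*samples)
            test = "ks_2sample"
    else:
        if parametric:
            res = stats.f_oneway(*samples)
            test = "anova"
        else:
            res = stats.kruskal(*samples)
            test = "kruskal_wallis"
    return GroupComparison(
        metric=metric,
        groups=clean,
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group={k: len(v) for k, v in clean.items()},
        normality=normality,
        alpha=alpha,
    )


def population_summary(table: pd.DataFrame, group_col: str = "group",
                       groups: list[str] | None = None) -> pd.DataFrame:
    """Per-group n, mean, SEM, SD, median and quartiles for every numeric
    metric column.  Single-value groups report NaN SD (flagged downstream)."""
    if table.empty:
        raise ConfigurationError("metrics table is empty")
    if group_col not in table.columns:
        raise ConfigurationError(f"missing group column {group_col!r}")
    if groups is not None:
        unknown = set(table[group_col].unique()) - set(groups)
        if unknown:
            raise ConfigurationError(f"unknown group labels: {sorted(unknown)}")
    metrics = [c for c in table.columns
               if c != group_col and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for gname, sub in table.groupby(group_col, sort=True):
        for m in metrics:
            vals = sub[m].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            rows.append({
                "group": gname,
                "metric": m,
                "n": len(vals),
                "mean": vals.mean(),
                "sem": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                "median": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
            })
    return pd.DataFrame(rows)
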