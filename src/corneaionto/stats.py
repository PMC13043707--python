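"""Between-group inference on albumin concentrations.

One-way ANOVA with the classical between/within sum-of-squares
decomposition, followed by Tukey's honestly-significant-difference test.
Tukey quantiles come from the studentized-range distribution evaluated
numerically (scipy.stats.studentized_range), not from printed tables;
unbalanced designs use the Tukey-Kramer standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["GroupData", "AnovaResult", "TukeyResult", "one_way_anova", "tukey_hsd"]


@dataclass(frozen=True)
class GroupData:
    """Measurements of one treatment group (label = applied current, mA)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError(f"group {self.label!r}: need at least 2 values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float


def one_way_anova(groups: Sequence[GroupData]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Degenerate case: if the within-group variance is zero and the group
    means are equal, every observation is identical — F is defined as 0
    and p as 1 (no evidence of any difference).  Zero within-variance
    with unequal means gives F = inf, p = 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    all_vals = np.concatenate([g.values for g in groups])
    grand = all_vals.mean()
    ss_between = sum(g.n * (g.values.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g.values - g.values.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    if df_w < 1:
        raise ValueError("no residual degrees of freedom")
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0, 0.0, 0.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0, float(ss_between), 0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p, float(ss_between), float(ss_within))


@dataclass(frozen=True)
class TukeyResult:
    """One pairwise comparison of the Tukey HSD family."""

    group_a: str
    group_b: str
    mean_diff: float
    se: float
    q: float
    p_adj: float
    significant: bool


def tukey_hsd(groups: Sequence[GroupData], alpha: float = 0.05) -> list[TukeyResult]:
    """Tukey HSD pairwise comparisons with pooled within-group variance.

    The q statistic for groups a, b is |mean_a - mean_b| / SE with the
    Tukey-Kramer SE = sqrt(MSW/2 * (1/n_a + 1/n_b)) (reducing to the
    classical sqrt(MSW/n) for equal n); adjusted p-values come from the
    studentized-range distribution with k groups and the within df.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    anova = one_way_anova(groups)
    k = len(groups)
    df_w = anova.df_within
    msw = anova.ss_within / df_w
    results: list[TukeyResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            diff = a.values.mean() - b.values.mean()
            se = np.sqrt(msw / 2.0 * (1.0 / a.n + 1.0 / b.n))
            if se == 0.0:
                q = 0.0 if diff == 0 else float("inf")
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_w))
            results.append(
                TukeyResult(
                    group_a=a.label,
                    group_b=b.label,
                    mean_diff=float(diff),
                    se=float(se),
                    q=float(q),
                    p_adj=min(1.0, p),
                    significant=bool(p < alpha),
                )
            )
    return results
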