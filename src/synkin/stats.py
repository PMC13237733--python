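"""Significance tests used in the aggregation analysis, as thin wrappers.

One-way ANOVA compares end-point ThT intensities or fibril yields across
variants; two-way ANOVA (Type-II sums of squares, suitable for the
unbalanced layouts left by replicate attrition) covers variant ×
concentration designs; Tukey's HSD provides the post hoc pairwise
comparisons and Pearson's test the yield–intensity correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedData",
    "AnovaResult",
    "one_way_anova",
    "two_way_anova",
    "tukey_hsd",
    "pearson",
]


@dataclass
class GroupedData:
    """Observations with one or two categorical factors."""

    values: np.ndarray
    factor_a: np.ndarray
    factor_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.factor_a = np.asarray(self.factor_a, dtype=object)
        if self.factor_b is not None:
            self.factor_b = np.asarray(self.factor_b, dtype=object)
        if self.factor_a.size != self.values.size:
            raise ValueError("factor labels must match values")

    def groups(self) -> list[np.ndarray]:
        return [
            self.values[self.factor_a == g]
            for g in pd.unique(self.factor_a)
        ]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def one_way_anova(data: GroupedData) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA."""
    groups = data.groups()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    F, p = sps.f_oneway(*groups)
    n = sum(g.size for g in groups)
    return AnovaResult(
        F=float(F), df_between=len(groups) - 1,
        df_within=n - len(groups), p=float(p),
    )


def two_way_anova(data: GroupedData, interaction: bool = True) -> pd.DataFrame:
    """Two-factor ANOVA with Type-II sums of squares.

    Returns a table indexed by term with columns sum_sq, df, F, p.
    Raises when an interaction is requested but some factor-level cell
    is empty.
    """
    if data.factor_b is None:
        raise ValueError("two_way_anova needs a second factor")
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"y": data.values, "a": data.factor_a.astype(str),
         "b": data.factor_b.astype(str)}
    )
    if interaction:
        cells = df.groupby(["a", "b"]).size()
        n_a, n_b = df["a"].nunique(), df["b"].nunique()
        if len(cells) < n_a * n_b:
            raise ValueError("empty cells: cannot fit the interaction")
        formula = "y ~ C(a) * C(b)"
    else:
        formula = "y ~ C(a) + C(b)"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(columns={"PR(>F)": "p"})
    return table


def tukey_hsd(data: GroupedData) -> pd.DataFrame:
    """Studentized-range adjusted pairwise comparisons (one-way layout).

    With fewer than 3 groups the adjustment is vacuous and the function
    warns and reduces to a pooled-variance t-test for the single pair.
    """
    labels = list(pd.unique(data.factor_a))
    groups = data.groups()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if len(groups) < 3:
        warnings.warn("fewer than 3 groups: reducing to a two-sample t-test")
        t, p = sps.ttest_ind(groups[0], groups[1])
        return pd.DataFrame(
            [{"group_1": labels[0], "group_2": labels[1],
              "diff": float(np.mean(groups[0]) - np.mean(groups[1])),
              "p_adj": float(p)}]
        )
    res = sps.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append({
                "group_1": labels[i], "group_2": labels[j],
                "diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                "p_adj": float(res.pvalue[i, j]),
            })
    return pd.DataFrame(rows)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the samples")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
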