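"""The strain-comparison statistical battery.

Equal-variance two-sample t-tests, one- and two-way fixed-effects ANOVA,
Bonferroni(-Dunn) pairwise comparisons on the pooled ANOVA error term,
Pearson correlation tested through Student's t-distribution, and the
arcsine-square-root transform for proportions.  All tests are two-sided and
use the exact t/F distribution functions.

Significance stars follow the convention NS (p > 0.05), * (p < 0.05),
** (p < 0.01), *** (p < 0.001); on a boundary the strictest satisfied
category is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass(frozen=True)
class StatResult:
    statistic_name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    flagged: bool = False

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass
class ComparisonMatrix:
    """Pairwise test results over an ordered set of groups (symmetric)."""

    group_labels: list[str]
    cells: dict[tuple[str, str], StatResult]
    adjusted_alpha: float | None = None
    alpha: float = 0.05

    def get(self, a: str, b: str) -> StatResult:
        if a == b:
            raise KeyError("diagonal cells are empty")
        return self.cells[(a, b)] if (a, b) in self.cells else self.cells[(b, a)]

    def significant(self, a: str, b: str) -> bool:
        cut = self.adjusted_alpha if self.adjusted_alpha is not None else self.alpha
        return self.get(a, b).p_value < cut

    def star_frame(self) -> pd.DataFrame:
        """Strain x strain star matrix (the published-table layout)."""
        labels = self.group_labels
        out = pd.DataFrame("-", index=labels, columns=labels)
        for a, b in combinations(labels, 2):
            out.loc[a, b] = out.loc[b, a] = self.get(a, b).stars
        return out

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for a, b in combinations(self.group_labels, 2):
            r = self.get(a, b)
            rows.append({"group_a": a, "group_b": b, "statistic": r.statistic,
                         "p_value": r.p_value, "stars": r.stars})
        return pd.DataFrame(rows)


def t_test_equal_var(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Student's t-test on independent samples assuming equal variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs n >= 2")
    df = len(x) + len(y) - 2
    sp2 = (((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df)
    if sp2 == 0:
        if x.mean() == y.mean():
            return StatResult("t", 0.0, df, 1.0)
        return StatResult("t", np.inf if x.mean() > y.mean() else -np.inf, df, 0.0,
                          flagged=True)
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return StatResult("t", float(t), df, float(p))


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Fixed-effects one-way ANOVA table (between / within rows)."""
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValidationError(f"group {k!r} needs n >= 2")
    alldata = np.concatenate(list(arrays.values()))
    grand = alldata.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df_between = len(arrays) - 1
    df_within = len(alldata) - len(arrays)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    if ms_within == 0:
        F, p = (0.0, 1.0) if ms_between == 0 else (np.inf, 0.0)
    else:
        F = ms_between / ms_within
        p = float(sps.f.sf(F, df_between, df_within))
    return pd.DataFrame(
        {"df": [df_between, df_within],
         "sum_sq": [ss_between, ss_within],
         "mean_sq": [ms_between, ms_within],
         "F": [F, np.nan], "p": [p, np.nan]},
        index=["between_groups", "within_groups"])


def two_way_anova(values: Sequence[float], factor_a: Sequence,
                  factor_b: Sequence) -> pd.DataFrame:
    """Fixed-effects crossed two-way ANOVA (e.g. strain x time bin).

    Requires a fully crossed design with at least one observation per cell;
    an empty cell raises an error naming the cell.  Returns a table with
    rows ``factor_a``, ``factor_b``, ``interaction`` and ``residual`` and
    columns df, sum_sq, mean_sq, F, p.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "a": list(factor_a), "b": list(factor_b)})
    cells = df.groupby(["a", "b"], observed=True).size()
    full = pd.MultiIndex.from_product([df["a"].unique(), df["b"].unique()])
    missing = full.difference(cells.index)
    if len(missing) > 0:
        a0, b0 = missing[0]
        raise ValidationError(f"empty design cell (a={a0!r}, b={b0!r})")
    model = smf.ols("value ~ C(a) * C(b)", data=df).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(index={"C(a)": "factor_a", "C(b)": "factor_b",
                                "C(a):C(b)": "interaction", "Residual": "residual"},
                         columns={"PR(>F)": "p"})
    table["mean_sq"] = table["sum_sq"] / table["df"]
    # a residual SS at numerical-noise level means a saturated (noise-free)
    # design: F is undefined, flagged as NaN
    total_ss = float(table["sum_sq"].sum())
    if table.loc["residual", "sum_sq"] <= 1e-12 * max(total_ss, 1.0):
        table.loc[["factor_a", "factor_b", "interaction"], ["F", "p"]] = np.nan
    return table[["df", "sum_sq", "mean_sq", "F", "p"]]


def bonferroni_dunn(groups: Mapping[str, Sequence[float]],
                    alpha: float = 0.05) -> ComparisonMatrix:
    """All pairwise mean comparisons on the pooled one-way ANOVA error term.

    Each pair is tested with t = (mean_i - mean_j) /
    sqrt(MS_error (1/n_i + 1/n_j)) at the error df; significance is declared
    at the Bonferroni-adjusted level alpha / n_pairs.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    table = one_way_anova(groups)
    ms_error = float(table.loc["within_groups", "mean_sq"])
    df_error = float(table.loc["within_groups", "df"])
    labels = list(groups)
    n_pairs = len(labels) * (len(labels) - 1) // 2
    adjusted = alpha / n_pairs
    cells = {}
    for a, b in combinations(labels, 2):
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        se = np.sqrt(ms_error * (1.0 / len(xa) + 1.0 / len(xb)))
        if se == 0:
            t = 0.0 if xa.mean() == xb.mean() else np.inf
            p = 1.0 if t == 0.0 else 0.0
            cells[(a, b)] = StatResult("t", t, df_error, p, flagged=se == 0)
            continue
        t = (xa.mean() - xb.mean()) / se
        p = 2.0 * float(sps.t.sf(abs(t), df_error))
        cells[(a, b)] = StatResult("t", float(t), df_error, p)
    return ComparisonMatrix(labels, cells, adjusted_alpha=adjusted, alpha=alpha)


def pearson_test(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson product-moment r tested through Student's t-distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must be paired")
    if len(x) < 3:
        raise ValidationError("Pearson test needs n >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValidationError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return StatResult("r", float(r), len(x) - 2, float(p))


def arcsine_sqrt(p):
    """asin(sqrt(p)) for proportions in [0, 1]; monotone onto [0, pi/2]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValidationError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out
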