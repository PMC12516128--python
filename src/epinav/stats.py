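"""Group comparisons matching the study's figure-legend conventions.

Standard tests are delegated to scipy/statsmodels; this module only maps
a declarative :class:`ComparisonSpec` onto them, applies Bonferroni
correction where named, and renders the usual significance stars
(*P<0.05, **P<0.01, ***P<0.001, ****P<0.0001).  Stars are cosmetic output
only — nothing downstream gates on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonSpec", "ComparisonResult", "compare", "stars", "TESTS"]

TESTS = (
    "mann_whitney",
    "fisher_exact",
    "chi_squared",
    "ks",
    "anova_bonferroni",
    "two_way_anova_bonferroni",
)

_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p: float) -> str:
    for thr, s in _STAR_LEVELS:
        if p < thr:
            return s
    return "ns"


@dataclass(frozen=True)
class ComparisonSpec:
    test: str
    alpha: float = 0.05
    raw_counts: bool = False  # categorical tests operate on raw event counts

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise ValueError(f"unknown test {self.test!r}; expected one of {TESTS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    stars: str
    n_groups: int
    pairwise: dict = field(default_factory=dict)  # Bonferroni-adjusted


def compare(spec: ComparisonSpec, data) -> ComparisonResult:
    """Run the named test on grouped data.

    Data shapes: two samples (mann_whitney, ks), a 2x2 or RxC integer
    table (fisher_exact, chi_squared), a list of >=3 samples
    (anova_bonferroni), or a tidy table of (value, factor_a, factor_b)
    columns (two_way_anova_bonferroni).
    """
    t = spec.test
    if t == "mann_whitney":
        a, b = _two_samples(data)
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return _result(t, res.statistic, res.pvalue, 2)
    if t == "ks":
        a, b = _two_samples(data)
        res = sps.ks_2samp(a, b)
        return _result(t, res.statistic, res.pvalue, 2)
    if t == "fisher_exact":
        table = _count_table(data)
        if table.shape != (2, 2):
            raise ValueError("Fisher's exact test needs a 2x2 raw-count table")
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return _result(t, odds, p, 2)
    if t == "chi_squared":
        table = _count_table(data)
        chi2, p, _, _ = sps.chi2_contingency(table)
        return _result(t, chi2, p, table.shape[0])
    if t == "anova_bonferroni":
        groups = [np.asarray(g, dtype=float) for g in data]
        if len(groups) < 2:
            raise ValueError("ANOVA needs at least two groups")
        res = sps.f_oneway(*groups)
        out = _result(t, res.statistic, res.pvalue, len(groups))
        m = len(groups) * (len(groups) - 1) // 2
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                tt = sps.ttest_ind(groups[i], groups[j])
                p_adj = min(1.0, tt.pvalue * m)
                out.pairwise[(i, j)] = dict(p_adj=p_adj, stars=stars(p_adj))
        return out
    if t == "two_way_anova_bonferroni":
        return _two_way_anova(data)
    raise AssertionError("unreachable")


def _two_samples(data) -> tuple[np.ndarray, np.ndarray]:
    if len(data) != 2:
        raise ValueError("this test needs exactly two groups")
    a, b = (np.asarray(g, dtype=float) for g in data)
    if a.ndim != 1 or b.ndim != 1 or not len(a) or not len(b):
        raise ValueError("groups must be non-empty 1D samples")
    return a, b


def _count_table(data) -> np.ndarray:
    table = np.asarray(data)
    if table.ndim != 2:
        raise ValueError("categorical tests need a 2D count table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or np.any(table < 0):
            raise ValueError("counts must be non-negative integers")
        table = table.astype(int)
    return table


def _two_way_anova(data) -> ComparisonResult:
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame(data)
    required = {"value", "factor_a", "factor_b"}
    if not required.issubset(df.columns):
        raise ValueError(f"two-way ANOVA needs columns {sorted(required)}")
    model = ols("value ~ C(factor_a) * C(factor_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p = float(table.loc["C(factor_a)", "PR(>F)"])
    f = float(table.loc["C(factor_a)", "F"])
    out = _result("two_way_anova_bonferroni", f, p, df["factor_a"].nunique())
    # Bonferroni pairwise across factor_a within each level of factor_b
    levels_b = sorted(df["factor_b"].unique())
    levels_a = sorted(df["factor_a"].unique())
    m = len(levels_b) * len(levels_a) * (len(levels_a) - 1) // 2
    for lb in levels_b:
        sub = df[df["factor_b"] == lb]
        for i, la in enumerate(levels_a):
            for la2 in levels_a[i + 1 :]:
                x = sub[sub["factor_a"] == la]["value"]
                y = sub[sub["factor_a"] == la2]["value"]
                if len(x) < 2 or len(y) < 2:
                    continue
                tt = sps.ttest_ind(x, y)
                p_adj = min(1.0, tt.pvalue * max(m, 1))
                out.pairwise[(la, la2, lb)] = dict(p_adj=p_adj, stars=stars(p_adj))
    return out


def _result(test: str, statistic, p, n_groups: int) -> ComparisonResult:
    return ComparisonResult(
        test=test,
        statistic=float(statistic),
        p_value=float(p),
        stars=stars(float(p)),
        n_groups=n_groups,
    )
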