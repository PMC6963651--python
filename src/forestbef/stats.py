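"""Bivariate layer: OLS, ANCOVA, one-way ANOVA, Pearson correlation.

Thin, typed wrappers over scipy/statsmodels that return tidy summaries.
ANCOVA fits ``y ~ x + group + x:group`` and reports Type II F-tests; with
the covariate dropped it reduces to one-way ANOVA. No multiplicity
correction is applied by default; `adjust_bh` offers Benjamini–Hochberg
for users who want it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r2: float
    f_stat: float
    p_value: float
    n: int


@dataclass
class AncovaSummary:
    """Type II F-tests for covariate, group and interaction terms."""

    table: pd.DataFrame  # term x (sum_sq, df, F, PR(>F))
    ss_type: str = "II"

    def term(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["F"]), float(row["PR(>F)"])


def ols(x, y) -> RegressionSummary:
    """Simple least squares with R^2 and the overall F-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise DegenerateDataError("OLS needs n >= 3")
    if np.var(x) == 0:
        raise DegenerateDataError("zero variance in predictor")
    res = sps.linregress(x, y)
    r2 = res.rvalue**2
    if r2 >= 1.0:
        f = np.inf
        p = 0.0
    else:
        f = (n - 2) * r2 / (1 - r2)
        p = float(sps.f.sf(f, 1, n - 2))
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(r2),
        f_stat=float(f),
        p_value=p,
        n=n,
    )


def _group_frame(y, group, x=None) -> pd.DataFrame:
    df = pd.DataFrame({"y": np.asarray(y, dtype=float), "group": np.asarray(group)})
    if x is not None:
        df["x"] = np.asarray(x, dtype=float)
    counts = df["group"].value_counts()
    if len(counts) < 2:
        raise DegenerateDataError("ANCOVA/ANOVA needs >= 2 groups")
    small = counts[counts < 2].index.tolist()
    if small:
        raise DegenerateDataError(f"group(s) with < 2 points: {small}")
    return df


def ancova(y, x, group) -> AncovaSummary:
    """Heterogeneity-of-slopes ANCOVA: y ~ x + group + x:group, Type II SS."""
    df = _group_frame(y, group, x)
    model = smf.ols("y ~ x + C(group) + x:C(group)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={"C(group)": "group", "x:C(group)": "x:group", "Residual": "residual"}
    )
    return AncovaSummary(table=table)


def anova(y, group) -> AncovaSummary:
    """One-way ANOVA as the no-covariate reduction of the ANCOVA."""
    df = _group_frame(y, group)
    model = smf.ols("y ~ C(group)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(index={"C(group)": "group", "Residual": "residual"})
    return AncovaSummary(table=table)


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise DegenerateDataError("Pearson correlation needs n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateDataError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def correlation_table(
    left: pd.DataFrame, right: pd.DataFrame, adjust_bh: bool = False
) -> pd.DataFrame:
    """Tidy all-pairs Pearson correlations between two column blocks."""
    rows = []
    for a in left.columns:
        for b in right.columns:
            r, p = pearson(left[a], right[b])
            rows.append({"var_a": a, "var_b": b, "r": r, "p_value": p})
    out = pd.DataFrame(rows)
    if adjust_bh:
        out["p_adj_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
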