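"""Cohort-level assessment statistics.

The value of GC correction is judged by how tightly a profile feature
tracks tumor fraction across a cohort: for each site list the feature is
regressed on tumor fraction (Pearson r, line of best fit, RMSE of that
fit), p-values are BH-adjusted per feature type, and the paired RMSEs
before vs after correction are compared with a two-sided Wilcoxon
signed-rank test.  Differential accessibility between phenotype groups is
tested by ANCOVA with tumor fraction as a covariate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float
    rmse: float
    p_adjusted: float = float("nan")


@dataclass
class AncovaResult:
    f_group: float
    p_group: float
    covariate_coef: float
    covariate_p: float


def correlate_vs_tumor_fraction(
    values: Sequence[float], tumor_fractions: Sequence[float]
) -> CorrelationResult:
    """Least-squares fit of a feature on tumor fraction.

    RMSE is computed from the residuals of the fitted line; the Pearson
    p-value is two-sided via the t transform (scipy's convention).
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(tumor_fractions, dtype=float)
    fit = sps.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return CorrelationResult(
        float(fit.rvalue), float(fit.pvalue), float(fit.slope), float(fit.intercept), rmse
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def paired_wilcoxon(before: Sequence[float], after: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 non-zero differences (when there are no ties) and the normal
    approximation with continuity correction above.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    d = b - a
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("no nonzero differences")
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "approx" if (len(d) > 25 or has_ties) else "exact"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return float(res.statistic), float(res.pvalue)


def mad(values: Sequence[float]) -> float:
    """Mean absolute deviation about the mean."""
    x = np.asarray(values, dtype=float)
    return float(np.mean(np.abs(x - x.mean())))


def ancova(
    feature: Sequence[float], groups: Sequence, covariate: Sequence[float]
) -> AncovaResult:
    """OLS model ``feature ~ group + covariate`` with a Type II F-test.

    Returns the F statistic and p-value of the group term plus the
    covariate coefficient and its p-value.  No interaction term is fitted.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame(
        {"y": np.asarray(feature, float), "g": pd.Categorical(groups), "x": np.asarray(covariate, float)}
    )
    model = smf.ols("y ~ C(g) + x", data=df).fit()
    table = anova_lm(model, typ=2)
    return AncovaResult(
        float(table.loc["C(g)", "F"]),
        float(table.loc["C(g)", "PR(>F)"]),
        float(model.params["x"]),
        float(model.pvalues["x"]),
    )


def compare_correction_modes(
    before: pd.DataFrame,
    after: pd.DataFrame,
    tumor_fractions: Sequence[float],
) -> Dict:
    """Per-site-list tumor-fraction fits before vs after GC correction.

    ``before``/``after``: samples x site-list feature tables (e.g. central
    coverage).  Returns a per-site-list table of RMSE and MAD before/after,
    BH-adjusted correlation p-values, the fraction of site lists whose RMSE
    decreased, and a Wilcoxon summary of the paired RMSEs (flagged
    degenerate when the tables are identical).
    """
    if list(before.columns) != list(after.columns):
        raise ValueError("before/after tables must share site-list columns")
    tf = np.asarray(tumor_fractions, dtype=float)
    rows = []
    for col in before.columns:
        rb = correlate_vs_tumor_fraction(before[col].to_numpy(), tf)
        ra = correlate_vs_tumor_fraction(after[col].to_numpy(), tf)
        rows.append(
            {
                "site_list": col,
                "r_before": rb.r,
                "r_after": ra.r,
                "p_before": rb.p,
                "p_after": ra.p,
                "rmse_before": rb.rmse,
                "rmse_after": ra.rmse,
                "mad_before": mad(before[col]),
                "mad_after": mad(after[col]),
            }
        )
    table = pd.DataFrame(rows).set_index("site_list")
    table["p_adj_before"] = bh_adjust(table["p_before"])
    table["p_adj_after"] = bh_adjust(table["p_after"])
    reduced = table["rmse_after"] < table["rmse_before"]
    out = {
        "table": table,
        "fraction_rmse_reduced": float(reduced.mean()),
        "wilcoxon": None,
        "degenerate": False,
    }
    try:
        out["wilcoxon"] = paired_wilcoxon(table["rmse_before"], table["rmse_after"])
    except ValueError:
        out["degenerate"] = True
    return out
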