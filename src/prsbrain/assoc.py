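"""Covariate-adjusted association statistics and group comparisons.

Multiple linear regression of an outcome (region-wise ALFF or an emotion
score) on a PRS with age, sex, education, disease status and four ancestry
PCs as covariates; the reported effect is the signed partial correlation
r = t / sqrt(t^2 + df) of the score coefficient.  Also: PRS x status
interaction tests, Bonferroni correction (family of 90 regions for ALFF,
4 scores for emotion), and the pooled two-sample t and Pearson chi-square
tests used for case-control sample description.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

ALFF_FAMILY = 90      # one test per AAL region
EMOTION_FAMILY = 4    # positive, neutral, negative, total


@dataclass
class AssociationResult:
    outcome: str
    beta: float
    se: float
    t: float
    df: int
    partial_r: float
    p_uncorrected: float
    p_corrected: float | None = None
    m_tests: int | None = None
    p_t: float | None = None
    score_label: str | None = None


@dataclass
class GroupTestResult:
    variable: str
    statistic: float
    df: int
    p: float
    summaries: dict | None = None


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected P: min(1, p * m)."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return float(min(1.0, p * m))


def fit_assoc(y: np.ndarray, score: np.ndarray,
              covars: pd.DataFrame | np.ndarray | None = None,
              outcome: str = "y", m_tests: int | None = None) -> AssociationResult:
    """OLS of y on [intercept, score, covariates]; score-coefficient stats.

    The partial correlation is t / sqrt(t^2 + df) with df the residual
    degrees of freedom, carrying the sign of the coefficient (equivalent,
    by Frisch-Waugh, to the plain correlation of the two covariate-residual
    vectors).
    """
    y = np.asarray(y, dtype=float)
    score = np.asarray(score, dtype=float)
    blocks = [score[:, None]]
    if covars is not None:
        c = covars.to_numpy(dtype=float) if isinstance(covars, pd.DataFrame) \
            else np.asarray(covars, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        blocks.append(c)
    x = sm.add_constant(np.column_stack(blocks), has_constant="add")
    n, p_model = x.shape
    if n <= p_model + 1:
        raise ValueError("too few complete cases for the design")
    if np.linalg.matrix_rank(x) < p_model:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(y, x).fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    t = float(fit.tvalues[1])
    df = int(fit.df_resid)
    partial_r = t / np.sqrt(t * t + df)
    p_unc = float(fit.pvalues[1])
    res = AssociationResult(outcome=outcome, beta=beta, se=se, t=t, df=df,
                            partial_r=float(partial_r), p_uncorrected=p_unc)
    if m_tests is not None:
        res.m_tests = m_tests
        res.p_corrected = bonferroni(p_unc, m_tests)
    return res


def interaction_test(y: np.ndarray, score: np.ndarray, status: np.ndarray,
                     covars: pd.DataFrame | np.ndarray | None = None) -> float:
    """Two-sided P of the score x status product term.

    OLS of y on [intercept, score, status, score*status, covariates];
    invariant to affine recoding of status.
    """
    y = np.asarray(y, dtype=float)
    score = np.asarray(score, dtype=float)
    status = np.asarray(status, dtype=float)
    groups, counts = np.unique(status, return_counts=True)
    if len(groups) < 2:
        raise ValueError("interaction test needs both status groups")
    if counts.min() < 10:
        raise ValueError("each status group needs >= 10 subjects")
    blocks = [score[:, None], status[:, None], (score * status)[:, None]]
    if covars is not None:
        c = covars.to_numpy(dtype=float) if isinstance(covars, pd.DataFrame) \
            else np.asarray(covars, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        blocks.append(c)
    x = sm.add_constant(np.column_stack(blocks), has_constant="add")
    fit = sm.OLS(y, x).fit()
    return float(fit.pvalues[3])


def two_sample_t(mean1: float | np.ndarray, sd1: float | None = None,
                 n1: int | None = None, mean2: float | np.ndarray | None = None,
                 sd2: float | None = None, n2: int | None = None,
                 variable: str = "x") -> GroupTestResult:
    """Pooled-variance two-sample t test (df = n1 + n2 - 2).

    Accepts either printed summaries (mean, SD, n per group) or two raw
    vectors as the first and fourth arguments.
    """
    if sd1 is None:  # raw-vector form: two_sample_t(x1, mean2=x2)
        x1 = np.asarray(mean1, dtype=float)
        x2 = np.asarray(mean2, dtype=float)
        mean1, sd1, n1 = x1.mean(), x1.std(ddof=1), len(x1)
        mean2, sd2, n2 = x2.mean(), x2.std(ddof=1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = float((mean1 - mean2) / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return GroupTestResult(variable=variable, statistic=t, df=df, p=p,
                           summaries={"mean1": mean1, "sd1": sd1, "n1": n1,
                                      "mean2": mean2, "sd2": sd2, "n2": n2})


def chi_square_test(table: np.ndarray, variable: str = "x") -> GroupTestResult:
    """Pearson chi-square on a 2 x k contingency table, df = k - 1,
    without continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x k contingency table")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected <= 0):
        raise ValueError("zero expected cell count")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return GroupTestResult(variable=variable, statistic=float(chi2),
                           df=int(df), p=float(p))


def associate_regions(alff: pd.DataFrame, score: np.ndarray,
                      covars: pd.DataFrame,
                      m_tests: int = ALFF_FAMILY) -> pd.DataFrame:
    """fit_assoc for every ALFF region column; tidy results, Bonferroni
    over the region family."""
    rows = []
    for region in alff.columns:
        r = fit_assoc(alff[region].to_numpy(), score, covars,
                      outcome=str(region), m_tests=m_tests)
        rows.append((r.outcome, r.beta, r.t, r.df, r.partial_r,
                     r.p_uncorrected, r.p_corrected))
    return pd.DataFrame(rows, columns=["region", "beta", "t", "df",
                                       "partial_r", "p_uncorrected",
                                       "p_corrected"]).set_index("region")
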