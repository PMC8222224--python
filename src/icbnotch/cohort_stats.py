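"""Benefit-association statistics.

Two-group comparisons of scores between clinical-benefit (CB) and
no-clinical-benefit (NCB) samples use the two-tailed Mann-Whitney U
test; 2x2 category-vs-benefit tables use the Pearson chi-squared test
or the two-sided Fisher exact test (probability-mass rule); continuous
pairs use Pearson correlation. The multivariable benefit model regresses
CB on z-scored signature covariates (logistic by default) and adjusts
the covariate p-values with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io_formats import ValidationError

__all__ = [
    "TwoByTwoTable",
    "MultivariableResult",
    "mann_whitney_cb",
    "chi2_2x2",
    "fisher_exact_2x2",
    "pearson_correlation",
    "bh_fdr",
    "multivariable_benefit_model",
    "BENEFIT_MODEL_COVARIATES",
]

#: covariate order of the default benefit model
BENEFIT_MODEL_COVARIATES = ("Notch", "Immune", "NE", "MYC", "EZH2")


@dataclass
class TwoByTwoTable:
    """Counts (a, b; c, d): rows = in-category / not, columns = CB / NCB."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValidationError(f"2x2 counts must be non-negative integers, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("2x2 table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class MultivariableResult:
    """Per-covariate estimates of the multivariable benefit model.

    ``table`` has one row per covariate with columns estimate,
    statistic, p and fdr; ``converged`` is False when the likelihood
    maximization failed (e.g. perfect separation), in which case the
    p and fdr columns are NaN rather than raising.
    """

    table: pd.DataFrame
    family: str
    converged: bool
    n_samples: int


def _split_by_benefit(values: pd.Series, benefit: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    benefit = benefit.reindex(values.index)
    if benefit.isna().any():
        missing = values.index[benefit.isna()][0]
        raise ValidationError(f"no benefit label for sample {missing!r}")
    cb = values[benefit == "CB"].to_numpy(dtype=float)
    ncb = values[benefit == "NCB"].to_numpy(dtype=float)
    if len(cb) == 0 or len(ncb) == 0:
        raise ValidationError("both benefit groups must be non-empty")
    return cb, ncb


def mann_whitney_cb(values: pd.Series, benefit: pd.Series) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U of a score between CB and NCB samples.

    The exact null distribution is used for combined n <= 20 without
    ties; otherwise the normal approximation with tie correction.
    Returns (U of the CB group, two-sided p).
    """
    cb, ncb = _split_by_benefit(values, benefit)
    pooled = np.concatenate([cb, ncb])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(cb, ncb, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi2_2x2(t: TwoByTwoTable, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, 1 df, Yates only on request."""
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("2x2 table has a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return float(chi2), float(p)


def fisher_exact_2x2(t: TwoByTwoTable) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities
    of all tables with the observed margins that are no more probable
    than the observed table."""
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("2x2 table has a zero margin")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided t-distribution p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and paired")
    if len(x) < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in one of the variables")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw,
    capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p-values must be a non-empty 1-D sequence")
    if (p <= 0).any() or (p > 1).any():
        bad = p[(p <= 0) | (p > 1)][0]
        raise ValidationError(f"p-values must lie in (0, 1], got {bad}")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def multivariable_benefit_model(
    scores: pd.DataFrame,
    benefit: pd.Series,
    family: str = "logit",
) -> MultivariableResult:
    """Multivariable model of clinical benefit on signature covariates.

    ``scores`` is samples x covariates (typically Notch, immune and NE
    signature scores plus MYC and EZH2 expression). Covariates are
    z-scored across the cohort before fitting, matching the cross-cohort
    z-combination of the inputs, so estimates are per-SD effects.
    ``family='logit'`` fits logistic regression and reports Wald z
    statistics; ``family='ols'`` fits a linear probability model and
    reports t statistics. FDR is Benjamini-Hochberg over the covariate
    p-values (intercept excluded).

    Perfect separation or non-convergence under logit is reported as a
    flagged result (``converged=False``, NaN p-values), not an exception.
    """
    if family not in ("logit", "ols"):
        raise ValidationError(f"family must be 'logit' or 'ols', got {family!r}")
    benefit = benefit.reindex(scores.index)
    if benefit.isna().any():
        missing = scores.index[benefit.isna()][0]
        raise ValidationError(f"no benefit label for sample {missing!r}")
    bad = sorted(set(benefit) - {"CB", "NCB"})
    if bad:
        raise ValidationError(f"unknown benefit label(s) {bad}")
    y = (benefit == "CB").astype(float).to_numpy()
    if scores.shape[0] < scores.shape[1] + 2:
        raise ValidationError(
            f"need at least {scores.shape[1] + 2} samples for {scores.shape[1]} covariates"
        )
    # population SD so the standardization (and hence the estimates) is
    # invariant under sample duplication
    sd = scores.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValidationError(f"constant covariate {sd.index[sd == 0][0]!r}")
    Xz = (scores - scores.mean(axis=0)) / sd
    X = sm.add_constant(Xz.to_numpy(dtype=float))
    names = list(scores.columns)

    converged = True
    if family == "logit":
        model = sm.Logit(y, X)
        try:
            fit = model.fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            fit = None
            converged = False
        if fit is None or not converged:
            if fit is None:
                est = np.full(len(names), np.nan)
                stat = np.full(len(names), np.nan)
            else:
                est = fit.params[1:]
                stat = np.full(len(names), np.nan)
            table = pd.DataFrame(
                {
                    "estimate": est,
                    "statistic": stat,
                    "p": np.nan,
                    "fdr": np.nan,
                },
                index=pd.Index(names, name="covariate"),
            )
            return MultivariableResult(
                table=table, family=family, converged=False, n_samples=len(y)
            )
        est, stat, p = fit.params[1:], fit.tvalues[1:], fit.pvalues[1:]
    else:
        fit = sm.OLS(y, X).fit()
        est, stat, p = fit.params[1:], fit.tvalues[1:], fit.pvalues[1:]

    p = np.clip(np.asarray(p, dtype=float), np.nextafter(0, 1), 1.0)
    table = pd.DataFrame(
        {"estimate": est, "statistic": stat, "p": p, "fdr": bh_fdr(p)},
        index=pd.Index(names, name="covariate"),
    )
    return MultivariableResult(table=table, family=family, converged=converged, n_samples=len(y))
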