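"""Confirmation-stage statistics.

The central model is a weighted logistic regression under the
frequency-weight convention: the sampling weights (7.692 inpatient, 100
outpatient) multiply each record's Bernoulli log-likelihood,

    l(beta) = sum_i w_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ],

so a weighted fit behaves like a fit to the expanded source population.
Standard errors come from the inverse of the weighted information matrix
(model-based); a robust sandwich variance is available as an option since
survey analyses differ on this point.  Also provided: crude 2x2 odds
ratios with Woolf confidence intervals, chi-square and Fisher's exact
tests for categorical comparisons, a Welch-style weighted t-test using
Kish effective sample sizes, and mean imputation for missing covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .claims import ClaimsError
from .synth import cross_product_or

log = logging.getLogger(__name__)

Z95 = scipy.stats.norm.ppf(0.975)


class SeparationError(ClaimsError):
    """A predictor perfectly predicts the outcome; the MLE does not exist."""


class ConvergenceError(ClaimsError):
    """The iteratively reweighted least-squares fit failed to converge."""


@dataclass
class AssociationResult:
    """Odds ratio with 95% Wald confidence interval for one model term."""

    term: str
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool
    beta: float = float("nan")
    se: float = float("nan")

    def __post_init__(self) -> None:
        if not self.ci_low <= self.or_estimate <= self.ci_high:
            raise ClaimsError(
                f"{self.term}: CI ({self.ci_low}, {self.ci_high}) does not "
                f"bracket the estimate {self.or_estimate}"
            )


def mean_impute(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Replace missing entries by each column's observed (unweighted) mean.

    Returns the imputed frame and the per-column imputation counts; raises
    on an all-missing column.
    """
    out = df.copy()
    counts: dict[str, int] = {}
    for col in out.columns:
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        if n_missing == len(out):
            raise ClaimsError(f"column {col!r} has no observed values")
        out[col] = out[col].fillna(out[col].mean())
        counts[col] = n_missing
        log.info("mean_impute: imputed %d value(s) in %r", n_missing, col)
    return out, counts


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    for col in X.columns:
        x = X[col].to_numpy()
        vals = np.unique(x)
        if len(vals) != 2:
            continue
        y1 = y[x == vals[1]]
        y0 = y[x == vals[0]]
        if (
            y1.size
            and y0.size
            and len(np.unique(y1)) == 1
            and len(np.unique(y0)) == 1
            and y1[0] != y0[0]
        ):
            raise SeparationError(f"term {col!r} perfectly predicts the outcome")


def weighted_logistic(
    X: pd.DataFrame,
    y,
    weights=None,
    *,
    robust: bool = False,
    maxiter: int = 100,
    gtol: float = 1e-8,
) -> list[AssociationResult]:
    """Fit the weighted logistic model and return per-term odds ratios.

    ``X`` holds the named predictor columns (an intercept is added);
    ``weights`` are frequency weights multiplying the log-likelihood
    (default 1).  The fit is iteratively reweighted least squares followed
    by Newton refinement until the score's max-norm falls below ``gtol``
    (scaled by the largest weight); odds ratios are exp(beta) with Wald
    95% intervals from the model-based inverse-information covariance or,
    with ``robust``, the sampling-weight sandwich.  The intercept is not
    reported.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ClaimsError("outcome must contain both classes")
    X = X.astype(float)
    if X.isna().any().any():
        raise ClaimsError("missing predictor values; run mean_impute first")
    _check_separation(X, y)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ClaimsError("weights must be positive")

    design = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, design, family=sm.families.Binomial(), freq_weights=w)
    try:
        fit = model.fit(maxiter=maxiter)
    except PerfectSeparationError as exc:
        raise SeparationError(str(exc)) from exc

    # Newton refinement to an explicit gradient criterion (IRLS's deviance
    # criterion can stall at float precision on heavily weighted data)
    Xd = design.to_numpy()
    beta_vec = np.asarray(fit.params, dtype=float)
    scale = gtol * max(1.0, float(w.max()))
    for _ in range(maxiter):
        p = expit(Xd @ beta_vec)
        score = Xd.T @ (w * (y - p))
        if np.max(np.abs(score)) < scale:
            break
        H = (Xd * (w * p * (1 - p))[:, None]).T @ Xd
        beta_vec = beta_vec + np.linalg.solve(H, score)
    else:
        raise ConvergenceError(f"IRLS did not converge in {maxiter} iterations")

    p = expit(Xd @ beta_vec)
    H = (Xd * (w * p * (1 - p))[:, None]).T @ Xd
    Hinv = np.linalg.inv(H)
    if robust:
        # sampling-weight sandwich: H^-1 (sum (w_i s_i)(w_i s_i)') H^-1,
        # with s_i the unweighted per-record score
        B = (Xd * ((w * (y - p)) ** 2)[:, None]).T @ Xd
        cov = Hinv @ B @ Hinv
    else:
        cov = Hinv
    params = pd.Series(beta_vec, index=design.columns)
    bse = pd.Series(np.sqrt(np.diag(cov)), index=design.columns)

    results = []
    for term in X.columns:
        beta = float(params[term])
        se = float(bse[term])
        results.append(
            AssociationResult(
                term=str(term),
                or_estimate=float(np.exp(beta)),
                ci_low=float(np.exp(beta - Z95 * se)),
                ci_high=float(np.exp(beta + Z95 * se)),
                p_value=float(2 * scipy.stats.norm.sf(abs(beta / se))),
                adjusted=X.shape[1] > 1,
                beta=beta,
                se=se,
            )
        )
    return results


def crude_or(
    outcome, flag, weights=None, *, term: str = "flag", robust: bool = False
) -> AssociationResult:
    """Single-predictor odds ratio for a binary flag.

    Unweighted: the 2x2 cross-product ratio with the Woolf interval
    exp(log OR +- 1.96 * sqrt(sum 1/n_ij)) (+0.5 correction on a zero
    cell, with a warning).  Weighted: an intercept + flag weighted
    logistic fit.
    """
    y = np.asarray(outcome, dtype=int)
    x = np.asarray(flag, dtype=int)
    if y.shape != x.shape:
        raise ClaimsError("outcome and flag must have equal length")
    if len(np.unique(y)) < 2 or len(np.unique(x)) < 2:
        raise ClaimsError("both outcome and flag must contain both classes")
    if weights is not None:
        res = weighted_logistic(pd.DataFrame({term: x}), y, weights, robust=robust)[0]
        res.adjusted = False
        return res

    n11 = float(np.sum((x == 1) & (y == 1)))
    n10 = float(np.sum((x == 1) & (y == 0)))
    n01 = float(np.sum((x == 0) & (y == 1)))
    n00 = float(np.sum((x == 0) & (y == 0)))
    cells = np.array([n11, n10, n01, n00])
    if cells.min() == 0:
        log.warning("crude_or: zero cell, applying +0.5 correction")
        cells = cells + 0.5
    n11, n10, n01, n00 = cells
    or_est = cross_product_or(n11, n10, n01, n00)
    log_or = np.log(or_est)
    se = float(np.sqrt((1 / cells).sum()))
    z = log_or / se
    p = 2 * scipy.stats.norm.sf(abs(z))
    return AssociationResult(
        term=term,
        or_estimate=float(or_est),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        p_value=float(p),
        adjusted=False,
        beta=float(log_or),
        se=se,
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric enumeration)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ClaimsError("fisher_exact requires a non-negative 2x2 table")
    return float(scipy.stats.fisher_exact(t, alternative="two-sided")[1])


def chi_square_test(table, *, fisher_fallback: bool = True) -> float:
    """Pearson chi-square p (no continuity correction) for a 2xk table.

    When any expected cell count is below 5 and the table is 2x2, falls
    back to Fisher's exact test (logged).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ClaimsError("table must be a non-negative 2-d array")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ClaimsError("degenerate table: a row or column margin is zero")
    expected = scipy.stats.contingency.expected_freq(t)
    if fisher_fallback and t.shape == (2, 2) and (expected < 5).any():
        log.info("chi_square_test: expected cell < 5, using Fisher's exact test")
        return fisher_exact(t.astype(int))
    stat, p, _, _ = scipy.stats.chi2_contingency(t, correction=False)
    return float(p)


@dataclass
class WeightedTTestResult:
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    t_statistic: float
    df: float
    p_value: float


def weighted_t_test(x, wx, y, wy) -> WeightedTTestResult:
    """Welch-style weighted t-test on Kish effective sample sizes.

    Weighted means sum(w v)/sum(w); weighted variances with the
    reliability-weight (unbiased) normalization; effective sample sizes
    n_eff = (sum w)^2 / sum w^2; Welch-Satterthwaite degrees of freedom on
    the effective sizes.  With unit weights this is exactly Welch's
    t-test.
    """
    x, wx = np.asarray(x, float), np.asarray(wx, float)
    y, wy = np.asarray(y, float), np.asarray(wy, float)
    for v, w, name in ((x, wx, "A"), (y, wy, "B")):
        if w.sum() <= 0:
            raise ClaimsError(f"group {name}: weight sum must be positive")
        if len(np.unique(v)) < 2:
            raise ClaimsError(f"group {name}: needs >= 2 distinct values")

    def _stats(v, w):
        sw = w.sum()
        mean = float((w * v).sum() / sw)
        # unbiased under reliability weights; equals /(n-1) for unit weights
        var = float((w * (v - mean) ** 2).sum() / (sw - (w**2).sum() / sw))
        n_eff = float(sw**2 / (w**2).sum())
        return mean, var, n_eff

    ma, va, na = _stats(x, wx)
    mb, vb, nb = _stats(y, wy)
    se2a, se2b = va / na, vb / nb
    if se2a + se2b == 0:
        return WeightedTTestResult(ma, 0.0, mb, 0.0, 0.0, na + nb - 2, 1.0)
    tstat = (ma - mb) / np.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    p = 2 * scipy.stats.t.sf(abs(tstat), df)
    return WeightedTTestResult(
        mean_a=ma,
        se_a=float(np.sqrt(se2a)),
        mean_b=mb,
        se_b=float(np.sqrt(se2b)),
        t_statistic=float(tstat),
        df=float(df),
        p_value=float(p),
    )


#: Covariates entering every adjusted model: 5-year age band (single
#: ordinal term), data year (single linear term) and the low-SES flag.
ADJUSTMENT_COVARIATES = ("age_band_5y", "year", "low_ses")


def _design(cohort_df: pd.DataFrame, flag_names: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "age_band_5y": cohort_df["age_band_5y"].astype(float),
            "year": cohort_df["year"].astype(float) - cohort_df["year"].min(),
            "low_ses": cohort_df["low_ses"].astype(float),
        }
    )
    for name in flag_names:
        X[name] = cohort_df[name].astype(float)
    return X


def run_confirmation(
    cohort,
    level: str = "category",
    *,
    significance: float = 0.05,
    robust: bool = True,
) -> list[AssociationResult]:
    """Crude and adjusted odds ratios for every candidate disease.

    Stage 1 fits one weighted intercept + flag model per disease (crude
    odds ratios).  Stage 2 fits a single multivariable weighted logistic
    model with age band, data year, low SES and *all* candidate flags
    simultaneously.  At ``level="full"`` (candidate categories expanded
    to full diagnosis codes upstream), a final model keeping only the
    disease terms significant (p < ``significance``) in stage 2, plus the
    covariates, is refit and reported.  Standard errors default to the
    sampling-weight sandwich; set ``robust=False`` for the model-based
    frequency-weight variance.  Returns crude results (adjusted=False)
    followed by adjusted results (adjusted=True) in term order.
    """
    if level not in ("category", "full"):
        raise ClaimsError("level must be 'category' or 'full'")
    df = cohort.data
    y = df["case"].astype(int).to_numpy()
    w = df["weight"].to_numpy(float)
    names = list(cohort.disease_names)

    crude = [
        crude_or(y, df[name].astype(int).to_numpy(), w, term=name, robust=robust)
        for name in names
    ]

    full_fit = weighted_logistic(_design(df, names), y, w, robust=robust)
    if level == "full":
        by_term = {r.term: r for r in full_fit}
        keep = [n for n in names if by_term[n].p_value < significance]
        dropped = [n for n in names if n not in keep]
        if dropped and keep:
            log.info("run_confirmation: refitting without %s", dropped)
            final_fit = weighted_logistic(_design(df, keep), y, w, robust=robust)
        else:
            final_fit = full_fit
    else:
        final_fit = full_fit
    return crude + list(final_fit)


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Pivot crude/adjusted results into one row per term.

    Columns mirror a published odds-ratio table: unadjusted OR (95% CI)
    and p, adjusted OR (95% CI) and p.
    """
    crude = {r.term: r for r in results if not r.adjusted}
    adj = {r.term: r for r in results if r.adjusted}
    terms = list(dict.fromkeys([r.term for r in results]))

    def _fmt(r: AssociationResult | None) -> tuple[str, float]:
        if r is None:
            return "", float("nan")
        return (
            f"{r.or_estimate:.2f} ({r.ci_low:.2f}–{r.ci_high:.2f})",
            r.p_value,
        )

    rows = []
    for term in terms:
        u, up = _fmt(crude.get(term))
        a, ap = _fmt(adj.get(term))
        rows.append(
            {
                "term": term,
                "unadjusted_or_ci": u,
                "unadjusted_p": up,
                "adjusted_or_ci": a,
                "adjusted_p": ap,
            }
        )
    return pd.DataFrame(rows)
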