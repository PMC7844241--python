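"""Univariate PGS association analyses.

Logistic regression of a binary outcome on one corrected (standardized)
polygenic score with age, age^2 and sex covariates; effect sizes reported as
the odds ratio per SD of score with Wald 95% confidence intervals.  Also
here: the Bonferroni cutoff for the score x cohort test battery, score x
modifier interaction tests with age-bin stratified odds ratios, decile
contrasts, Nagelkerke delta-R^2, sensitivity refits under row exclusions or
extra covariates, and linear models for quantitative symptom scales.

Age is centered before squaring (reduces collinearity between the linear and
quadratic terms; estimates for the score are unchanged).  Sex enters as an
indicator.  Deciles use empirical quantiles with ties assigned to the lower
decile, computed within the analysis cohort after exclusions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_COVARS = ("age", "age2", "sex")
DEFAULT_AGE_BINS = ((8.0, 12.0), (12.0, 16.0), (16.0, 22.0))


class AssocError(ValueError):
    pass


@dataclass
class AssocResult:
    trait: str
    cohort: str
    n: int
    or_per_sd: float
    ci95: tuple
    p: float
    beta: float
    se: float
    covariates: tuple
    nagelkerke_delta_r2: float | None = None
    notes: str = ""
    wald: bool = True           # False when a penalized fallback was used

    def __post_init__(self):
        lo, hi = self.ci95
        if self.wald and not (lo <= self.or_per_sd <= hi):
            raise AssocError("CI does not bracket the OR")


def _design(data: pd.DataFrame, covars: tuple) -> np.ndarray:
    """Covariate design matrix; 'age2' means centered-age squared."""
    cols = []
    age_c = None
    if "age" in covars or "age2" in covars:
        age_c = data["age"].to_numpy(float) - data["age"].to_numpy(float).mean()
    for c in covars:
        if c == "age":
            cols.append(age_c)
        elif c == "age2":
            cols.append(age_c ** 2)
        elif c == "sex":
            s = data["sex"]
            cols.append((s == s.iloc[0]).to_numpy(float) if s.dtype == object
                        else s.to_numpy(float))
        else:
            cols.append(data[c].to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(data), 0))


def _logit_fit(y: np.ndarray, X: np.ndarray):
    """Maximum-likelihood logistic fit; penalized fallback on separation."""
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
        if np.all(np.isfinite(res.bse)) and np.all(np.isfinite(res.params)) \
                and np.all(res.bse < 1e3):
            return res, True
    except Exception:                                    # noqa: BLE001
        pass
    logger.warning("logistic fit unstable (possible separation); "
                   "using L2-penalized fallback")
    res = model.fit_regularized(disp=0, alpha=1e-4, L1_wt=0.0, maxiter=500)
    return res, False


def fit_univariate(score, outcome, covars: tuple = DEFAULT_COVARS,
                   data: pd.DataFrame | None = None, trait: str = "",
                   cohort: str = "") -> AssocResult:
    """Logistic regression of a binary outcome on one standardized score.

    ``score``/``outcome`` may be arrays or column names into ``data``.
    Returns the OR per SD with Wald 95% CI and two-sided Wald p.  Rows with
    missing values in any used column are dropped (complete-case), with the
    resulting n recorded.
    """
    if isinstance(score, str):
        score = data[score]
    if isinstance(outcome, str):
        outcome = data[outcome]
    s = np.asarray(score, float)
    y = np.asarray(outcome, float)
    if data is None:
        data = pd.DataFrame(index=range(len(s)))
        covars = tuple(c for c in covars if c in data.columns)
    used = pd.DataFrame({"_s": s, "_y": y}, index=data.index)
    for c in covars:
        col = "age" if c == "age2" else c
        if col in data.columns:
            used[c] = data[col] if c != "age2" else data["age"]
    keep = ~used.isna().any(axis=1)
    d = data.loc[keep]
    s, y = s[keep.to_numpy()], y[keep.to_numpy()]
    if len(np.unique(y)) < 2:
        raise AssocError("outcome is constant")
    Z = _design(d, covars)
    X = np.column_stack([np.ones(len(s)), s, Z])
    res, wald = _logit_fit(y, X)
    beta = float(res.params[1])
    se = float(res.bse[1]) if wald else float("nan")
    if wald:
        z = beta / se
        p = 2 * stats.norm.sf(abs(z))
        ci = (np.exp(beta - 1.959963984540054 * se),
              np.exp(beta + 1.959963984540054 * se))
    else:
        p, ci = float("nan"), (float("nan"), float("nan"))
    return AssocResult(trait=trait, cohort=cohort, n=len(y),
                       or_per_sd=float(np.exp(beta)), ci95=ci, p=float(p),
                       beta=beta, se=se, covariates=tuple(covars), wald=wald)


@dataclass
class BonferroniCutoff:
    raw: float
    reported: float     # rounded to one significant digit, as printed

    def __float__(self):
        return self.raw


def bonferroni_threshold(n_scores: int, n_cohorts: int,
                         alpha: float = 0.05) -> BonferroniCutoff:
    """alpha / (n_scores x n_cohorts); reported value keeps one significant
    digit, the raw value is retained."""
    if n_scores < 1 or n_cohorts < 1:
        raise AssocError("counts must be >= 1")
    raw = alpha / (n_scores * n_cohorts)
    reported = float(f"{raw:.0e}")
    return BonferroniCutoff(raw, reported)


@dataclass
class InteractionResult:
    modifier: str
    p_interaction: float
    interaction_beta: float
    stratified: pd.DataFrame    # per-bin / per-level ORs


def test_interaction(score, outcome, modifier: str,
                     covars: tuple = DEFAULT_COVARS,
                     data: pd.DataFrame | None = None,
                     age_bins: tuple = DEFAULT_AGE_BINS) -> InteractionResult:
    """Wald test on a score x modifier term added to the full model.

    For ``modifier='age'`` also returns per-bin ORs for the half-open bins
    [8,12), [12,16) and the closed last bin [16,22]; for ``'sex'``, per-level
    ORs.  Empty strata are omitted with a warning.
    """
    s = np.asarray(data[score] if isinstance(score, str) else score, float)
    y = np.asarray(data[outcome] if isinstance(outcome, str) else outcome, float)
    if modifier not in data.columns:
        raise AssocError(f"modifier {modifier!r} not in data")
    if modifier == "sex":
        mvals = (data["sex"] == data["sex"].iloc[0]).to_numpy(float)
    else:
        m0 = data[modifier].to_numpy(float)
        mvals = m0 - m0.mean()
    cov = tuple(covars)
    Z = _design(data, cov)
    # the modifier's main effect is already in Z when it is a covariate
    main = [] if modifier in cov else [mvals]
    X = np.column_stack([np.ones(len(s)), s, Z, *main, s * mvals])
    res, wald = _logit_fit(y, X)
    beta_int = float(res.params[-1])
    p_int = (2 * stats.norm.sf(abs(beta_int / res.bse[-1]))
             if wald else float("nan"))

    rows = []
    if modifier == "age":
        age = data["age"].to_numpy(float)
        for i, (lo, hi) in enumerate(age_bins):
            last = i == len(age_bins) - 1
            mask = (age >= lo) & ((age <= hi) if last else (age < hi))
            if mask.sum() == 0 or len(np.unique(y[mask])) < 2:
                logger.warning("age bin [%g,%g%s empty or single-class; omitted",
                               lo, hi, "]" if last else ")")
                continue
            sub = fit_univariate(s[mask], y[mask], covars=cov,
                                 data=data.loc[mask].reset_index(drop=True))
            rows.append(dict(stratum=f"[{lo:g},{hi:g}{']' if last else ')'}",
                             n=sub.n, or_per_sd=sub.or_per_sd,
                             ci_low=sub.ci95[0], ci_high=sub.ci95[1], p=sub.p))
    else:
        for level in pd.unique(data[modifier]):
            mask = (data[modifier] == level).to_numpy()
            if mask.sum() == 0 or len(np.unique(y[mask])) < 2:
                continue
            cov_nosex = tuple(c for c in cov if c != modifier)
            sub = fit_univariate(s[mask], y[mask], covars=cov_nosex,
                                 data=data.loc[mask].reset_index(drop=True))
            rows.append(dict(stratum=str(level), n=sub.n,
                             or_per_sd=sub.or_per_sd, ci_low=sub.ci95[0],
                             ci_high=sub.ci95[1], p=sub.p))
    return InteractionResult(modifier, float(p_int), beta_int,
                             pd.DataFrame(rows))


@dataclass
class DecileResult:
    proportions: pd.DataFrame   # decile (1..10), n, n_cases, case_proportion
    or_top_vs_bottom: float
    ci95: tuple
    p: float
    n: int


def assign_deciles(score: np.ndarray) -> np.ndarray:
    """Decile index 1..10 by empirical quantiles; ties go to the lower decile."""
    s = np.asarray(score, float)
    n = len(s)
    ranks = stats.rankdata(s, method="min")  # ties share the lowest rank
    dec = np.minimum(((ranks - 1) * 10 // n).astype(int) + 1, 10)
    return dec


def decile_contrast(score, outcome, covars: tuple = (),
                    data: pd.DataFrame | None = None) -> DecileResult:
    """Per-decile case proportions and the top-vs-bottom decile odds ratio.

    Requires >= 10 distinct score values; the contrast is a logistic fit of
    the outcome on a top-decile indicator restricted to deciles 1 and 10,
    with optional covariates.
    """
    s = np.asarray(data[score] if isinstance(score, str) else score, float)
    y = np.asarray(data[outcome] if isinstance(outcome, str) else outcome, float)
    if len(np.unique(s)) < 10:
        raise AssocError("degenerate score: fewer than 10 distinct values")
    dec = assign_deciles(s)
    props = (pd.DataFrame({"decile": dec, "y": y})
             .groupby("decile")["y"].agg(n="size", n_cases="sum",
                                         case_proportion="mean")
             .reset_index())
    mask = (dec == 1) | (dec == 10)
    top = (dec[mask] == 10).astype(float)
    d = (data.loc[mask].reset_index(drop=True) if data is not None
         else pd.DataFrame(index=range(int(mask.sum()))))
    res = fit_univariate(top, y[mask], covars=covars, data=d)
    return DecileResult(props, res.or_per_sd, res.ci95, res.p, res.n)


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 from model and intercept-only log-likelihoods."""
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    max_r2 = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / max_r2)


def nagelkerke_delta_r2(model_with_score, model_without) -> float:
    """R^2(full) - R^2(covariates-only) for nested logistic fits.

    Both arguments are fitted statsmodels results on identical subjects
    (checked via the endog vectors).  Nonnegative up to numerical tolerance.
    """
    y1, y0 = model_with_score.model.endog, model_without.model.endog
    if len(y1) != len(y0) or not np.array_equal(y1, y0):
        raise AssocError("models are not fit on identical subjects")
    n = len(y1)
    ll_null = sm.Logit(y1, np.ones((n, 1))).fit(disp=0).llf
    r2_full = nagelkerke_r2(model_with_score.llf, ll_null, n)
    r2_cov = nagelkerke_r2(model_without.llf, ll_null, n)
    return r2_full - r2_cov


def delta_r2_for_score(score, outcome, covars: tuple = DEFAULT_COVARS,
                       data: pd.DataFrame | None = None) -> float:
    """Convenience: Nagelkerke delta-R^2 attributable to one score."""
    s = np.asarray(data[score] if isinstance(score, str) else score, float)
    y = np.asarray(data[outcome] if isinstance(outcome, str) else outcome, float)
    Z = _design(data, covars) if data is not None else np.empty((len(s), 0))
    X0 = np.column_stack([np.ones(len(s)), Z])
    X1 = np.column_stack([X0, s])
    m1 = sm.Logit(y, X1).fit(disp=0)
    m0 = sm.Logit(y, X0).fit(disp=0)
    return nagelkerke_delta_r2(m1, m0)


def sensitivity_refit(data: pd.DataFrame, score_col: str, outcome_col: str,
                      exclusions=None, extra_covars: tuple = (),
                      covars: tuple = DEFAULT_COVARS, trait: str = "",
                      cohort: str = "") -> AssocResult:
    """Refit after row exclusions and/or with appended covariates.

    ``exclusions`` is a list of rules; each rule is either ``(column, value)``
    — drop rows where column equals value — or a callable mapping the frame
    to a boolean drop-mask.  Raises if an exclusion empties an outcome class.
    The result records the post-exclusion n and outcome rate in ``notes``.
    """
    d = data.copy()
    for rule in (exclusions or []):
        if callable(rule):
            drop = np.asarray(rule(d), bool)
        else:
            col, val = rule
            if col not in d.columns:
                raise AssocError(f"exclusion references unknown column {col!r}")
            drop = (d[col] == val).to_numpy()
        d = d.loc[~drop]
    if d[outcome_col].nunique() < 2:
        raise AssocError("exclusions emptied an outcome class")
    res = fit_univariate(score_col, outcome_col,
                         covars=tuple(covars) + tuple(extra_covars),
                         data=d.reset_index(drop=True), trait=trait,
                         cohort=cohort)
    rate = float(d[outcome_col].mean())
    res.notes = (f"n={res.n}, outcome rate={rate:.3f}, "
                 f"exclusions={len(exclusions or [])}, "
                 f"extra_covars={list(extra_covars)}")
    return res


@dataclass
class QuantResult:
    beta: float
    se: float
    p: float
    n: int


def fit_quantitative(score, outcome, covars: tuple = DEFAULT_COVARS,
                     data: pd.DataFrame | None = None) -> QuantResult:
    """Least-squares fit of a quantitative scale on a standardized score."""
    s = np.asarray(data[score] if isinstance(score, str) else score, float)
    y = np.asarray(data[outcome] if isinstance(outcome, str) else outcome, float)
    if np.ptp(y) == 0:
        raise AssocError("outcome is constant")
    Z = (_design(data, covars) if data is not None and covars
         else np.empty((len(s), 0)))
    X = np.column_stack([np.ones(len(s)), s, Z])
    res = sm.OLS(y, X).fit()
    return QuantResult(float(res.params[1]), float(res.bse[1]),
                       float(res.pvalues[1]), int(res.nobs))
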