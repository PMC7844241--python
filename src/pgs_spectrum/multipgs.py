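"""Elastic-net multi-PGS classification with a permutation null.

The classifier is a penalized logistic regression over a panel of corrected
polygenic scores, mixing L1 and L2 penalties via the mixing parameter
``alpha`` (1 = lasso, 0 = ridge) with overall strength ``lambda``.  Hyper-
parameters are tuned by (repeated) stratified 10-fold cross-validation
maximizing AUC; the prediction model uses the CV-optimal lambda at the best
alpha (``lambda_rule='cv_opt'``; ``'min_grid'`` selects the smallest lambda
on the grid instead).

Evaluation mirrors a train/test protocol: fit on a stratified random 70% of
subjects, measure AUC on the held-out 30%, repeat many times; in parallel,
refit on phenotype permutations (shuffled within ancestry stratum) to build
a null AUC distribution.  Significance is the conservative empirical p
(r+1)/(n_perm+1), where r counts permutation AUCs at or above the *mean*
observed AUC over repetitions.

Age, age^2 and sex covariates can ride along unpenalized (default), be
penalized like the scores, or be excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 2))


class MultiPGSError(ValueError):
    pass


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, float)
    return X, [f"pgs_{i}" for i in range(X.shape[1])]


def _check_xy(X: np.ndarray, y: np.ndarray) -> None:
    if np.isnan(X).any():
        raise MultiPGSError("X contains missing values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise MultiPGSError("outcome has a single class")
    if not set(classes) <= {0, 1}:
        raise MultiPGSError("outcome must be binary 0/1")


def _strat_labels(y: np.ndarray, group: np.ndarray | None) -> np.ndarray:
    if group is None:
        return y.astype(str)
    return np.char.add(np.asarray(group, str), y.astype(int).astype(str))


def auc_score(y: np.ndarray, pred: np.ndarray) -> float:
    """AUC in its Mann-Whitney form (tie-aware, rank-based).

    Probability that a random case outscores a random control, counting ties
    as one half.  Identical to the trapezoidal ROC area.
    """
    y = np.asarray(y)
    r = stats.rankdata(pred)
    n1 = int(np.sum(y == 1))
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise MultiPGSError("AUC needs both classes")
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def lambda_path(X: np.ndarray, y: np.ndarray, alpha: float,
                n_lambdas: int = 20, eps: float = 1e-3) -> np.ndarray:
    """Log-spaced penalty path from the smallest all-zero lambda downward."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.max(np.abs(X.T @ resid)) / (n * max(alpha, 0.1))
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * eps, n_lambdas)


def _fit_enet(X: np.ndarray, y: np.ndarray, alpha: float, lam: float,
              covars: np.ndarray | None, covar_mode: str, n_pgs: int,
              max_iter: int = 2000, tol: float = 1e-7):
    """Fit one elastic-net logistic model; returns (pgs_coefs, predictor).

    sklearn's saga objective is (1/C) * penalty + sum loglik, so C maps to
    1/(n*lambda) for the per-observation-average parameterization used here.
    The ``unpenalized`` covariate mode adds covariates through a fixed
    offset from an unpenalized covariate-only fit.
    """
    n = len(y)
    if covars is not None and covar_mode == "unpenalized":
        # per-parameter penalty weights: intercept and covariates unpenalized
        import statsmodels.api as sm

        Z = np.column_stack([np.ones(n), X, covars])
        pen = np.concatenate([[0.0], np.full(X.shape[1], lam),
                              np.zeros(covars.shape[1])])
        mod = sm.GLM(y, Z, family=sm.families.Binomial())
        res = mod.fit_regularized(method="elastic_net", alpha=pen,
                                  L1_wt=float(alpha), cnvrg_tol=tol,
                                  maxiter=max_iter)
        params = np.asarray(res.params)
        coefs = params[1:1 + n_pgs]

        def predict(Xnew, covars_new=None):
            Zn = np.column_stack([np.ones(len(Xnew)), Xnew, covars_new])
            return Zn @ params

        return coefs, res, predict

    if covars is not None and covar_mode == "penalized":
        Xfit = np.column_stack([X, covars])
    else:
        Xfit = X
    model = LogisticRegression(
        penalty="elasticnet", solver="saga", l1_ratio=float(alpha),
        C=1.0 / (n * lam), max_iter=max_iter, tol=tol, random_state=0)
    with warnings.catch_warnings():
        # sklearn >= 1.8 deprecates the explicit penalty= spelling; the
        # explicit form keeps older releases working
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(Xfit, y)
    coefs = model.coef_.ravel()[:n_pgs]

    def predict(Xnew, covars_new=None):
        if covars is not None and covar_mode == "penalized":
            Z = np.column_stack([Xnew, covars_new])
        else:
            Z = Xnew
        return model.decision_function(Z)

    return coefs, model, predict


@dataclass
class TuneResult:
    chosen_alpha: float
    chosen_lambda: float
    coef: np.ndarray            # standardized PGS coefficients
    pgs_names: list[str]
    model: object
    cv_auc: float


def tune_fit(X, y, alpha_grid=DEFAULT_ALPHA_GRID, folds: int = 10,
             repeats: int = 1, lambda_grid=None, n_lambdas: int = 20,
             covars=None, covar_mode: str = "unpenalized",
             group=None, seed: int = 0, lambda_rule: str = "cv_opt"
             ) -> TuneResult:
    """Grid-search (alpha, lambda) by repeated stratified k-fold CV on AUC.

    Predictors are standardized before fitting, so coefficients are on the
    per-SD scale.  ``lambda_rule='cv_opt'`` picks the CV-best lambda at the
    best alpha; ``'min_grid'`` the smallest lambda of the path.
    """
    X, names = _as_matrix(X)
    y = np.asarray(y, float)
    _check_xy(X, y)
    n = len(y)
    if n < folds:
        raise MultiPGSError(f"n={n} smaller than number of folds {folds}")
    mu, sd = X.mean(0), X.std(0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    C = None
    if covars is not None:
        C = np.asarray(covars, float)
        if covar_mode == "exclude":
            C = None
    strat = _strat_labels(y, group)

    best = (-np.inf, None, None)
    rng = np.random.default_rng(seed)
    for alpha in alpha_grid:
        lams = (np.asarray(lambda_grid, float) if lambda_grid is not None
                else lambda_path(Xs, y, alpha, n_lambdas))
        aucs = np.zeros(len(lams))
        counts = np.zeros(len(lams))
        for rep in range(repeats):
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=int(rng.integers(2 ** 31)))
            for tr, te in skf.split(Xs, strat):
                if len(np.unique(y[te])) < 2:
                    continue
                for li, lam in enumerate(lams):
                    _, _, predict = _fit_enet(
                        Xs[tr], y[tr], alpha, lam,
                        None if C is None else C[tr], covar_mode, len(names))
                    pred = predict(Xs[te], None if C is None else C[te])
                    aucs[li] += auc_score(y[te], pred)
                    counts[li] += 1
        mean_auc = aucs / np.maximum(counts, 1)
        li = (int(np.argmax(mean_auc)) if lambda_rule == "cv_opt"
              else int(np.argmin(lams)))
        if mean_auc[li] > best[0]:
            best = (mean_auc[li], float(alpha), float(lams[li]))
    cv_auc, chosen_alpha, chosen_lambda = best
    coef, model, _ = _fit_enet(Xs, y, chosen_alpha, chosen_lambda, C,
                               covar_mode, len(names))
    return TuneResult(chosen_alpha, chosen_lambda, coef, names, model, cv_auc)


@dataclass
class SplitResult:
    auc: float
    coef: np.ndarray
    chosen_alpha: float
    chosen_lambda: float


def split_eval(X, y, train_frac: float = 0.7, seed: int = 0, covars=None,
               group=None, **tune_kwargs) -> SplitResult:
    """Stratified 70/30 split; tune+fit on train, AUC on the held-out test."""
    X, names = _as_matrix(X)
    y = np.asarray(y, float)
    _check_xy(X, y)
    strat = _strat_labels(y, group)
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, train_size=train_frac, stratify=strat,
                              random_state=seed % (2 ** 32 - 1))
    C = None if covars is None else np.asarray(covars, float)
    g = None if group is None else np.asarray(group)
    res = tune_fit(pd.DataFrame(X[tr], columns=names), y[tr],
                   covars=None if C is None else C[tr],
                   group=None if g is None else g[tr],
                   seed=seed, **tune_kwargs)
    mu, sd = X[tr].mean(0), X[tr].std(0)
    sd[sd == 0] = 1.0
    covar_mode = tune_kwargs.get("covar_mode", "unpenalized")
    Cfit = None if (C is None or covar_mode == "exclude") else C
    coef, model, predict = _fit_enet((X[tr] - mu) / sd, y[tr],
                                     res.chosen_alpha, res.chosen_lambda,
                                     None if Cfit is None else Cfit[tr],
                                     covar_mode, len(names))
    pred = predict((X[te] - mu) / sd, None if Cfit is None else Cfit[te])
    if len(np.unique(y[te])) < 2:
        raise MultiPGSError("test split has a single class")
    if np.ptp(pred) == 0:
        auc = 0.5        # fully shrunk model: chance discrimination
    else:
        auc = auc_score(y[te], pred)
    return SplitResult(auc, coef, res.chosen_alpha, res.chosen_lambda)


@dataclass
class ElasticNetRun:
    """Result record of the repeated-split + permutation procedure."""

    pgs_names: list[str]
    alpha_grid: tuple
    repetition_aucs: np.ndarray          # (n_repetitions,)
    repetition_coefs: np.ndarray         # (n_repetitions, n_pgs)
    permutation_aucs: np.ndarray         # (n_permutations,)
    empirical_p: float
    coef_mean: np.ndarray
    coef_sem: np.ndarray
    chosen_alphas: np.ndarray = field(default=None)
    chosen_lambdas: np.ndarray = field(default=None)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.repetition_aucs))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"pgs": self.pgs_names, "coef_mean": self.coef_mean,
                             "coef_sem": self.coef_sem})


def coefficient_summary(coefs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error of the mean per PGS across repetitions."""
    coefs = np.atleast_2d(np.asarray(coefs, float))
    mean = coefs.mean(axis=0)
    nrep = coefs.shape[0]
    sem = (coefs.std(axis=0, ddof=1) / np.sqrt(nrep) if nrep > 1
           else np.full(coefs.shape[1], np.nan))
    return mean, sem


def empirical_p(observed_mean_auc: float, permutation_aucs: np.ndarray) -> float:
    """Conservative permutation p: (r+1)/(n+1), r = #{perm AUC >= observed}."""
    perm = np.asarray(permutation_aucs, float)
    if perm.size < 1:
        raise MultiPGSError("need at least one permutation")
    r = int(np.sum(perm >= observed_mean_auc))
    return (r + 1) / (perm.size + 1)


def _permute_within(y: np.ndarray, group: np.ndarray | None,
                    rng: np.random.Generator) -> np.ndarray:
    out = y.copy()
    if group is None:
        return rng.permutation(out)
    for g in np.unique(group):
        m = group == g
        out[m] = rng.permutation(out[m])
    return out


def repeat_and_permute(X, y, n_repetitions: int = 1000,
                       n_permutations: int = 1000, group=None, seed: int = 0,
                       train_frac: float = 0.7, covars=None,
                       **tune_kwargs) -> ElasticNetRun:
    """Repeated 70/30 evaluation plus a within-stratum permutation null.

    Permutations shuffle the phenotype within ancestry stratum and run the
    identical split/tune/test procedure once each.  ``empirical_p`` compares
    the mean observed AUC to the permutation AUC distribution.
    """
    if n_permutations < 1:
        raise MultiPGSError("n_permutations must be >= 1")
    X, names = _as_matrix(X)
    y = np.asarray(y, float)
    g = None if group is None else np.asarray(group)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=n_repetitions)
    perm_seeds = rng.integers(0, 2 ** 31 - 1, size=n_permutations)

    rep_aucs = np.empty(n_repetitions)
    rep_coefs = np.empty((n_repetitions, len(names)))
    alphas = np.empty(n_repetitions)
    lambdas = np.empty(n_repetitions)
    for i, s in enumerate(rep_seeds):
        res = split_eval(X, y, train_frac=train_frac, seed=int(s),
                         covars=covars, group=g, **tune_kwargs)
        rep_aucs[i] = res.auc
        rep_coefs[i] = res.coef
        alphas[i], lambdas[i] = res.chosen_alpha, res.chosen_lambda

    perm_aucs = np.empty(n_permutations)
    for i, s in enumerate(perm_seeds):
        prng = np.random.default_rng(int(s))
        yp = _permute_within(y, g, prng)
        res = split_eval(X, yp, train_frac=train_frac, seed=int(s),
                         covars=covars, group=g, **tune_kwargs)
        perm_aucs[i] = res.auc

    mean, sem = coefficient_summary(rep_coefs)
    p = empirical_p(float(rep_aucs.mean()), perm_aucs)
    logger.info("repeat_and_permute: mean AUC=%.4f, empirical p=%.4g",
                rep_aucs.mean(), p)
    return ElasticNetRun(names, tuple(tune_kwargs.get("alpha_grid",
                                                      DEFAULT_ALPHA_GRID)),
                         rep_aucs, rep_coefs, perm_aucs, p, mean, sem,
                         alphas, lambdas)


@dataclass
class CompareResult:
    p: float
    statistic: float
    median_a: float
    median_b: float


def compare_runs(run_a: ElasticNetRun, run_b: ElasticNetRun) -> CompareResult:
    """Two-sided Wilcoxon rank-sum test on two per-repetition AUC vectors.

    Used to ask whether a multivariate run outperforms a single-score run
    (or vice versa).
    """
    a, b = run_a.repetition_aucs, run_b.repetition_aucs
    if len(a) == 0 or len(b) == 0:
        raise MultiPGSError("empty AUC vector")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return CompareResult(float(res.pvalue), float(res.statistic),
                         float(np.median(a)), float(np.median(b)))


# spec-facing alias
compare_multivariate_vs_univariate = compare_runs
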