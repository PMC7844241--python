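"""Phenotypic-overlap statistics.

2x2 contingency tables between pairs of binary phenotypes with the
cross-product (sample) odds ratio, Woolf log-scale confidence interval and
Fisher's exact two-sided p; Wilcoxon rank-sum tests for binary-vs-
quantitative pairs; Spearman rank correlation for quantitative pairs.

The reported OR is the cross-product (a*d)/(b*c), not the conditional
maximum-likelihood estimate underlying the Fisher test — the two differ, and
printed ORs in the literature this package mirrors are cross-product ORs.
The conditional MLE is available behind ``estimator='conditional_mle'``.
Zero cells get the Haldane–Anscombe 0.5 correction for the OR/CI only, never
for the Fisher p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_or

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


class OverlapError(ValueError):
    pass


@dataclass
class ContingencyResult:
    """2x2 table result: cells are (exposed&case, exposed&control,
    unexposed&case, unexposed&control)."""

    a: int
    b: int
    c: int
    d: int
    or_: float
    ci95: tuple
    fisher_p: float
    n_missing: int = 0
    or_undefined: bool = False
    estimator: str = "cross_product"

    @property
    def cells(self) -> tuple:
        return (self.a, self.b, self.c, self.d)


def contingency_from_cells(a: int, b: int, c: int, d: int,
                           estimator: str = "cross_product",
                           n_missing: int = 0) -> ContingencyResult:
    """Build the overlap statistic directly from table cells."""
    if min(a, b, c, d) < 0:
        raise OverlapError("negative cell count")
    table = np.array([[a, b], [c, d]])
    margin_zero = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if margin_zero:
        return ContingencyResult(a, b, c, d, float("nan"),
                                 (float("nan"), float("nan")), fisher_p,
                                 n_missing, or_undefined=True)
    aa, bb, cc, dd = (x + 0.5 if min(a, b, c, d) == 0 else x
                      for x in (a, b, c, d))
    if estimator == "cross_product":
        orv = (aa * dd) / (bb * cc)
    elif estimator == "conditional_mle":
        orv = float(_conditional_or(table).statistic)
    else:
        raise OverlapError(f"unknown estimator {estimator!r}")
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = np.log((aa * dd) / (bb * cc))
    ci = (float(np.exp(log_or - Z975 * se)), float(np.exp(log_or + Z975 * se)))
    return ContingencyResult(int(a), int(b), int(c), int(d), float(orv), ci,
                             fisher_p, n_missing, estimator=estimator)


def contingency(exposure, outcome, estimator: str = "cross_product"
                ) -> ContingencyResult:
    """Tabulate two aligned binary vectors and compute the overlap statistic.

    Subjects with a missing value in either vector are dropped; the count is
    recorded on the result and logged.
    """
    e = np.asarray(exposure, float)
    o = np.asarray(outcome, float)
    if len(e) != len(o):
        raise OverlapError("vectors are not aligned")
    keep = ~(np.isnan(e) | np.isnan(o))
    n_missing = int((~keep).sum())
    if n_missing:
        logger.info("contingency: dropped %d subjects with missing values",
                    n_missing)
    e, o = e[keep].astype(int), o[keep].astype(int)
    a = int(np.sum((e == 1) & (o == 1)))
    b = int(np.sum((e == 1) & (o == 0)))
    c = int(np.sum((e == 0) & (o == 1)))
    d = int(np.sum((e == 0) & (o == 0)))
    return contingency_from_cells(a, b, c, d, estimator, n_missing)


@dataclass
class RankSumResult:
    statistic: float
    p: float
    n1: int
    n0: int
    median1: float
    median0: float


def rank_sum(group, values) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with tie correction.

    ``group`` is binary; tests whether ``values`` differ between groups.
    Exact p for small tie-free samples, normal approximation otherwise.
    """
    g = np.asarray(group, float)
    v = np.asarray(values, float)
    keep = ~(np.isnan(g) | np.isnan(v))
    g, v = g[keep], v[keep]
    x1, x0 = v[g == 1], v[g == 0]
    if len(x1) == 0 or len(x0) == 0:
        raise OverlapError("one group is empty")
    res = stats.mannwhitneyu(x1, x0, alternative="two-sided", method="auto")
    return RankSumResult(float(res.statistic), float(res.pvalue),
                         len(x1), len(x0),
                         float(np.median(x1)), float(np.median(x0)))


@dataclass
class RankCorrResult:
    rho: float
    p: float
    n: int
    undefined: bool = False


def rank_correlation(x, y) -> RankCorrResult:
    """Spearman rank correlation with midrank tie handling.

    p-value from the standard large-sample t approximation.  A constant
    input vector leaves rho undefined (flagged, not an exception).
    """
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    keep = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[keep], yv[keep]
    if len(xv) < 3:
        raise OverlapError("need at least 3 paired observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        logger.warning("rank_correlation: constant vector, rho undefined")
        return RankCorrResult(float("nan"), float("nan"), len(xv),
                              undefined=True)
    rho, p = stats.spearmanr(xv, yv)
    return RankCorrResult(float(rho), float(p), len(xv))


def overlap_table(cohort: pd.DataFrame, pairs: list[tuple[str, str]],
                  by: str | None = None) -> pd.DataFrame:
    """Contingency statistics for phenotype pairs, optionally per stratum."""
    rows = []
    strata = [("All", cohort)]
    if by is not None:
        strata += [(str(lv), sub) for lv, sub in cohort.groupby(by)]
    for label, sub in strata:
        for expo, outc in pairs:
            r = contingency(sub[expo], sub[outc])
            rows.append(dict(cohort=label, exposure=expo, outcome=outc,
                             a=r.a, b=r.b, c=r.c, d=r.d, odds_ratio=r.or_,
                             ci_low=r.ci95[0], ci_high=r.ci95[1],
                             fisher_p=r.fisher_p, n_missing=r.n_missing))
    return pd.DataFrame(rows)
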