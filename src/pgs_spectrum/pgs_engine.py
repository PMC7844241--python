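"""Polygenic scoring: harmonization, clumping+thresholding, LDpred-inf,
ancestry principal components, and PC-residualized standardized scores.

The scoring contract is the standard one: a subject's raw score is the sum of
GWAS effect sizes times effect-allele dosages over the retained variants.
Variant selection is either greedy LD clumping by ascending p-value followed
by a p-value threshold, or the infinitesimal-model LD adjustment
(``ldpred_inf``), which rescales all effects jointly within LD windows.

"Corrected" scores — the quantity every downstream analysis consumes — are
the residuals of the raw score on ancestry-specific principal components,
standardized to mean 0 / SD 1 within the group they were corrected in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .io_formats import GenotypeMatrix, SummaryStats

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ScoringError(ValueError):
    pass


class DegenerateScoreError(ScoringError):
    pass


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedWeights:
    """Summary-statistic effects aligned to the target panel's effect allele.

    ``table`` has one row per retained variant: id, chrom, pos, vindex (column
    index into the genotype matrix), beta (sign-aligned to target a1), p.
    ``exclusions`` maps dropped variant ids to a reason string.
    """

    table: pd.DataFrame
    exclusions: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def subset(self, mask) -> "HarmonizedWeights":
        return HarmonizedWeights(self.table.loc[mask].reset_index(drop=True),
                                 dict(self.exclusions))


def _is_ambiguous(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def harmonize(stats: SummaryStats, variants: pd.DataFrame,
              policy: str = "drop_ambiguous") -> HarmonizedWeights:
    """Align summary-statistic alleles to the target variant table.

    Matching rules, applied per shared variant id:

    * alleles equal to target (a1, a2)      -> beta kept
    * alleles swapped                       -> beta negated
    * strand-flipped (complement) match     -> resolved, then as above
    * A/T or C/G (strand-ambiguous) pairs   -> dropped under
      ``drop_ambiguous`` (default); kept, matched on the literal alleles,
      under ``keep_ambiguous``
    * anything else, or id absent from target -> excluded with a reason

    All failures are logged exclusions, never errors.
    """
    if policy not in ("drop_ambiguous", "keep_ambiguous"):
        raise ValueError(f"unknown policy {policy!r}")
    tgt = variants.reset_index(drop=True)
    tgt_idx = {vid: i for i, vid in enumerate(tgt["id"])}
    exclusions: dict[str, str] = {}
    rows = []
    st = stats.table
    for snp, sa1, sa2, beta, p in zip(st["SNP"], st["A1"], st["A2"],
                                      st["BETA"], st["P"]):
        i = tgt_idx.get(snp)
        if i is None:
            exclusions[snp] = "absent-from-target"
            continue
        ta1, ta2 = tgt.at[i, "a1"], tgt.at[i, "a2"]
        if _is_ambiguous(sa1, sa2) and policy == "drop_ambiguous":
            exclusions[snp] = "strand-ambiguous"
            continue
        if (sa1, sa2) == (ta1, ta2):
            b = beta
        elif (sa1, sa2) == (ta2, ta1):
            b = -beta
        else:
            ca1, ca2 = COMPLEMENT[sa1], COMPLEMENT[sa2]
            if (ca1, ca2) == (ta1, ta2):
                b = beta
            elif (ca1, ca2) == (ta2, ta1):
                b = -beta
            else:
                exclusions[snp] = "allele-mismatch"
                continue
        rows.append(dict(id=snp, chrom=tgt.at[i, "chrom"], pos=tgt.at[i, "pos"],
                         vindex=i, beta=b, p=p))
    table = pd.DataFrame(rows, columns=["id", "chrom", "pos", "vindex", "beta", "p"])
    if exclusions:
        logger.info("harmonize: excluded %d variants (%s)", len(exclusions),
                    pd.Series(list(exclusions.values())).value_counts().to_dict())
    return HarmonizedWeights(table, exclusions)


# ---------------------------------------------------------------------------
# LD view
# ---------------------------------------------------------------------------

class LDMatrixView:
    """Banded correlation accessor over a genotype panel.

    Correlations are computed lazily from standardized dosages; ``radius``
    bounds the band of flanking variants the view will serve (queries beyond
    it return 0, matching the banded-LD assumption of the methods that use
    the view).
    """

    def __init__(self, genotypes: GenotypeMatrix | np.ndarray, radius: int = 500):
        D = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else genotypes
        D = np.asarray(D, float)
        mu = np.nanmean(D, axis=0)
        X = np.where(np.isnan(D), mu, D) - mu
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._X = X / sd
        self._n = X.shape[0]
        self.radius = int(radius)

    @property
    def n_variants(self) -> int:
        return self._X.shape[1]

    def r(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        if abs(i - j) > self.radius:
            return 0.0
        return float(self._X[:, i] @ self._X[:, j] / self._n)

    def r_profile(self, i: int, js: np.ndarray) -> np.ndarray:
        js = np.asarray(js)
        out = self._X[:, js].T @ self._X[:, i] / self._n
        out[np.abs(js - i) > self.radius] = 0.0
        out[js == i] = 1.0
        return out

    def block(self, lo: int, hi: int) -> np.ndarray:
        """Dense correlation matrix for variant slice [lo, hi)."""
        Xb = self._X[:, lo:hi]
        R = Xb.T @ Xb / self._n
        np.fill_diagonal(R, 1.0)
        return R


def build_ld_view(genotypes: GenotypeMatrix, radius: int = 500,
                  group: str | None = None) -> LDMatrixView:
    if group is not None:
        genotypes = genotypes.subset(genotypes.group_mask(group))
    return LDMatrixView(genotypes, radius=radius)


# ---------------------------------------------------------------------------
# clumping + thresholding
# ---------------------------------------------------------------------------

def ld_clump(weights: HarmonizedWeights, ld: LDMatrixView,
             r2_max: float = 0.1, window_kb: float = 500.0) -> set[str]:
    """Greedy LD clumping: returns the set of index variant ids.

    Repeatedly takes the smallest-p unclaimed variant as index and claims all
    unclaimed variants within ``window_kb`` on the same chromosome whose r^2
    with it is >= ``r2_max``.  Ties on p are broken by (chrom, pos)
    ascending, making the result independent of input row order.
    """
    tab = weights.table.reset_index(drop=True)
    if tab.empty:
        return set()
    order = tab.sort_values(["p", "chrom", "pos"], kind="mergesort").index.to_numpy()
    claimed = np.zeros(len(tab), dtype=bool)
    chrom = tab["chrom"].to_numpy()
    pos = tab["pos"].to_numpy(float)
    vindex = tab["vindex"].to_numpy()
    ids = tab["id"].to_numpy()
    index_ids: set[str] = set()
    window = window_kb * 1000.0
    for k in order:
        if claimed[k]:
            continue
        claimed[k] = True
        index_ids.add(ids[k])
        near = (~claimed) & (chrom == chrom[k]) & (np.abs(pos - pos[k]) <= window)
        if near.any():
            cand = np.flatnonzero(near)
            r = ld.r_profile(vindex[k], vindex[cand])
            claimed[cand[r ** 2 >= r2_max]] = True
    return index_ids


def threshold(weights: HarmonizedWeights, p_max: float = 0.05) -> HarmonizedWeights:
    """Retain variants with p strictly below ``p_max``."""
    out = weights.subset((weights.table["p"] < p_max).to_numpy())
    logger.info("threshold: retained %d of %d variants at p<%g",
                out.n_variants, weights.n_variants, p_max)
    return out


def clump_and_threshold(weights: HarmonizedWeights, ld: LDMatrixView,
                        p_max: float = 0.05, r2_max: float = 0.1,
                        window_kb: float = 500.0) -> HarmonizedWeights:
    index_ids = ld_clump(weights, ld, r2_max=r2_max, window_kb=window_kb)
    kept = weights.subset(weights.table["id"].isin(index_ids).to_numpy())
    return threshold(kept, p_max=p_max)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score(genotypes: GenotypeMatrix, weights: HarmonizedWeights) -> np.ndarray:
    """Raw polygenic score: sum of beta x effect-allele dosage.

    Missing dosages are replaced by the per-variant mean within the
    subject's ancestry group.  Linear in the weights.
    """
    if weights.n_variants == 0:
        raise ScoringError("no scoring variants")
    cols = weights.table["vindex"].to_numpy()
    beta = weights.table["beta"].to_numpy(float)
    D = genotypes.dosages[:, cols].astype(float)
    if np.isnan(D).any():
        for anc in np.unique(genotypes.ancestry):
            m = genotypes.ancestry == anc
            block = D[m]
            mu = np.nanmean(block, axis=0)
            mu = np.where(np.isnan(mu), 0.0, mu)
            inds = np.where(np.isnan(block))
            block[inds] = mu[inds[1]]
            D[m] = block
    return D @ beta


# ---------------------------------------------------------------------------
# LDpred (infinitesimal model)
# ---------------------------------------------------------------------------

def ldpred_inf(weights: HarmonizedWeights, ld: LDMatrixView, h2: float,
               n: int, m: int | None = None) -> HarmonizedWeights:
    """Infinitesimal-model LD adjustment of marginal effects.

    Within each LD window solves (D + (m/(n h2)) I) beta_adj = beta_hat,
    where D is the local LD correlation block.  Windows are consecutive
    variant chunks of ``2*radius`` (the view's radius); with identity LD this
    reduces to the closed-form shrinkage beta * (n h2)/(n h2 + m).  Singular
    local systems get a logged 1e-6 ridge jitter.
    """
    if not (0 < h2 <= 1):
        raise ValueError(f"h2 must be in (0,1], got {h2}")
    tab = weights.table
    if m is None:
        m = len(tab)
    c = m / (n * h2)
    vindex = tab["vindex"].to_numpy()
    if len(vindex) and not np.all(np.diff(vindex) > 0):
        raise ValueError("weights must be ordered by variant index for ldpred_inf")
    beta = tab["beta"].to_numpy(float)
    adj = np.empty_like(beta)
    wsize = max(1, 2 * ld.radius)
    for lo in range(0, len(beta), wsize):
        hi = min(lo + wsize, len(beta))
        idx = vindex[lo:hi]
        Xsub = ld._X[:, idx]
        D = Xsub.T @ Xsub / ld._n
        np.fill_diagonal(D, 1.0)
        A = D + c * np.eye(hi - lo)
        try:
            adj[lo:hi] = linalg.solve(A, beta[lo:hi], assume_a="pos")
        except linalg.LinAlgError:
            logger.warning("ldpred_inf: singular window [%d,%d), adding 1e-6 jitter",
                           lo, hi)
            adj[lo:hi] = linalg.solve(A + 1e-6 * np.eye(hi - lo), beta[lo:hi])
    out = tab.copy()
    out["beta"] = adj
    return HarmonizedWeights(out, dict(weights.exclusions))


# ---------------------------------------------------------------------------
# principal components and score correction
# ---------------------------------------------------------------------------

def compute_pcs(genotypes: GenotypeMatrix, group: np.ndarray | str | None = None,
                k: int = 10) -> np.ndarray:
    """Top-k principal components of the standardized genotypes of a group.

    Returns an (n_group, k) matrix with orthonormal columns.  Sign is fixed
    by making each component's largest-magnitude variant loading positive,
    so results are reproducible across runs and LAPACK builds.
    """
    if isinstance(group, str):
        mask = genotypes.group_mask(group)
    elif group is None:
        mask = np.ones(genotypes.n_subjects, dtype=bool)
    else:
        mask = np.asarray(group, dtype=bool)
    D = genotypes.dosages[mask].astype(float)
    n = D.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than group size {n}")
    mu = np.nanmean(D, axis=0)
    X = np.where(np.isnan(D), mu, D) - mu
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    if k < min(X.shape) // 2 and min(X.shape) > 20:
        # truncated SVD; fixed start vector keeps the result deterministic
        from scipy.sparse.linalg import svds

        U, s, Vt = svds(X, k=k, v0=np.ones(min(X.shape)))
        order = np.argsort(s)[::-1]
        U, Vt = U[:, order], Vt[order]
    else:
        U, s, Vt = linalg.svd(X, full_matrices=False)
        U, Vt = U[:, :k], Vt[:k]
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    return U


def residualize_standardize(raw_scores: np.ndarray, pcs: np.ndarray | None
                            ) -> np.ndarray:
    """Residual of score on [intercept, PCs], standardized to mean 0 / SD 1.

    This is the "corrected polygenic score" consumed by all downstream
    analyses.  Raises :class:`DegenerateScoreError` when the residual has
    (numerically) zero variance.
    """
    y = np.asarray(raw_scores, float)
    n = len(y)
    if pcs is None or (hasattr(pcs, "size") and pcs.size == 0):
        Z = np.ones((n, 1))
    else:
        pcs = np.asarray(pcs, float)
        Z = np.column_stack([np.ones(n), pcs])
    if y.std() == 0:
        raise DegenerateScoreError("degenerate score: zero variance")
    coef, *_ = linalg.lstsq(Z, y)
    resid = y - Z @ coef
    sd = resid.std()
    if sd < 1e-10 * max(y.std(), 1.0):
        raise DegenerateScoreError("degenerate score: zero residual variance")
    return resid / sd


def group_pcs(genotypes: GenotypeMatrix, k: int = 10) -> dict:
    """Ancestry-specific PCs for every group, computed once for reuse."""
    out = {}
    for g in np.unique(genotypes.ancestry):
        sub = genotypes.subset(genotypes.group_mask(g))
        kk = min(k, sub.n_subjects - 2)
        out[g] = compute_pcs(sub, None, k=kk) if kk > 0 else None
    return out


def corrected_scores(genotypes: GenotypeMatrix, weights: HarmonizedWeights,
                     k_pcs: int = 10, by_group: bool = True,
                     pcs: dict | None = None) -> np.ndarray:
    """Raw score -> PC-residualized standardized score, per ancestry group.

    With ``by_group`` (default) PCs are computed and the residualization /
    standardization done within each ancestry group separately, so pooled
    multi-ancestry analyses see scores that are mean 0 / SD 1 within each
    group.  Pass a precomputed ``pcs`` dict (from :func:`group_pcs`) when
    scoring many traits on the same panel.
    """
    raw = score(genotypes, weights)
    out = np.empty_like(raw, dtype=float)
    if by_group:
        if pcs is None:
            pcs = group_pcs(genotypes, k=k_pcs)
        for g, P in pcs.items():
            mask = genotypes.group_mask(g)
            out[mask] = residualize_standardize(raw[mask], P)
    else:
        k = min(k_pcs, genotypes.n_subjects - 2)
        P = compute_pcs(genotypes, None, k=k) if k > 0 else None
        out[:] = residualize_standardize(raw, P)
    return out
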