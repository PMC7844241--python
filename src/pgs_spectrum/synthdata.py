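"""Synthetic two-ancestry cohort generator.

Generates the three inputs the analysis pipeline consumes — genotypes, GWAS
summary statistics and a phenotype/covariate table — with the statistical
structure the downstream methods assume:

* **Genotypes.**  Two ancestry groups whose allele frequencies diverge under
  a Balding–Nichols model with divergence parameter ``fst``; linkage
  disequilibrium is blockwise, built from a Gaussian-copula autoregressive
  chain whose pairwise latent correlations are calibrated (by tetrachoric
  inversion) so that the *dosage* correlation between adjacent variants in a
  block equals ``block_rho``, decaying geometrically with distance and zero
  across block boundaries.
* **Summary statistics.**  Per-trait true effects are point-normal (a
  ``prop_causal`` fraction of variants carry effects, scaled so the summed
  per-variant variance on the standardized-genotype scale equals the
  liability heritability ``h2``).  Cross-trait architecture follows a
  single-factor model: each trait's effect vector correlates with a latent
  outcome-liability architecture by its ``rg_to_ps_liability``.  Observed
  effects add sampling noise with se = 1/sqrt(2 N p(1-p)).
* **Phenotypes.**  The binary psychosis-spectrum (PS) outcome follows a
  liability-threshold model on the logistic scale: liability = per-trait
  genetic scores weighted by configured log odds ratios (with a linear
  age x score interaction) plus standard logistic noise, thresholded
  per-ancestry to hit the configured prevalence.  Comorbid flags (ADHD, ADHD
  symptom endorsement, depression, mania, anxiety, trauma, substance use)
  and quantitative symptom scales (PRIME, SOPS) are generated with
  configurable associations to PS.

Every draw derives from ``SimulationConfig.seed``; identical configs produce
identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io_formats import ConfigurationError, GenotypeMatrix, SummaryStats

logger = logging.getLogger(__name__)

_LN = np.log


@dataclass
class TraitSpec:
    """Architecture of one source-trait GWAS.

    ``h2`` is liability-scale heritability captured by the simulated variant
    panel; ``prop_causal`` the fraction of variants with nonzero effects;
    ``rg_to_ps_liability`` the genetic correlation between this trait's
    effect vector and the latent architecture that drives the PS outcome.
    ``h2_zscore`` is carried as metadata for the GWAS-selection filter.
    """

    name: str
    gwas_n: int
    h2: float
    prop_causal: float = 0.3
    rg_to_ps_liability: float = 0.0
    h2_zscore: float | None = None

    def validate(self) -> None:
        if not (0 <= self.h2 <= 1):
            raise ConfigurationError(f"{self.name}: h2 must be in [0,1], got {self.h2}")
        if not (0 < self.prop_causal <= 1):
            raise ConfigurationError(f"{self.name}: prop_causal must be in (0,1]")
        if not (-1 <= self.rg_to_ps_liability <= 1):
            raise ConfigurationError(f"{self.name}: rg_to_ps_liability outside [-1,1]")
        if self.gwas_n <= 0:
            raise ConfigurationError(f"{self.name}: gwas_n must be positive")
        if self.h2 * self.rg_to_ps_liability ** 2 > 1:
            raise ConfigurationError(f"{self.name}: h2*rg^2 exceeds 1")


def default_trait_specs() -> list[TraitSpec]:
    """Thirteen psychiatric / brain / behavioural source traits.

    Sample sizes and heritabilities are round numbers typical of the 2018-era
    GWAS each entry emulates.  Only the ADHD-like trait shares architecture
    with the PS outcome by default; all others are genetically unrelated to
    it, matching a study design in which one score carries the signal.
    """
    mk = TraitSpec
    return [
        mk("ADHD", 55374, 0.22, 0.3, 1.0, 10.0),
        mk("SCZ", 105318, 0.24, 0.3, 0.0, 30.0),
        mk("BIP", 51710, 0.20, 0.3, 0.0, 15.0),
        mk("MDD", 173005, 0.09, 0.3, 0.0, 12.0),
        mk("Autism", 46350, 0.12, 0.3, 0.0, 9.0),
        mk("CrossDisorder", 60000, 0.18, 0.3, 0.0, 14.0),
        mk("Depression23andMe", 307354, 0.06, 0.3, 0.0, 16.0),
        mk("MDD_CONVERGE", 10640, 0.20, 0.3, 0.0, 5.5),
        mk("CaudateVol", 30717, 0.25, 0.2, 0.0, 8.0),
        mk("PutamenVol", 30717, 0.28, 0.2, 0.0, 9.0),
        mk("Morningness", 89283, 0.10, 0.3, 0.0, 13.0),
        mk("Neuroticism", 170911, 0.09, 0.3, 0.0, 12.0),
        mk("SWB", 298420, 0.03, 0.3, 0.0, 7.0),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults set to the cohort the
    analysis was designed around: ~4852 European-ancestry (EA) and ~1802
    African-American (AA) youth aged 8-22, ~15%/29% PS prevalence, ~5% ADHD,
    and a genetic effect of OR 1.23 per SD of the ADHD-architecture score in
    EA, absent (OR 1.0) in AA, attenuating linearly with age on the log-OR
    scale."""

    n_subjects_per_ancestry: dict = field(
        default_factory=lambda: {"EA": 4852, "AA": 1802})
    n_variants: int = 2000
    n_blocks: int = 100
    block_rho: float = 0.5
    fst: float = 0.1
    maf_range: tuple = (0.05, 0.5)
    trait_specs: list = field(default_factory=default_trait_specs)
    # trait -> ancestry -> marginal odds ratio per SD of that trait's true
    # genetic score; traits absent from the map get OR 1 everywhere.
    target_or_per_sd: dict = field(
        default_factory=lambda: {"ADHD": {"EA": 1.23, "AA": 1.0}})
    ps_prevalence: dict = field(default_factory=lambda: {"EA": 0.15, "AA": 0.29})
    adhd_prevalence: float = 0.05
    age_range: tuple = (8.0, 22.0)
    # per-year change in the log-OR of the genetic effect; the configured OR
    # holds at the midpoint of age_range.
    age_interaction_slope: float = -0.015
    # log-ORs tying comorbid phenotypes to the PS flag
    comorbidity_logor: dict = field(default_factory=lambda: {
        "adhd": _LN(3.03), "adhd_symptoms": _LN(4.7), "depression": _LN(3.0),
        "mania": _LN(3.0), "anxiety": _LN(3.0), "trauma": _LN(2.0),
        "alcohol": _LN(1.5), "tobacco": _LN(1.5), "marijuana": _LN(1.5),
        "cocaine": 0.0, "otc": 0.0})
    comorbidity_prevalence: dict = field(default_factory=lambda: {
        "adhd_symptoms": 0.45, "depression": 0.30, "mania": 0.15,
        "anxiety": 0.25, "trauma": 0.30, "alcohol": 0.20, "tobacco": 0.15,
        "marijuana": 0.15, "cocaine": 0.02, "otc": 0.05})
    substance_coverage: float = 0.43   # fraction of subjects with substance data
    seed: int = 2021

    def validate(self) -> None:
        if not self.n_subjects_per_ancestry:
            raise ConfigurationError("need at least one ancestry group")
        if any(n <= 0 for n in self.n_subjects_per_ancestry.values()):
            raise ConfigurationError("subject counts must be positive")
        if not (0 <= self.block_rho < 1):
            raise ConfigurationError(f"block_rho must be in [0,1), got {self.block_rho}")
        if not (0 <= self.fst <= 0.5):
            raise ConfigurationError(f"fst must be in [0,0.5], got {self.fst}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must satisfy 0<lo<=hi<=0.5, got {self.maf_range}")
        if self.n_variants % self.n_blocks != 0:
            raise ConfigurationError(
                f"n_variants ({self.n_variants}) not divisible by n_blocks ({self.n_blocks})")
        for anc, prev in self.ps_prevalence.items():
            if not (0 < prev < 1):
                raise ConfigurationError(f"ps_prevalence[{anc}] must be in (0,1)")
        if not (0 < self.adhd_prevalence < 1):
            raise ConfigurationError("adhd_prevalence must be in (0,1)")
        for s in self.trait_specs:
            s.validate()

    @property
    def ancestries(self) -> list[str]:
        return list(self.n_subjects_per_ancestry)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _bvn_cdf(h: np.ndarray, k: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal, via Owen's T.

    Vectorized over all arguments; used to calibrate latent correlations.
    """
    h = np.where(np.abs(h) < 1e-10, 1e-10, h)
    k = np.where(np.abs(k) < 1e-10, 1e-10, k)
    denom = np.sqrt(np.clip(1.0 - rho ** 2, 1e-12, None))
    a_h = (k - rho * h) / (h * denom)
    a_k = (h - rho * k) / (k * denom)
    out = (0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
           - special.owens_t(h, a_h) - special.owens_t(k, a_k))
    out = out - np.where((h * k < 0) | ((h * k == 0) & (h + k < 0)), 0.5, 0.0)
    return np.clip(out, 0.0, 1.0)


def _latent_for_target_corr(q1: np.ndarray, q2: np.ndarray, target: float,
                            tol: float = 1e-6) -> np.ndarray:
    """Latent Gaussian correlation giving Bernoulli(q1),Bernoulli(q2)
    indicators a Pearson correlation of ``target`` (tetrachoric inversion,
    vectorized bisection).  Capped at 0.999 when the target is unreachable
    for very unequal frequencies."""
    h, k = stats.norm.ppf(q1), stats.norm.ppf(q2)
    sd = np.sqrt(q1 * (1 - q1) * q2 * (1 - q2))
    lo = np.zeros_like(h)
    hi = np.full_like(h, 0.999)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        corr = (_bvn_cdf(h, k, mid) - q1 * q2) / sd
        too_low = corr < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
        if np.max(hi - lo) < tol:
            break
    return 0.5 * (lo + hi)


def simulate_genotypes(config: SimulationConfig
                       ) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Draw the variant table and dosage matrix for all ancestry groups.

    Ancestral allele frequencies are uniform on ``maf_range``; per-ancestry
    frequencies follow Balding–Nichols Beta(p(1-F)/F, (1-p)(1-F)/F) around
    them.  Haplotypes are sampled from a per-block latent AR chain whose
    lag-1 dosage correlation is calibrated to ``block_rho``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    M = config.n_variants
    block_size = M // config.n_blocks

    # Variants in an LD block share one drift history: the ancestral
    # frequency is a block-level draw with small per-variant jitter, and the
    # Balding–Nichols divergence uses one quantile per block.  Without this
    # local frequency smoothness the configured pairwise dosage correlation
    # would be unattainable for binary genotypes (Frechet bound).
    lo, hi = config.maf_range
    base = rng.uniform(lo, hi, size=config.n_blocks)
    anc_freq = np.clip(np.repeat(base, block_size)
                       + rng.normal(0.0, 0.01, size=M), lo, hi)
    freqs = {}
    for anc in config.ancestries:
        if config.fst == 0:
            freqs[anc] = anc_freq.copy()
        else:
            F = config.fst
            a = anc_freq * (1 - F) / F
            b = (1 - anc_freq) * (1 - F) / F
            u = stats.norm.cdf(np.repeat(rng.standard_normal(config.n_blocks),
                                         block_size))
            freqs[anc] = np.clip(stats.beta.ppf(u, a, b), 0.005, 0.995)

    variants = pd.DataFrame({
        "id": [f"rs{100000 + i}" for i in range(M)],
        "chrom": "1",
        "pos": np.arange(1, M + 1) * 1000,  # 1 kb spacing
        "a1": np.take(list("ACGT"), rng.integers(0, 4, size=M)),
    })
    # choose a2 different from a1 (deterministic cyclic fallback on collision)
    alt = np.take(list("ACGT"), rng.integers(0, 3, size=M))
    same = alt == variants["a1"].to_numpy()
    nxt = {"A": "C", "C": "G", "G": "T", "T": "A"}
    alt[same] = [nxt[x] for x in alt[same]]
    variants["a2"] = alt
    for anc in config.ancestries:
        variants[f"freq_{anc}"] = freqs[anc]

    dosage_blocks, ids, ancs = [], [], []
    for anc in config.ancestries:
        n = config.n_subjects_per_ancestry[anc]
        q = freqs[anc]
        thresh = stats.norm.ppf(q)
        if config.block_rho > 0:
            a_lat = _latent_for_target_corr(q[:-1], q[1:], config.block_rho)
        else:
            a_lat = np.zeros(M - 1)
        # zero latent correlation across block boundaries
        boundary = (np.arange(1, M) % block_size) == 0
        a_lat[boundary] = 0.0

        n_hap = 2 * n
        H = np.empty((n_hap, M), dtype=bool)
        z = rng.standard_normal(n_hap)
        H[:, 0] = z < thresh[0]
        for j in range(1, M):
            a = a_lat[j - 1]
            z = a * z + np.sqrt(1 - a * a) * rng.standard_normal(n_hap)
            H[:, j] = z < thresh[j]
        D = (H[0::2].astype(np.float64) + H[1::2].astype(np.float64))
        dosage_blocks.append(D)
        ids.extend([f"{anc}_{i:05d}" for i in range(n)])
        ancs.extend([anc] * n)

    genotypes = GenotypeMatrix(np.vstack(dosage_blocks), np.asarray(ids),
                               np.asarray(ancs))
    logger.info("simulated %d subjects x %d variants (seed=%d)",
                genotypes.n_subjects, M, config.seed)
    return variants, genotypes


# ---------------------------------------------------------------------------
# true effects and summary statistics
# ---------------------------------------------------------------------------

def simulate_true_effects(n_variants: int, specs: list[TraitSpec], seed: int
                          ) -> dict[str, np.ndarray]:
    """Per-trait true effect vectors on the standardized-genotype scale.

    A latent architecture vector ``u`` induces cross-trait correlation:
    trait t draws rg_t * u + sqrt(1-rg_t^2) * noise, masks to its causal
    fraction, and scales so the summed squared effects equal ``h2``.  The
    returned dict also holds ``u`` under the key ``_liability_anchor``.
    """
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n_variants)
    out = {"_liability_anchor": u}
    for spec in specs:
        spec.validate()
        rg = spec.rg_to_ps_liability
        raw = rg * u + np.sqrt(max(0.0, 1 - rg ** 2)) * rng.standard_normal(n_variants)
        mask = rng.random(n_variants) < spec.prop_causal
        if not mask.any():
            mask[rng.integers(n_variants)] = True
        b = raw * mask
        ssq = float(b @ b)
        if spec.h2 > 0 and ssq > 0:
            b = b * np.sqrt(spec.h2 / ssq)
        else:
            b = np.zeros(n_variants)
        out[spec.name] = b
    return out


def simulate_sumstats(variants: pd.DataFrame, spec: TraitSpec, ancestry: str,
                      seed: int, true_effects: np.ndarray | None = None
                      ) -> SummaryStats:
    """Noisy GWAS summary statistics for one trait.

    Observed per-allele effects are the true effects plus Gaussian noise with
    standard error 1/sqrt(2 N p(1-p)), p-values two-sided from the z-ratio.
    ``true_effects`` (standardized scale) may be passed to share architecture
    across traits; otherwise a fresh point-normal draw is used.
    """
    spec.validate()
    fcol = f"freq_{ancestry}"
    if fcol not in variants.columns:
        raise ConfigurationError(f"no frequency column for ancestry {ancestry!r}")
    rng = np.random.default_rng(seed)
    M = len(variants)
    if true_effects is None:
        true_effects = simulate_true_effects(M, [spec], seed)[spec.name]
    p = variants[fcol].to_numpy(float)
    scale = np.sqrt(2 * p * (1 - p))
    beta_true = true_effects / scale            # per-allele scale
    se = 1.0 / np.sqrt(2 * spec.gwas_n * p * (1 - p))
    beta_hat = beta_true + rng.normal(0.0, se)
    z = beta_hat / se
    pvals = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    table = pd.DataFrame({
        "SNP": variants["id"], "CHR": variants["chrom"], "BP": variants["pos"],
        "A1": variants["a1"], "A2": variants["a2"],
        "BETA": beta_hat, "SE": se, "P": pvals, "N": spec.gwas_n,
    })
    return SummaryStats(name=spec.name, table=table, h2_zscore=spec.h2_zscore)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return special.expit(x)


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept c with mean(sigmoid(c + eta)) == prevalence."""
    def f(c):
        return float(np.mean(_sigmoid(c + eta))) - prevalence
    lo, hi = -35.0, 35.0
    if f(lo) > 0 or f(hi) < 0:
        raise ConfigurationError(
            f"prevalence {prevalence} unreachable for given liability spread")
    return optimize.brentq(f, lo, hi, xtol=1e-10)


def _genetic_scores(genotypes: GenotypeMatrix, true_effects: dict,
                    specs: list[TraitSpec]) -> dict[str, np.ndarray]:
    """Per-trait genetic score, standardized within ancestry group."""
    D = genotypes.dosages
    scores = {}
    for spec in specs:
        b = true_effects[spec.name]
        if len(b) != D.shape[1]:
            raise ConfigurationError("effect vector length does not match variant count")
        g = D @ b
        out = np.empty_like(g)
        for anc in np.unique(genotypes.ancestry):
            m = genotypes.ancestry == anc
            sd = g[m].std()
            out[m] = (g[m] - g[m].mean()) / (sd if sd > 0 else 1.0)
        scores[spec.name] = out
    return scores


def simulate_phenotypes(genotypes: GenotypeMatrix, true_effects: dict,
                        config: SimulationConfig) -> pd.DataFrame:
    """Generate the cohort table from genotypes and true effect vectors.

    PS arises from a logistic liability threshold: for each trait with a
    configured odds ratio, its standardized genetic score enters the linear
    predictor with coefficient log(OR) + slope*(age - midpoint); the
    intercept is solved per ancestry to hit ``ps_prevalence``.  Comorbid
    flags are then drawn from logistic models conditioned on PS (and, for
    ADHD and trauma, on the ADHD-architecture genetic score), with
    intercepts solved to hit their configured prevalences.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    n = genotypes.n_subjects
    age_lo, age_hi = config.age_range
    age = rng.uniform(age_lo, age_hi, size=n)
    age_mid = 0.5 * (age_lo + age_hi)
    sex = np.array(["M", "F"])[rng.permutation(np.arange(n) % 2)]

    gscores = _genetic_scores(genotypes, true_effects, config.trait_specs)
    anc = np.asarray(genotypes.ancestry)

    # --- PS liability ---
    eta = np.zeros(n)
    slope = config.age_interaction_slope
    for trait, per_anc in config.target_or_per_sd.items():
        if trait not in gscores:
            raise ConfigurationError(f"target_or_per_sd names unknown trait {trait!r}")
        g = gscores[trait]
        for a, orx in per_anc.items():
            m = anc == a
            if not m.any():
                continue
            coef = _LN(orx) + slope * (age[m] - age_mid) * (0.0 if orx == 1.0 else 1.0)
            eta[m] += coef * g[m]
    ps = np.zeros(n, dtype=int)
    for a in config.ancestries:
        m = anc == a
        prev = config.ps_prevalence.get(a)
        if prev is None:
            raise ConfigurationError(f"no ps_prevalence for ancestry {a!r}")
        c = _solve_intercept(eta[m], prev)
        ps[m] = (rng.random(m.sum()) < _sigmoid(c + eta[m])).astype(int)

    cohort = pd.DataFrame({
        "id": genotypes.subject_ids, "age": age, "sex": sex, "ancestry": anc,
        "ps": ps,
    })

    lg = config.comorbidity_logor
    pv = config.comorbidity_prevalence
    g_adhd = gscores.get("ADHD", np.zeros(n))

    def draw_flag(logor_terms: np.ndarray, prevalence: float) -> np.ndarray:
        c = _solve_intercept(logor_terms, prevalence)
        return (rng.random(n) < _sigmoid(c + logor_terms)).astype(int)

    # ADHD DSM flag: tied to PS and weakly to the ADHD genetic score
    cohort["adhd"] = draw_flag(lg["adhd"] * ps + _LN(1.18) * g_adhd,
                               config.adhd_prevalence)
    # symptom endorsement: tied to PS, near-certain among DSM ADHD cases
    cohort["adhd_symptoms"] = draw_flag(
        lg["adhd_symptoms"] * ps + 2.0 * cohort["adhd"].to_numpy(),
        pv["adhd_symptoms"])
    for flag in ("depression", "mania", "anxiety"):
        cohort[flag] = draw_flag(lg[flag] * ps, pv[flag])
    cohort["trauma"] = draw_flag(lg["trauma"] * ps + _LN(1.13) * g_adhd,
                                 pv["trauma"])

    # quantitative severity scales from the shared liability (plus noise);
    # nonnegative integer scores, correlated with each other through eta+ps
    lat = eta + 1.5 * ps + rng.standard_normal(n)
    lat = (lat - lat.mean()) / lat.std()
    prime = np.round(np.clip(np.exp(0.6 + 0.7 * lat + 0.5 * rng.standard_normal(n)) - 1,
                             0, 60)).astype(int)
    sops = np.round(np.clip(np.exp(1.0 + 0.6 * lat + 0.5 * rng.standard_normal(n)) - 1,
                            0, 60)).astype(int)
    cohort["prime"] = prime
    cohort["sops"] = sops

    for sub in ("alcohol", "tobacco", "marijuana", "cocaine", "otc"):
        flag = draw_flag(lg[sub] * ps, pv[sub]).astype(float)
        cohort[sub] = flag
    observed = rng.random(n) < config.substance_coverage
    cohort.loc[~observed, ["alcohol", "tobacco", "marijuana", "cocaine", "otc"]] = np.nan

    logger.info("simulated phenotypes: n=%d, PS prevalence=%.3f (seed=%d)",
                n, ps.mean(), config.seed)
    return cohort


# ---------------------------------------------------------------------------
# one-call orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    variants: pd.DataFrame
    genotypes: GenotypeMatrix
    true_effects: dict
    sumstats: dict              # trait name -> SummaryStats
    cohort: pd.DataFrame

    def genetic_score(self, trait: str) -> np.ndarray:
        """True (noise-free) standardized genetic score for one trait."""
        return _genetic_scores(self.genotypes, self.true_effects,
                               [s for s in self.config.trait_specs
                                if s.name == trait])[trait]


def simulate_study(config: SimulationConfig,
                   sumstats_ancestry: str | None = None) -> SimulatedStudy:
    """Run the full generator: genotypes, effects, sumstats, phenotypes.

    GWAS summary statistics are generated against the allele frequencies of
    ``sumstats_ancestry`` (default: the first configured ancestry, mirroring
    discovery GWAS being predominantly of a single ancestry).
    """
    config.validate()
    variants, genotypes = simulate_genotypes(config)
    effects = simulate_true_effects(config.n_variants, config.trait_specs,
                                    config.seed + 7)
    anc0 = sumstats_ancestry or config.ancestries[0]
    sumstats = {}
    for i, spec in enumerate(config.trait_specs):
        sumstats[spec.name] = simulate_sumstats(
            variants, spec, anc0, config.seed + 31 * (i + 1),
            true_effects=effects[spec.name])
    cohort = simulate_phenotypes(genotypes, effects, config)
    return SimulatedStudy(config, variants, genotypes, effects, sumstats, cohort)
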