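# Methods

`pgs-spectrum` implements a multi-polygenic-score (multi-PGS) analysis of a
binary psychosis-spectrum (PS) phenotype in a two-ancestry youth cohort,
together with a synthetic-data generator that reproduces the statistical
structure the analysis assumes.  This note records the models, the defaults
and their rationale, the numerical choices, and what the synthetic data do
and do not establish.

## 1. Synthetic cohort generator (`synthdata`)

### Genotypes

Ancestral allele frequencies are drawn uniformly on `maf_range` at the level
of LD blocks (one base frequency per block, ±0.01 per-variant jitter).
Per-ancestry frequencies diverge from the ancestral values under a
Balding–Nichols model: Beta(p(1−F)/F, (1−p)(1−F)/F) with F = `fst`
(default 0.1, a typical continental-scale divergence).  Within each block,
one Balding–Nichols quantile is shared by all variants of a block within an
ancestry, so that linked variants share a drift history.  Two consequences
are intended:

* the Hudson ratio-of-averages Fst estimator recovers F on simulated
  panels (the estimator's expectation under this model is F);
* adjacent variants have similar allele frequencies, which is what makes a
  target dosage correlation attainable at all — the correlation of two
  binary variables is bounded by a function of their frequencies (the
  Fréchet bound), so independent per-variant frequency draws would silently
  cap realized LD far below the configured value.

Haplotypes come from a latent Gaussian autoregressive chain per block,
thresholded at the frequency quantile.  The pairwise latent correlations are
**calibrated by tetrachoric inversion** (vectorized bisection on the
bivariate-normal CDF, evaluated via Owen's T) so that the *dosage*
correlation at lag 1 equals `block_rho` (default 0.5).  Correlation decays
geometrically with lag on the latent scale and is exactly zero across block
boundaries.  The calibration targets lag-1; at larger lags the dosage
correlation decays slightly faster than `block_rho^k` because thresholding
attenuates the latent chain's products.  Dosages are hard calls in {0,1,2}.

### Effect architecture and summary statistics

Each source trait draws a point-normal effect vector: a `prop_causal`
fraction of variants receive effects, scaled so the summed per-variant
variance on the standardized-genotype scale equals the panel heritability
`h2`.  Cross-trait structure follows a single-factor model: a latent
liability-architecture vector `u` is shared, and trait t's raw effects are
`rg_t · u + sqrt(1−rg_t²) · noise`, so two traits' effect vectors correlate
as `rg_s · rg_t` (times a masking attenuation of `sqrt(prop_causal)` when
`prop_causal < 1`).

Observed GWAS effects add sampling noise on the per-allele scale with
standard error `1/sqrt(2 N p(1−p))`; p-values are two-sided normal on the
z-ratio.  This reproduces the two facts the scoring layer relies on:
z-scores are standard normal for null variants, and regression of observed
on true effects has slope 1.

### Phenotypes

PS follows a liability-threshold model on the logistic scale: for each trait
with a configured odds ratio, its standardized true genetic score enters the
linear predictor with coefficient

    log(OR_trait,ancestry) + slope · (age − age_midpoint),

and the intercept is solved per ancestry (Brent root-finding on the mean
predicted probability) to hit the configured prevalence exactly in
expectation.  Thresholding standard logistic noise at zero is equivalent, so
the configured OR is exactly the marginal logistic OR per SD of the true
score when a single trait is non-null (the default).  With several non-null
traits the configured values act as conditional log-odds weights and the
marginal ORs are approximate.

Defaults encode the study conditions the package was designed around: 4852
EA and 1802 AA subjects aged 8–22; PS prevalence 15% (EA) and 29% (AA),
~19% overall; ADHD prevalence 5%; OR 1.23 per SD of the ADHD-architecture
score in EA and 1.0 in AA; age-interaction slope −0.015/yr on the log-OR
scale (chosen so the association attenuates visibly but monotonically from
the 8–12 to the 16–22 age bin, the qualitative pattern the analysis layer
must detect).  The configured OR holds at the age midpoint (15 yr); this is
an equivalent reparameterization of a linear-in-(age−8) form.

Comorbid binary phenotypes (DSM ADHD, ADHD symptom endorsement, depression,
mania, anxiety, trauma, substance-use flags) are drawn from logistic models
conditioned on the PS flag, with log-ORs defaulting to the overlap scale the
contingency layer is meant to reproduce (ADHD×PS ln 3.03; symptoms×PS
ln 4.7; mood/anxiety ln 3; trauma ln 2 plus a weak direct genetic term
ln 1.13 per SD; DSM ADHD also carries ln 1.18 per SD of the ADHD score).
Intercepts are again solved to hit configured prevalences.  PRIME and SOPS
quantitative scales are nonnegative integers built from a shared latent
(liability + PS shift + noise) through an exponential link, giving Spearman
correlations in the 0.4–0.6 range between scales.  Substance-use columns are
jointly missing for a random 57% of subjects (43% coverage), emulating
partial instrument administration.

What the generator does **not** emulate: realistic human LD maps and
recombination, chromosome-scale coordinates, imputation uncertainty,
admixture (ancestry is a hard label), family structure, item-level
psychopathology instruments, and ancestry-specific effect sizes beyond the
configured OR map.  Passing tests therefore establish internal consistency
of the statistical machinery under the assumed generative model, not
performance on real genotypes.

## 2. Polygenic scoring (`pgs_engine`)

* **Harmonization**: allele matching with swap (beta negated), strand-flip
  (complement) resolution, and A/T-C/G ambiguous pairs dropped by default
  (`keep_ambiguous` retains them on the literal alleles).  All failures are
  logged exclusions, never errors.
* **Clumping**: greedy by ascending p-value; an index variant claims all
  unclaimed variants within `window_kb` (default 500) with r² ≥ `r2_max`
  (default 0.1).  Ties on p break by (chrom, pos), making the index set
  independent of row order.  Defaults are standard practice; both are flags.
* **Thresholding**: strict `p < p_max`, default 0.05.  Strictness is a
  documented convention (the boundary value is excluded); configurable.
* **LDpred-inf**: within consecutive windows of `2·radius` variants the
  marginal effects are jointly rescaled by solving
  `(D + (m/(n·h2))·I) β_adj = β̂` with D the local LD correlation from the
  target panel.  This is exact when LD is block-diagonal within windows and
  reduces to the closed-form shrinkage `(n·h2)/(n·h2+m)` under identity LD.
  Singular windows receive a logged 1e-6 ridge jitter.  `h2` is a required
  user input; the package does not estimate heritability.
* **PCs**: top-k eigenvectors of the standardized genotype matrix within an
  ancestry group (k = 10 by default), via truncated SVD with a fixed start
  vector (full SVD for small problems); the sign convention (largest
  variant loading positive) makes results reproducible across runs.
* **Correction**: every downstream analysis uses the *corrected score* —
  the least-squares residual of the raw score on [intercept, PCs],
  standardized to mean 0 / SD 1 within the group it was corrected in.
  Missing dosages are mean-imputed per variant within ancestry at scoring
  time only.

## 3. Multi-PGS classification (`multipgs`)

Elastic-net logistic regression over the corrected scores.  Fitting goes
through scikit-learn's saga solver with `C = 1/(n·λ)` (so λ is the
per-observation-average penalty strength); the `unpenalized` covariate mode
instead uses a statsmodels GLM elastic net with per-parameter penalty
weights so age, age² and sex escape shrinkage.  AUC is computed in its
rank-based Mann–Whitney form (ties count one half), identical to the
trapezoidal ROC area.

Hyperparameters are tuned by stratified k-fold CV (strata = outcome ×
ancestry, preventing class-empty folds) over an alpha grid (default 0,
0.1, …, 1.0) and a per-alpha log-spaced lambda path; `lambda_rule='cv_opt'`
(default) takes the CV-best lambda, `'min_grid'` the smallest of the path —
the two readings of "minimal lambda".

Evaluation: stratified 70/30 split, tune+fit on train, AUC on test; repeated
`n_repetitions` times (default 1000).  The permutation null shuffles the
phenotype within ancestry stratum and runs the same single-split procedure
per permutation (default 1000).  Significance is `(r+1)/(n_perm+1)` with r
the count of permutation AUCs at or above the **mean** observed AUC; this
estimator cannot return zero.

A deliberate property of this protocol, worth stating plainly: comparing a
*mean over repetitions* (whose split-to-split noise is averaged away) against
*single-split* permutation AUCs (which retain that noise) makes the test
conservative under the null — its empirical type-I error is well below the
nominal level (about 1% at nominal 5% in our calibration runs).  That is the
protocol as designed; a calibrated variant would average each permutation
over the same number of splits, at `n_repetitions`-fold higher cost.  The
permutation p-values this package reports should therefore be read as
conservative.

`compare_runs` applies a two-sided Wilcoxon rank-sum (Mann–Whitney) test to
two per-repetition AUC vectors (exact p for small tie-free samples).

## 4. Univariate association (`assoc`)

Maximum-likelihood logistic regression of the outcome on one standardized
score with age, centered-age² and sex covariates; OR per SD with Wald 95% CI
and two-sided Wald p.  Age is centered before squaring to reduce
collinearity (score estimates unchanged).  Perfect separation falls back to
a lightly L2-penalized fit flagged `wald=False` rather than failing.
Complete-case analysis with the realized n reported — relevant for the
substance-use covariates, which are missing by design for 57% of subjects.

* Bonferroni cutoff: `alpha/(n_scores·n_cohorts)`; the reported value keeps
  one significant digit (0.05/42 → 0.001), the raw value is retained.
* Interactions: score×modifier Wald test in the full model; age-stratified
  ORs for bins [8,12), [12,16), [16,22] (half-open, last closed — a
  convention the overlapping printed bin labels require).
* Deciles: empirical quantiles with ties to the lower decile, computed
  within the analysis cohort after exclusions; the contrast is a logistic
  fit of outcome on a top-decile indicator restricted to deciles 1 and 10.
  For OR/SD = 1.23 the truncated-normal closed form gives a top-vs-bottom
  OR of exp(ln 1.23 · 2 · φ(z₉₀)/0.1) ≈ 2.07.
* Nagelkerke ΔR²: `R² = (1 − exp(2(ℓ₀−ℓ₁)/n)) / (1 − exp(2ℓ₀/n))`,
  difference between the full and covariates-only model; both fits must be
  on identical subjects.
* Sensitivity refits: row-exclusion rules (column == value, or a callable
  drop-mask) and/or appended covariates, refit through the same estimator
  with post-exclusion n and outcome rate recorded.

PCs are *not* re-entered in these models by default (scores are already
PC-residualized); a caller can add them as extra covariates.

## 5. Phenotypic overlap (`overlap`)

2×2 tables report the cross-product OR (a·d)/(b·c) with a Woolf log-scale
CI, alongside Fisher's exact two-sided p (scipy's convention: summing table
probabilities ≤ the observed).  The cross-product — not the conditional
MLE underlying the Fisher test — is the reported estimator because it is
what printed confusion-matrix ORs correspond to; the conditional MLE is
available via `estimator='conditional_mle'`.  Zero cells: Haldane–Anscombe
0.5 correction for OR/CI only, never for the Fisher p; a zero margin leaves
the OR undefined (flagged) with the Fisher p still returned.  Rank-sum tests
use the tie-corrected Mann–Whitney form; Spearman correlations use midranks
with the large-sample t approximation.

## 6. Pipeline and seeds

`pipeline.run` executes simulate → score → multipgs → assoc → overlap from
one config; per-stage seeds derive from `crc32(master_seed:stage)` (kept
below 2³¹), so re-running one stage is unaffected by another stage's draw
count.  The manifest records seeds, parameters and SHA-256 checksums of all
written tables.  Identical configs yield byte-identical numeric outputs;
one source of cross-process nondeterminism (Python set ordering in allele
assignment) was found and removed — nothing in the package depends on hash
ordering.

## 7. Problem sizes in the test suite

Unit and acceptance tests run scaled-down versions of the analyses: cohorts
of 150–4800 subjects, panels of 200–5000 variants, repetition/permutation
counts of 20–99 (protocol structure — 70/30 split, within-stratum shuffling,
(r+1)/(n+1) estimator — is never altered), and 30–200 replicate batches for
calibration and recovery checks.  The methods themselves default to the
full-scale settings (1000 repetitions / 1000 permutations, 10-fold CV).

## 8. Known limitations

* The LD model is blockwise-autoregressive; clumping behaviour on real,
  long-range LD is not exercised.
* `ldpred_inf` windows are non-overlapping chunks; with LD spanning a chunk
  boundary the solution deviates slightly from the dense solve (exact for
  block LD within windows).
* The permutation significance test is conservative by construction (see
  §3); power statements based on it are pessimistic.
* Cross-ancestry portability is modeled only as a configured null effect in
  the second ancestry, not as LD/frequency-driven attenuation of a shared
  effect.
* OR recovery through the *estimated* PGS is attenuated relative to the
  configured OR by the PGS–true-score correlation (≈0.7 at default panel
  sizes), as expected for noisy score proxies; the configured OR is defined
  against the true score.
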