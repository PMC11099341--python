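# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## The generative model

Standardized log CRP for subject *i* is built from orthogonalized
components,

    y_i = sqrt(v_m) C_i + sqrt(v_g) G_i + Σ_k s_k sqrt(v_k) Q_ik + sqrt(v_e) e_i,

where `C` is the methylation-linked component (a weighted sum of causal
CpG latent scores), `G` a weighted sum of standardized SNP dosages, `Q_k`
confounder components (BMI, smoking score, alcohol, deprivation,
education, age, sex, CD4T fraction, batch), and `e` residual noise. The
components are Gram–Schmidt orthonormalized in-sample before being
combined, so the realized variance decomposition equals the configured
fractions essentially exactly (the spec-level tolerance of ±0.02 is met
trivially); the defaults are v_m = 0.50 and v_g = 0.13, the fractions a
large blood-methylation study of CRP would report. CRP on the natural
scale is `exp(0.6 + 1.0·y)` mg/L, giving a median near 1.8 and a mean
near 3 mg/L, as in adult population cohorts. Low-sensitivity assays flag
readings under 3 mg/L as below detection and the raw value is retained so
the 1.5 mg/L imputation rule stays testable in one place (`preprocess`).

Methylation is generated on a logistic latent scale and mapped through the
inverse logit, which guarantees beta-values in (0, 1) while keeping the
effect structure additive. Probes come in blocks of 1–5 sites placed
within 2.5 kb that share a block factor with within-block latent
correlation 0.7 by default (a parameter: the field reports "densely
correlated regions" without a number; 0.7 keeps pairs above the 0.5
grouping threshold after the mild logistic attenuation, realized ~0.63 on
the beta scale).

Three structural choices deserve explanation:

* **Causal CpGs sit on singleton blocks.** Each causal site carries an
  independent inflammation-linked signal; correlated blocks model the
  local co-methylation background. If instead causal weights are drawn
  independently *within* a correlated block, the block encodes
  near-cancelling contrasts, and no probe-level sum-of-squares estimator
  can represent its variance contribution without contrast inflation —
  the estimand itself becomes ill-posed. Tying signal to independent
  sites keeps the generative decomposition identifiable on the probe
  scale, which is what parameter-recovery tests require.
* **Confounding is concentrated.** Five percent of non-causal probes load
  on BMI or smoking with coefficients 0.5–1.0 (plus broad cell-composition
  and batch structure on ~30%/20% of probes). These probes correlate with
  CRP purely through the confounder paths, so basic-model EWAS hits on
  them vanish under full adjustment — the attenuation behavior the EWAS
  stage tests.
* **The genetic architecture is oligogenic at desk scale** (5 causal SNPs
  of 500 by default). A thresholded polygenic score needs individually
  genome-wide-detectable SNPs; spreading 13% of variance over 50 SNPs at
  n = 1,000 gives per-SNP p ≈ 0.1 and an empty score. Five SNPs at ~2.6%
  each are detectable at the desk-scale discovery threshold, letting the
  score's incremental R² land on the generative fraction.

What the generator does **not** emulate: array chemistry and normalization
artifacts, realistic LD maps, cell-type-specific methylation profiles,
related individuals, and non-linear CpG–CRP relationships. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative law, not robustness to those real-data features.

## Preprocessing

CRP is mapped to `log(x + 0.01)` after assigning 1.5 mg/L to
low-sensitivity below-detection readings; wide-range assays are treated as
the high-sensitivity branch (no imputation). The median ± 4·SD exclusion
runs on the log scale, after imputation (the ordering is not dictated by
the protocol; imputation-first is recorded in the prepared phenotype). SD
is the plain sample standard deviation. SNP QC removes markers with
missing call rate > 2%, HWE chi-square p < 1e-6 (one-degree test on hard
genotype counts), or MAF < 1%, then mean-imputes residual missingness.

## EWAS

Per-probe statistics come from the Frisch–Waugh–Lovell identity: phenotype
and all probes are residualized on the covariate design once (QR), and
per-probe simple regressions on the residuals reproduce the
multiple-regression coefficient, SE and t test exactly with the full
model's degrees of freedom — verified against `statsmodels` OLS to 1e-8.
λ is the median of the implied 1-df chi-square statistics over 0.4549.
Attenuation uses absolute effects, `100·(|b_basic| − |b_adj|)/|b_basic|`,
averaged over basic-model hits. The epigenome-wide threshold 3.6e-8 is a
configurable default calibrated to ~7.5e5 probes and tens of thousands of
samples; desk-scale runs use 1e-4, chosen to play the same role (a
discovery threshold that basic-model confounded probes can clear) at
n = 1,000 and m = 2,000.

## Bayesian mixture regression

On standardized data, each effect has prior
`π0 δ0 + Σ_c π_c N(0, σ²_c)` with σ²_c ∈ {0.001, 0.01, 0.1} — single
features explaining 0.1%, 1% or 10% of phenotypic variance. The variances
are fixed fractions of the (unit) phenotypic variance rather than being
rescaled by a sampled hyper-variance; both conventions exist in the
software lineage and the fixed reading keeps the calibration identity
exact. The residual variance has a weak scaled-inverse-chi-square prior
(ν0 = 4, s0² = 0.5).

Mixture proportions have a Dirichlet prior with spike pseudo-count
`1 + 0.2·m` and 1 per slab. A fully exchangeable flat Dirichlet is the
textbook choice, but at desk-scale sample sizes the smallest slab sits at
the spike/slab detectability floor (n·σ²_1 of order σ²_e): the
per-feature Bayes factor then satisfies E[BF] = 1 under the null, the
mixture weights have no drift toward sparsity, and the sampler reports
~75% inclusion for pure noise. The feature-count-scaled spike pseudo-count
restores null sparsity while leaving detectable effects untouched — their
log Bayes factors sit far above the prior log-odds penalty, and the slab
counts self-calibrate once signal enters. Note that under a global null a
feature whose *chance* correlation reaches ~4σ (which happens in a
sizeable fraction of 200-feature panels at n = 500) still correctly earns
a high inclusion probability: it is genome-wide significant by frequentist
standards too.

Sampling follows the reference protocol: 10,000 iterations, 5,000
burn-in, thinning 5, four chains with distinct seeds, final 250 thinned
draws per chain pooled (1,000 draws). The desk-scale configuration (1,000
iterations, 500 burn-in, thinning 2, two chains; 500 pooled draws) is used
in tests so fits complete in seconds; the update order is re-randomized
every sweep. The variance attributed to a class is the mean over pooled
draws of Σ_j β²_j; the 95% credible interval is read at ascending ranks
⌈0.025·T⌉ and ⌊0.975·T⌋ (25 and 975 at T = 1,000). Probe grouping seeds
leads at PIP > 0.20 (descending PIP, ties by genomic position), absorbs
unassigned probes within 2.5 kb and |r| > 0.5 with the lead (each probe in
at most one group), and reports groups whose union inclusion probability
exceeds 0.80.

For validation, the sampler can fix the residual variance and the mixture
proportions, making the single-feature posterior available in closed form
(mixture of conjugate normals); the acceptance suite checks the sampled
posterior mean against it within Monte-Carlo error.

## REML

The relationship matrix is `A = Z Zᵀ/m` for column-standardized features
(GRM variant standardizes by sqrt(2·MAF·(1−MAF))). Variance components are
fitted by average-information REML with EM fallback steps whenever the AI
step fails or decreases the restricted likelihood, variance floors at
1e-6, and convergence at |Δ log L| < 1e-8; the likelihood path is returned
so monotonicity is observable. Confidence intervals are Wald
(estimate ± 1.96·SE via the inverse AI matrix and a delta-method SE for
the fraction), truncated to [0, 1]. `--grm-cutoff`-style relatedness
pruning removes the max-degree sample of each over-threshold pair until
none remain.

**Cross-method agreement.** Bayesian Σβ² and ORM-REML estimate the same
fraction only when both estimators' assumptions hold. On the
block-structured default cohort they diverge by construction: causal
probes are singletons with below-average correlation to the rest of the
panel, and REML's equal-weight ORM then over-weights the correlated
background (the classic correlation-profile mismatch bias), landing ~0.07
high or low depending on architecture, while the sparse Bayesian estimator
is insensitive to the background. The dedicated consistency experiment
therefore uses an exchangeable panel — 500 independent probes, 20 causal,
n = 2,000 — where both are unbiased; measured agreement is within 0.02,
and the pipeline asserts only loose (< 0.15) agreement on the
block-structured default.

**Parameter recovery conditions.** The credible-interval coverage check
runs 20 replicate cohorts at n = 1,000, m = 2,000 with a true methylation
fraction of 0.40 carried by 20 causal probes (0.02 each) and no
confounding — an architecture where every causal effect is individually
detectable, so the estimator is validated where the data are informative.

## Predictors

Elastic net uses mixing parameter 0.5, a 100-value log-spaced penalty path
spanning a 1e-4 range below the data-derived maximum, and seeded k-fold CV
(20 folds at full scale; the pipeline's desk runs use 50 path values);
the penalty at minimum mean CV error is kept. Standardized-scale
coefficients are stored on the raw beta scale (`w_raw = w_std / sd`,
intercept adjusted), so projection into any cohort is a dot product over
the probes it contains; training means/SDs travel with the weights for
mean-imputation and audit, and serialization uses `repr` floats so weights
round-trip bit-exactly. PCA+elnet mean-centers (does not scale) the
pre-filtered probes, keeps all non-degenerate principal components (no
cap), fits the same elastic net on component scores, and composes
`w = L·c`, `intercept = a − μᵀw` — verified as an algebraic identity
against the component-space predictions. The Bayesian predictor applies
the same back-transformation to posterior-mean effects from a fit on
scaled-but-unadjusted data. Missing probes at projection default to
omission (mean-imputation is available); projection requires at least 50%
of weight probes present. Raw-beta application of back-transformed weights
(rather than re-standardizing in the test cohort) is the convention
adopted for published weight tables. A lifestyle-augmented elastic net is
available behind `extra_features`; selected extras are recorded in
provenance but excluded from the portable probe-weight file.

## Evaluation

Correlations carry Fisher-z 95% CIs. Incremental R² is R²(full) −
R²(null) with null `y ~ age + sex` (the full model nests the null, so the
quantity is non-negative); additions can be stacked (genetic score first,
then DNAm). ICC(2,k) — two-way random effects, absolute agreement,
average measures — is computed from ANOVA mean squares on complete cases
and cross-checked against `pingouin` to 1e-10. The longitudinal mixed
model regresses repeated log CRP on baseline × age with sex and a random
intercept per subject (REML, Wald test); singular random-effect fits fall
back to OLS with a flag. The outcome battery standardizes continuous
variables, uses OLS / logistic / Cox (Efron ties, via lifelines), adjusts
for age and sex (plus height for flagged outcomes, per the
lung-function/walk-test convention), flags binary outcomes with fewer
than 10 events, and applies BH-FDR within each exposure's 26-outcome
family. Polygenic scores sum effect × aligned dosage over SNPs passing
p < 5e-8 (desk-scale runs use 1e-4, matching the discovery power of the
simulated GWAS), negating effects for allele-swapped SNPs and dropping
unresolvable ones with a warning.

## Problem sizes and determinism

Default study sizes — 1,000 training samples, 2,000 probes, 500 SNPs, 600
test samples, reduced MCMC — were chosen so the full pipeline completes in
about a minute and the entire test suite in a few minutes on one core,
while keeping every qualitative contrast (confounding attenuation,
feature-selection superiority, stability ordering, variance recovery)
comfortably resolved. One master seed fans out to named substreams per
stage; identical seeds give bit-identical cohorts and summaries. Pipeline
configurations can be loaded from a TOML file (`RunConfig.from_toml`;
TOML because the standard library parses it without extra dependencies);
all tabular outputs are plain TSV.

## Known limitations

The sampler stores dense per-draw effect vectors (fine at desk scale;
hundreds of thousands of probes would need sparse storage). REML forms
dense n × n matrices (n ≲ 5,000 practical). The generator's confounders
are mutually independent, which understates real collinearity between
lifestyle factors. Kinship structure and mixed-model EWAS are out of
scope; synthetic samples are unrelated.
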