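# methylcrp

Blood DNA-methylation analysis of chronic low-grade inflammation, packaged
as a tested, fully synthetic study replica.

C-reactive protein (CRP) is the standard blood marker of systemic
inflammation, but single measurements are phasic — they spike with
infection and injury — so one assay is a noisy index of a person's
long-term inflammatory burden. DNA methylation (DNAm) at CpG sites shifts
slowly with sustained exposures (adiposity, smoking, chronic inflammation
itself), which makes weighted combinations of methylation beta-values
attractive as *stable* surrogates of chronic CRP. This package implements
the complete analysis arc behind that idea, for methods developers and
epidemiologists who want every step runnable, seeded and unit-tested on
cohorts with known ground truth:

1. **Synthetic cohorts** (`methylcrp.simulate`) — samples × CpG beta-value
   matrices with correlated probe blocks within 2.5 kb, SNP dosages in
   Hardy–Weinberg proportions, CRP in mg/L with high-/low-sensitivity
   assay behavior, lifestyle/cell-composition/batch confounding,
   longitudinal waves, 26 health outcomes, and a recorded ground-truth
   variance decomposition.
2. **Preprocessing** (`methylcrp.preprocess`) — low-sensitivity readings
   below 3 mg/L set to 1.5 mg/L, the log(CRP + 0.01) transform, the
   median ± 4 SD exclusion, OLS residualization (granulocytes dropped from
   cell designs), and SNP QC (call rate > 98%, HWE p ≥ 1e-6, MAF ≥ 1%).
3. **EWAS** (`methylcrp.ewas`) — per-probe linear models
   `log(CRP + 0.01) ~ CpG + covariates` under basic and fully adjusted
   covariate sets, genomic inflation λ, attenuation summaries, cross-study
   effect-size comparison.
4. **Bayesian mixture regression** (`methylcrp.bayesr`) — a Gibbs sampler
   for the spike-plus-three-Gaussian prior
   `b_j ~ π0 δ0 + π1 N(0, 0.001) + π2 N(0, 0.01) + π3 N(0, 0.1)`
   (slab variances as fractions of phenotypic variance), over one or two
   feature classes; posterior inclusion probabilities, grouping of
   correlated close probes, and variance partitioning via the mean of
   per-draw sums of squared standardized effects with rank-based credible
   intervals.
5. **REML cross-check** (`methylcrp.reml`) — omics/genomic relationship
   matrices `A = Z Zᵀ / m` and AI-REML variance components
   `σ²_g / (σ²_g + σ²_e)`.
6. **Predictors** (`methylcrp.predictors`) — elastic net (α = 0.5, 20-fold
   CV, λ at minimum CV error), Bayesian posterior-mean weights, PCA +
   elastic net with external pre-filtering and CpG-space weight
   composition, and EWAS-weight scores; portable raw-beta-scale weight
   files and missing-probe-tolerant projection.
7. **Evaluation** (`methylcrp.evaluate`) — Pearson correlations with
   Fisher-z CIs, incremental R² over age + sex, ICC(2,k) temporal
   stability, a baseline × age mixed model, a 21-continuous/4-binary/
   1-survival outcome battery with BH-FDR, and additive polygenic scoring
   with allele alignment.

`methylcrp.pipeline.run_pipeline` chains everything; the numbered scripts
under `analysis/` run the study stage by stage and write tables under
`results/`.

## Worked example

```bash
cd analysis
python 01_simulate_cohorts.py
python 03_variance_partition.py
```

prints, for the default study (1,000 training samples, 2,000 probes, a
true methylation fraction of 0.50 and genetic fraction of 0.13):

```
  component  estimate    lower    upper method conditioning
methylation  0.538521 0.476270 0.610687  bayes
methylation  0.549321 0.501136 0.601632  bayes      genetic
    genetic  0.135775 0.111737 0.159257  bayes  methylation
methylation  0.452894 0.356953 0.548834   reml
```

The Bayesian sampler attributes ~54% of age/sex-adjusted log-CRP variance
to genome-wide methylation (the adjusted-scale target is slightly above
the raw 0.50 because adjustment removes some non-methylation variance),
essentially unchanged when conditioned on genetics — i.e. the methylation
and genetic signals are largely independent — and the genetic component
lands on its generative value. The REML point estimate is lower on this
block-structured cohort; `docs/methods.md` explains why the two estimators
weight correlated probes differently, and the test suite shows they agree
within 0.02 on an exchangeable probe panel.

Training and projecting the five predictors
(`04_train_predictors.py`, `05_evaluate_predictors.py`) yields, on a
held-out cohort of 600 with 25 probes absent:

```
   method        r  incremental_r2
    elnet 0.740309        0.548770
    bayes 0.739041        0.548680
pca_elnet 0.682782        0.466044
 ewas_ref 0.596537        0.353974
 ewas_own 0.396042        0.160703
```

Feature-selection methods (elastic net, Bayesian, PCA+elnet) clearly beat
scores that reuse mass-univariate EWAS weights, and the DNAm score is far
more temporally stable than phasic assay CRP (ICC2k 0.99 vs 0.83 over
three simulated waves).

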