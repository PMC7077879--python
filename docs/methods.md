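# Methods

## The model

`ctxlife` analyses life span measured on a panel of fully inbred lines
reared as replicated groups in a crossed design: two sexes × several
thermal environments × replicate vials nested in line × temperature.
Because every line is a fixed, replicable genotype, the phenotypic
variance decomposes into components attributable to genotype and to its
interactions with the observable contexts:

    Y = μ + S + T + S×T                    (fixed: sex, temperature)
        + L + L×S + L×T + L×S×T            (random: line and interactions)
        + Rep(L×T) + S×Rep(L×T) + ε        (random: vial terms, error)

All derived quantities follow from the estimated components:

- broad-sense heritability `H² = σ²_G / (σ²_G + σ²_ε)` where `σ²_G` is
  the sum of every line-containing component in the fitted model.  Vial
  components are excluded from both numerator and denominator (they are
  rearing-unit effects, not genotype or individual micro-environment);
  they are always reported separately, so the alternative convention
  (pooling vial variance into σ²_ε) can be recomputed from the output.
- coefficients of variation `CV_G = 100 σ_G / x̄`, `CV_ε = 100 σ_ε / x̄`,
  with `x̄` the average of the female and male means in that context.
- cross-context genetic correlations, as variance ratios of the reduced
  models: `r_GMF = σ²_L/(σ²_L+σ²_LS)` from the two-sex model within one
  temperature, `r_GT = σ²_L/(σ²_L+σ²_LT)` from the one-sex model across
  temperatures, and `r_GST = σ²_L/(σ²_L+σ²_LS+σ²_LT+σ²_LST)` from the
  full model.  These ratios are non-negative by construction.
- the interaction decomposition for a pair of contexts A, B with genetic
  SDs `σ_A`, `σ_B` and correlation `r`:

      rank  = σ_A σ_B (1 − r)        (genotypes change rank order)
      scale = (σ_A − σ_B)² / 2       (genetic scale changes)

  with `rank + scale = (σ_A² + σ_B²)/2 − r σ_A σ_B`, the pairwise
  interaction variance, exactly (an algebraic identity, tested to
  machine precision).  `% rank = 100·rank/(rank+scale)` is reported as
  NaN when both terms are zero; the multi-temperature aggregate is the
  mean over the `t(t−1)/2` pairs.

## REML estimation

Variance components are estimated by REML with non-negativity enforced
through bound-constrained L-BFGS-B (convergence tolerance 1e-12 on the
scaled objective, ~1e-8 relative in the log-likelihood).  The engine
exploits two exact reductions rather than building an n×n covariance:

1. every random effect is constant within a (line, sex, temperature,
   vial) cell, so the likelihood factorises into a χ² term for the
   pooled within-cell sum of squares (involving only σ²_ε) plus a
   Gaussian likelihood of the cell means;
2. the cell-mean covariance is block diagonal by line, and lines with
   the same design pattern (same contexts, vial counts and cell sizes)
   share one Cholesky factorisation per likelihood evaluation.

A full-scale fit (186 lines, ~80k observations, 6 components) takes
about one second.  Estimates agree with `lme4::lmer` to ≥4 significant
digits and with the closed-form balanced one-way ANOVA estimator (both
are oracle tests in the suite).  Standard errors come from the inverse
observed information (central-difference Hessian); they are reported as
NaN for components on the zero boundary, where the quadratic
approximation fails.  Random terms are tested by REML likelihood-ratio
tests with the boundary-corrected 50:50 χ²₀/χ²₁ mixture.  Unbalanced
data — missing line × temperature cells, unequal cell sizes — are
handled natively; a constant response returns an all-zero, explicitly
degenerate fit.  Fixed-effect denominator degrees of freedom are not
uniquely defined in unbalanced mixed models; GLS Wald statistics are
provided, with the likelihood-ratio tests as the primary inference for
random terms.

## Micro-environmental variance

The variance phenotype of a genotype is `lnσ_ε = ½ ln S²`, the log
within-line standard deviation.  To make it replicable, the vials of
each (line, sex, temperature) cell are split into two groups (first
half vs second half of vial ids, e.g. 1–12 / 13–24; the split point is
configurable) and S² is the unbiased sample variance pooling all
individuals of a group — deliberately including between-vial along with
within-vial variation.  Cells that cannot be split and groups with
n < 2 or zero variance are excluded with warnings.  The resulting table
feeds straight back into the REML machinery with `ln_sigma_eps` as the
response (no vial terms), giving the heritability and the GSI/GEI
decomposition of micro-environmental variance.

Two heterogeneity tests accompany it, run per sex × temperature:

- **Brown-Forsythe**: one-way ANOVA of `z_ij = |y_ij − median_j|` with
  (k−1, N−k) df (scipy's median-centred Levene).  Ties at the median
  with even n use the standard sample median.  The test is exact in
  form but *conservative as the number of groups grows*: measured
  type-I error is ~0.05 at k = 2 but ~0.02 at k = 180 groups of n = 64.
  Calibration is therefore asserted at k = 12 where the F reference is
  accurate; at panel scale rejections are understated, never inflated.
- **Cochran's C**: `C = max_j S²_j / Σ_i S²_i`, with the p-value from
  the classical critical-value relation
  `C_crit = 1/(1 + (k−1)/F_{α/k}(ν, (k−1)ν))`, `ν = average n − 1`,
  inverted in closed form: `p = k · P(F_{ν,(k−1)ν} > (k−1)C/(1−C))`,
  clipped to [0, 1].  This union-bound construction is essentially
  exact at small α and mildly conservative otherwise.

## Line-mean GWA

Phenotypes are line means per context plus the derived contrasts: sex
average and sex difference (oriented M − F) per temperature,
temperature-pair differences per sex (oriented higher − lower), and the
sex difference of each temperature difference (variant-by-sex-by-
temperature interaction).  Lines missing a constituent context carry
missing contrasts.  The phenotype is residualised on fixed covariates
(Wolbachia infection status, inversion karyotypes, optionally the
leading genotype principal components as a light-weight relatedness
adjustment) and each variant with minor-allele frequency above 0.05 is
tested by OLS of the residual on minor-allele dosage (0/2 in inbred
lines; heterozygous or missing calls are dropped per variant).
Two-step residualisation rather than a joint fit is used deliberately:
at these covariate counts the difference is negligible and the scan
vectorises over the full variant set.  Minor-allele orientation is
fixed once at scan time so effect-sign summaries are well defined.
Variants reported at p < 1e-5 are classified across contexts as
context-specific, antagonistic (significant with opposite signs) or
concordant, with cross-context Spearman effect correlations and LD r²
among reported variants.

## Pooled-sequencing xQTL tests

In the outbred cohort, the longest-lived 10 % (96 flies) of each
replicate cohort form the H pool and 96 independently collected young
flies the C control pool.  The pool allele frequency is
`f̂ = alt/(ref+alt)` with a two-stage binomial variance — 96 diploid
flies into the pool, then reads from the pooled DNA:

    Var(f̂) = f̃(1−f̃) (1/(2·96) + 1/reads)

where `f̃ = (alt+0.5)/(reads+1)` is used inside the variance only, so a
fixed count cannot produce a zero variance (Δf itself is unmoderated).
The within-context statistic is `Δf̄`, the mean over replicates of
`f̂_H − f̂_C`, with model variance summed over contributing pools over
R²; `Z = Δf̄/√Var` is referred to the standard normal, with reporting
at p < 1e-7 and a Bonferroni annotation computed from the analysed
variant count (never hard-coded).  The empirical between-replicate
variance is carried as a diagnostic only — two replicates are too few
to replace the model variance.  Cross-context contrasts difference two
independent within-context statistics (variances add): sex within
temperature (M − F), temperature pairs within sex (higher − lower), and
the sex-by-temperature double difference.  Under the null generator the
within- and cross-context Z are standard normal to within Monte-Carlo
error (acceptance tests over 10⁴ variants).

## GO enrichment with gene-length correction

Long genes are bigger mutational/LD targets, so candidate sets from GWA
are length-biased.  The corrected test keeps the observed per-term
overlap but draws its null from `N` random gene sets of the same size
sampled from the universe *without replacement with probability
proportional to gene-body length*; `p = (B+1)/(N+1)` with `B` the
number of null draws reaching the observed overlap, and
Benjamini-Hochberg FDR across terms.  Sampling uses exponential race
keys, which is distributionally identical to sequential
draw-remove-renormalise (verified against a literal sequential oracle).
The naive hypergeometric p is reported alongside; with equal lengths
the two agree, and on length-biased sets the naive test flags long-gene
terms that the corrected test correctly absorbs (both behaviours are
acceptance-tested).  Annotations are used as given — no GO-graph
ancestor propagation.  Note that the permutation p is discrete and
tie-inflated: its null mean sits slightly above 0.5 even though the
rejection rate is nominal.

## The synthetic-data generator

The generator emulates the study design, not fly biology:

- **Panel**: 186 lines × 2 sexes × 3 temperatures (18/25/28 °C) × 24
  vials × 3 flies/sex/vial (= 72 flies/sex/line/temperature), with
  whole line × temperature cells dropped at rates mirroring the lines
  lost to poor viability (3/186 at 18 °C, 9/186 at 28 °C).  Context
  means default to the published sex × temperature means.  Life span is
  the sum of independent Gaussian draws for each model term, with the
  fly-level residual SD made heritable through a log-normal line
  structure (`exp(ln σ_ε + λ_L + λ_LS + λ_LT)`, default log-SDs
  0.23/0.11/0.15, matching the observed scale of heritable
  micro-environmental variance).  Default component SDs (8, 4, 7, 4, 3,
  12 days) sit at the observed 25 °C scale.  Draws are censored at a
  1-day floor (the observed minimum life span).
- **Outbred cohort**: founder haplotypes (40 founders, target
  frequencies uniform on (0.05, 0.5), resampled until segregating) set
  per-variant allele frequencies; cohort genotypes are drawn
  per-variant at those frequencies, i.e. at linkage equilibrium.  Life
  span is baseline + Σ context-dependent additive effects × dosage +
  Gaussian noise (residual SD a free parameter, default 10 days — the
  study does not report the outbred cohort's environmental variance).
  Each of the 2 replicates is an independent cohort of 960 flies per
  sex per temperature, as in the field design; C pools are independent
  draws of 96 young flies.  Sequencing is binomial read sampling at a
  per-variant, per-pool coverage uniform on 130–156×.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: linkage disequilibrium and
haplotype structure (xQTL statistics are per-variant, so LD realism is
out of scope by design), non-Gaussian life span distributions and
age-specific hazards, selection over generations, sequencing error
beyond binomial sampling, and Wolbachia/inversion covariate structure.

## Numerical and design choices

- REML parameter recovery (acceptance) is evaluated with context means
  set 30 days above the published means: at a 27-day mean the 1-day
  floor censors ~3 % of draws and biases σ²_ε by several times its
  (tiny, ~0.5 %) standard error, which would test the censoring
  artifact rather than the estimator.  Components for that check are
  homoscedastic so the generative values are exactly the estimands.
- The bounded REML estimate of a truly null variance sits on the zero
  boundary roughly half the time (it is zero iff the between mean
  square does not exceed the within mean square), not almost always;
  the boundary test asserts accordingly.
- Problem sizes in the test-suite simulations (e.g. 50 recovery
  replicates, 10⁴ null variants, 1000 heterogeneity-test sims, 12-line
  calibration panels) were chosen as the smallest sizes at which the
  Monte-Carlo error is well inside each acceptance band.
- Tie-breaking in H-pool selection uses a seed-stable random jitter, so
  pool membership is reproducible.
- The relatedness adjustment of the original line-mean GWA pipeline is
  simplified to fixed-effect covariates plus optional genotype PCs; the
  switch is `n_pcs` in `marker_scan`.  Exact reproduction of the
  original pipeline's mixed-model adjustment is out of scope.
- Gene "length" is gene-body length (end − start + 1); swap in
  transcript length by supplying a different length Series.

## Known limitations

- Fixed-effect F tests in unbalanced mixed designs use moment-based
  error strata (exact for balanced data, flagged approximate
  otherwise); no Satterthwaite/Kenward-Roger df.
- Cochran's C p-values use the average group size; strongly unequal
  group sizes degrade the approximation.
- The permutation enrichment p cannot go below 1/(N+1); raise `n_perm`
  for deeper significance.
- Published discovery counts that depend on the full raw sequence data
  (genome-wide variant tallies, overlap gene counts) are not
  reproducible from synthetic data and are out of scope; the package
  reproduces the derived-statistic tables exactly and the inferential
  machinery property-by-property.
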