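# Methods

## The score and its panel

The instrument is a fixed-weight LDL-C polygenic score: ten SNPs contribute
`weight × risk-allele dosage` (weights in score units on an mg/dL scale, from
a large lipid GWAS meta-analysis), and the two APOE ε-defining SNPs
contribute through a six-level diplotype weight table rather than per-allele
terms, because the APOE effect on LDL-C is haplotypic (ε2ε2 −34.75 … ε4ε4
+7.72, ε3ε3 the zero reference). The packaged panel file transcribes the
published table: risk alleles, weights, 6-SNP membership flags, and
minor-allele / diplotype frequencies for three groups — population controls,
FH mutation-negative (FH/M−) and FH mutation-positive (FH/M+).

Two transcription choices deserve note. First, risk-allele orientation is
stored explicitly (`risk_is_minor`), because frequency columns list *minor*
alleles while five of the ten weighted SNPs have a *common* risk allele; the
orientation set is cross-validated in aggregate by the requirement that the
analytic group means reproduce the published values within 0.2 units. For
rs3757354 the published typography is ambiguous; the common allele (C) is
stored as the risk allele because only that orientation reproduces the
published means (the alternative shifts the control mean by ≈ 1.4 units).
Second, frequencies are stored exactly as printed (3 decimals, no
renormalization); the published APOE diplotype vectors of the FH groups sum
to 0.885 and 0.930, not 1.

## Analytic oracles

With risk-allele frequency `f_j` (MAF or 1−MAF by orientation):

- expected score = `Σ_j w_j·2f_j + Σ_D π_D·w_D`, with diplotype frequencies
  `π_D` used **as printed** — this reproduces the arithmetic context of the
  published table, and is the quantity compared against the published group
  means (agreement ≤ 0.2 units, limited by frequency rounding);
- Hardy–Weinberg variance = `Σ_j w_j²·2f_j(1−f_j) + Var_π(w_D)` with
  **renormalized** `π_D` — this is the simulator's calibration oracle. Real
  cohorts carry linkage disequilibrium this ignores, so it is not an estimate
  of any observed SD (it gives SD ≈ 8.6 for controls vs 9.13 observed).

The printed-vs-renormalized split is deliberate: reproduction fidelity and
probabilistic validity serve different purposes, and the package keeps both
explicit rather than silently renormalizing everywhere.

## Genotype input and APOE calling

Variants are matched by rsID only; positions, build and strand are ignored.
A VCF record whose REF/ALT pair is not exactly the panel's two alleles (in
either order) is an error — never auto-complemented, because at 12 SNPs a
frequency-based strand heuristic is unsafe. Dosages are oriented to the risk
allele at read time; `./.` and half-calls are missing. Missing data is
explicit and propagates to scoring, where the policy is chosen: `fail`
(default — the source analyses use complete data), `omit` (missing terms
contribute 0, count reported), or `expected_impute` (missing dosage replaced
by `2f` of a named group).

The ε-diplotype is called by counting rs429358-C haplotypes (ε4 or ε1) and
rs7412-T haplotypes (ε2 or ε1): with `n3 = 2 − n4 − n2`, a negative `n3`
forces the vanishingly rare ε1 = (C,T) haplotype and returns UNKNOWN. The
doubly heterozygous genotype (CT, CT) is phase-ambiguous between ε2/ε4 and
ε1/ε3; it is resolved to ε2ε4 (and logged), since the published diplotype
table has no ε1 class. The caller is tested against exhaustive enumeration
of all nine unphased two-SNP genotypes.

## Phenotype preparation

- Treated subjects' LDL-C is corrected to an estimated untreated value by the
  fixed multiplier **1.43** whenever no measured baseline exists; a recorded
  pre-treatment baseline always wins. A `factor` mode applies the multiplier
  unconditionally, exposing the alternative convention (the source is silent
  on which was used in its control-group regressions).
- Treatment response = `100 × (baseline − on-treatment) / baseline` percent.
- CAC categories: 0, 1–99, 100–400, >400 Agatston units, with the boundaries
  closed on the moderate side so the binary high-burden flag (≥ 100) is
  exactly the union of moderate and severe. Scores at the precise boundaries
  are rare and the convention is documented rather than consequential.

## Association analyses

- Quantile strata use linear-interpolation empirical quantiles with ties to
  the lower stratum; group means are insensitive to the rule at these sizes.
- LDL-C ~ score is ordinary least squares; adjusted R² is
  `1 − (1−R²)(n−1)/(n−p−1)`; the slope CI is t-based.
- The CAC model is maximum-likelihood logistic regression of the ≥ 100 flag
  on indicator-coded score quartiles (reference Q1) with age (years) and sex
  (male = 1); a second fit with the quartile as an ordinal numeric gives the
  trend OR. Intervals are Wald, `exp(β ± 1.96·SE)`, matching the symmetric
  published intervals; non-convergence or unstable SEs (separation) raise
  rather than report.
- Group comparisons: chi-square for counts (with Yates continuity correction
  on 2×2 tables — this choice reproduces the published MI p = 0.011 and
  stroke p = 0.988 from the printed counts, where the uncorrected statistic
  gives 0.008 and 0.83), Mann–Whitney U for two continuous groups,
  Kruskal–Wallis for three or more with pairwise Mann–Whitney/Bonferroni
  post hoc. All tests two-sided at α = 0.05.

## The synthetic cohort generator

The generator's defaults are the study conditions: group sizes 1605/491/193,
genotypes drawn `Binomial(2, f)` per locus under HWE and linkage equilibrium
from each group's published frequencies, and APOE diplotypes drawn from the
renormalized published vectors, back-converted to SNP genotypes (ε2ε4 →
(CT, CT)).

Baseline LDL-C is additive in the 12-SNP score:
`intercept + effect_scale·(PRS − E[PRS]) + N(0, residual_sd)`, with
group intercepts at the published baseline medians (127 / 239 / 277 mg/dL),
`effect_scale = 1` (the score's own mg/dL scale) and `residual_sd = 40`
mg/dL, chosen so the score's variance share in controls is ≈ 0.045, matching
the published adjusted R² ≈ 0.044. A positivity guard rejects baselines
below 1 mg/dL (< 0.1% of draws; low enough not to distort the linear-Normal
model).

**Ascertainment** is the FH groups' defining feature: enrollment required
baseline LDL-C ≥ 210 mg/dL, modeled as per-subject rejection sampling of the
noise term at that floor (iteration-capped, with an explanatory error if the
configuration makes the floor unreachable). This is a modeling
interpretation, and it is what mechanically attenuates the within-FH
score–LDL-C gradient: high-score subjects clear the threshold on genetics,
low-score subjects only with large positive noise, compressing the tertile
separation — the package's explanation of the null tertile result in the FH
groups, verified as a strict inequality in the tests.

Therapy is Bernoulli per group (0.71 / 0.82 as published; 0.05 assumed for
controls, where the source does not report it); percent reduction under
therapy is truncated-normal on [0, 100) with mean 48% in FH groups (implied
by the published baseline→on-treatment medians 239→121 and 277→145) and 30%
in controls (consistent with the 1.43 correction's implied average). A
recorded pre-treatment baseline is available for 46% of treated subjects, as
in the source. Ages are normal approximations of the published median/IQR
(50±9, 56±12.5, 47±16, clipped to [20, 90]); female fractions 0.541 / 0.684
/ 0.601; event and comorbidity rates are the published group frequencies
(controls' event history is not collected, mirroring the source table).

CAC is zero-inflated: the high-burden (≥ 100) probability is logistic with
the published age/sex/intercept estimates (−10.77, ln 1.14 per year, ln 6.00
for male) plus a within-cohort score-quartile term reaching log-odds 0.55
(OR ≈ 1.7) in Q4; subjects not at high burden are zero with a logistic
probability calibrated (intercept 1.6) so the asymptotic control
zero-fraction is ≈ 0.73, satisfying the > 70% condition; the positive strata
are lognormal with a mild age slope. The sub-model is calibration plumbing —
the source makes no distributional claim about continuous CAC — so only the
zero-fraction and the quartile odds structure are meaningful.

All randomness derives from one config seed via documented sub-streams
(`default_rng([seed, 0])` genotypes, `[seed, 1]` phenotypes); outputs are
byte-stable per seed.

## What the synthetic data does and does not show

The generator omits linkage disequilibrium, ancestry admixture (groups
differ only by frequency table), genotyping error, and any real CAC
distribution shape. Passing tests therefore demonstrate that the pipeline's
arithmetic, calling, stratification and models are correct and calibrated
under the stated generative assumptions — not that the published real-cohort
effect sizes (e.g. the CAC Q4 OR 1.70 or the CVD OR 2.64) are themselves
recovered, which would require the original cohort. Those appear only as
generative inputs or calibration anchors, never as claimed reproductions.

## Numerical and testing choices

- Scores are full-precision internally, 2 dp in output tables.
- Quantile cuts: `numpy.quantile(..., method="linear")`; exact ties go low.
- Coverage-style acceptance tests use replicate counts (1000–1500) chosen so
  the Monte-Carlo error of the empirical coverage (~0.6–0.7%) is small
  against the 95% ± 2% acceptance band, with fixed seeds; the logistic null
  uses n = 2000 at a ~20% event rate, where the Wald interval's true
  coverage (~94.5%) reflects the method rather than small-sample artifacts.
- Problem sizes: moment-recovery checks use 50,000 subjects per group;
  calibration and recovery checks use the study's n = 1605 across 100–200
  seeds; null-coverage checks use smaller cohorts (n = 500) where coverage
  is size-invariant.

## Known limitations

- rsID-only matching cannot detect assay strand errors the allele check
  happens to pass (complementary-ambiguous contexts).
- The 1.43 correction is a single constant; intensity-specific corrections
  are out of scope.
- `expected_score` with printed (unnormalized) diplotype vectors understates
  the FH groups' generative mean by ~0.05–0.08 units relative to the
  renormalized sampler; tests account for the difference explicitly.
- The published SDs reflect real-cohort LD and are intentionally not
  reproduction targets of the HWE variance oracle.
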