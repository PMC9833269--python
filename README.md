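# fhprs

A tested pipeline for the 12-SNP and 6-SNP LDL-cholesterol polygenic risk
scores in familial-hypercholesterolemia (FH) cohort studies: genotype input,
APOE ε-diplotype calling, score computation with analytic oracles, LDL-C
treatment correction, coronary-artery-calcium (CAC) risk stratification, the
standard association analyses, and a synthetic cohort generator that emulates
the three study groups (population controls, FH mutation-negative, FH
mutation-positive) so every stage is testable without access to patient data.

## Who this is for

Lipid-genetics groups asking whether clinically diagnosed FH without an
identified causative variant (FH/M−) is partly *polygenic*
hypercholesterolemia: subjects whose common-variant burden alone pushes LDL-C
over the diagnostic threshold. The standard instrument is a weighted
LDL-raising allele count over 12 SNPs (with a 6-SNP reduction), compared
across control / FH/M− / FH/M+ groups and related to LDL-C, treatment
response and preclinical atherosclerosis.

## The score

For subject *i* with risk-allele dosages `g_ij ∈ {0,1,2}` at the ten directly
weighted SNPs:

    PRS_i = Σ_j  w_j · g_ij  +  w_APOE(D_i)

where `w_j` are fixed published per-allele weights (score units on an mg/dL
scale) and `w_APOE(D_i)` is a haplotypic weight for the subject's APOE
ε-diplotype `D_i ∈ {ε2ε2 … ε4ε4}`, called from rs429358/rs7412
(ε2 = T–T, ε3 = T–C, ε4 = C–C). The 6-SNP score restricts the sum to
rs629301, rs1367117, rs4299376, rs6511720 plus the APOE term. With group
risk-allele frequencies `f_j` the analytic expectation is
`Σ_j w_j·2f_j + Σ_D π_D·w_D`, and under Hardy–Weinberg and linkage
equilibrium the variance is `Σ_j w_j²·2f_j(1−f_j) + Var_π(w_D)`; both are
implemented as oracles against which the simulator and scorer are tested.

## Worked example

```bash
fhprs simulate --group control -n 1605 --seed 107 --out results/cohorts/control
fhprs score --vcf results/cohorts/control/genotypes.vcf --out results/scores.tsv
fhprs analyze --scores results/scores.tsv \
              --pheno results/cohorts/control/phenotypes.tsv \
              --out results/analysis
```

The analyze step prints (this exact run):

```
fhprs analysis report (1605 subjects, groups: CONTROL)
  CONTROL prs12: mean 33.03 (SD 8.73, n 1605)
  CONTROL prs6: mean 22.95 (SD 8.61, n 1605)
  CONTROL: LDL-C ~ prs12 adjusted R^2 = 0.067 (slope 1.23 mg/dL per unit, p = 3.32e-26)
  CONTROL: LDL-C across prs12 tertiles Kruskal-Wallis p = 2.5e-19
  CONTROL: CAC>=100 Q4 vs Q1 OR 2.32 (95% CI 1.35-4.00, p = 0.00239; n = 1605)
```

Read: the cohort's mean 12-SNP score (33.03) sits at its analytic expectation
(33.11) for the control frequency table; the score explains ~4–7% of
treatment-corrected LDL-C variance (slope ≈ 1 mg/dL per score unit, the
generative value); median LDL-C rises across score tertiles; and subjects in
the top score quartile have elevated age/sex-adjusted odds of a CAC score
≥ 100. Numbers vary by seed within the calibrated ranges checked in
`tests/test_acceptance.py`.

The numbered drivers under `analysis/` run the full study workflow
(01 simulate the three groups → 02 score and compare groups → 03 LDL-C
associations and ascertainment contrast → 04 CAC and event analyses),
writing tables under `results/`.

## Layout

- `src/fhprs/` — the library: `panel`, `genotype_io`, `scoring`, `phenotype`,
  `association`, `synthetic_cohort`, `cli`
- `src/fhprs/data/ldl_prs_panel.tsv` — the packaged score definition
  (weights, risk alleles, per-group frequencies, APOE diplotype table)
- `analysis/` — numbered narrative drivers
- `docs/methods.md` — model, parameters, calibration and limitations
- `tests/` — unit, property and acceptance suites
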