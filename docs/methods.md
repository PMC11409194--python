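# Methods

`pqtl-screen` implements a multi-stage screen that links protein
quantitative trait loci (pQTL-SNPs) to lung-adenocarcinoma (LUAD) risk
in a case-control setting. This note records the statistical model of
each stage, the synthetic-cohort generator that stands in for the
restricted source data, the numerical choices, and what the tests do and
do not establish.

## Screening pipeline

### 1. Differential expression and intersection (`diffexpr`)

Protein abundances are analysed on the log2 scale. The optional
normalization is per-sample median centering (after log2 transform for
raw input); the screen itself is:

- **plasma** (unpaired): pooled-variance Student's t per protein,
  case vs control, two-sided p from t with n1+n2-2 df;
- **tissue** (paired): paired t on tumor − adjacent differences.

A protein is retained when p < α (default 0.05) in **both** compartments
with the **same** direction, and labelled *suppressor* (down in both) or
*oncogenic* (up in both). Direction agreement is enforced at
intersection time. No multiple-testing correction is applied at this
stage — it is a deliberate screening choice, mirrored by the raw p < 0.05
convention of the downstream association stage; a Bonferroni column is
emitted there for transparency. Proteins with zero pooled variance and
equal means are assigned p = 1 (with a logged warning) so that degenerate
null fixtures run cleanly; zero variance with unequal means yields p = 0.

### 2. Candidate pQTL-SNP selection (`pqtl_select`)

pQTL catalogs (TSV; SNP, target protein, coordinates, effect allele, β,
p, source) are merged restricted to the retained proteins. Duplicate
(SNP, protein) entries keep the smallest p-value and join source labels;
effect alleles are harmonized per SNP against the first record seen — a
swapped effect/other pair flips the β sign, irreconcilable alleles drop
the record with a log entry. Filters, in order:

- **cis**: SNP on the target gene's chromosome within ±1 Mb of the TSS
  (closed interval). 1 Mb is the convention of the large plasma-pQTL
  catalogs this stage is designed to consume.
- **MAF**: panel minor allele frequency strictly > 0.05, computed as
  min(f, 1−f) with f the effect-allele dosage frequency over non-missing
  calls in a user-supplied reference panel (a stand-in for 1000 Genomes
  CHB; nothing is downloaded).
- **LD pruning**: greedy, best-p-first (ties broken by chromosome,
  position, snp_id). A record is accepted iff its r² with every
  already-accepted same-chromosome SNP is < 0.80. LD is the squared
  Pearson correlation of dosages (composite LD) — phase-free and
  deterministic, rather than EM haplotype r².

### 3. Case-control association (`association`)

Per SNP, five genetic models: het vs ref and hom vs ref (one codominant
fit with two genotype dummies), dominant 1[g≥1], recessive 1[g=2], and
additive g ∈ {0,1,2}. The reference genotype is the major-allele
homozygote; the effect allele is the minor allele.

Crude ORs use the contingency-table cross-product (a·d)/(b·c) with
95% Wald CI exp(ln OR ± 1.96·SE), SE = √(1/a+1/b+1/c+1/d), and a
Haldane–Anscombe +0.5 on all four cells when any cell is empty (flagged).
Adjusted analyses fit logistic regression by IRLS: convergence at
gradient max-norm < 1e−8 within 100 iterations; SEs from the inverse
observed information; separation declared when any coefficient passes 15
in absolute value (an explicit error — per-SNP failures are logged and
the scan continues). For a saturated 2×2 design the logistic coefficient
equals the log crude OR, an identity the tests assert to 10 significant
digits, with statsmodels as an independent oracle for general designs.

Significance is bound to the **additive** model (flag = additive p < α).
OR direction for the concordance stage is the sign of the additive
ln OR.

### 4. Regulation-pattern concordance (`concordance`)

For each significant SNP with a catalog record and a role label, the
verdict is a pure function of three signs: with s = −1 for a suppressor
and +1 for an oncogenic protein, the pattern is *plausible* iff
sign(ln OR) = s·sign(β), i.e.

| role       | β | OR  | verdict              |
|------------|---|-----|----------------------|
| suppressor | − | > 1 | plausible_risk       |
| suppressor | + | < 1 | plausible_protective |
| oncogenic  | + | > 1 | plausible_risk       |
| oncogenic  | − | < 1 | plausible_protective |
| otherwise  |   |     | discordant           |

β = 0 or OR = 1 exactly is an undefined direction: the SNP is reported
unevaluable, never silently dropped. If merged sources disagree on the
β sign the SNP is likewise unevaluable. Roles come from the expression
screen, not from external knowledge bases.

### 5. Biomarker evaluation (`biomarker`)

Validation-phase group comparisons reuse the pooled t. AUC is the
Mann-Whitney rank statistic with midrank ties, U/(n1·n0) — identical (to
1e−12, asserted) to trapezoidal integration of the empirical ROC curve.
`direction="auto"` orients scores so AUC ≥ 0.5 and records the
orientation. The 95% CI is a seeded stratified percentile bootstrap
(2000 replicates), chosen over DeLong for implementation simplicity and
exact reproducibility under a seed. Combined markers are scored by the
linear predictor of an in-sample logistic fit (equal-weight standardized
sum under separation, flagged); combined AUCs are therefore in-sample
and optimistically biased — no cross-validation is attempted.

## Synthetic cohort generator (`simulate`)

The source data are access-controlled (GWAS genotypes) or third-party
(proteomics), so every stage is exercised on synthetic cohorts whose
statistical structure matches what the pipeline assumes:

- **Genotypes**: biallelic loci in HWE at the specified MAF (effect
  allele = minor allele). Within an LD block, haplotype allele
  indicators come from thresholding latent bivariate normals whose
  correlation with the block anchor is calibrated by root-finding on the
  bivariate-normal orthant probability so realized dosage r² matches
  `target_r2` (star topology: every member correlates with the anchor).
  Blocks are independent.
- **Phenotype**: P(case | g, a) = logistic(intercept + Σ log_OR·g +
  age_effect·a) with a binary age group (≤60 / >60, P(>60) = 0.5,
  matching the reporting granularity of the source cohort). Cases and
  controls accrue by rejection sampling from the population model,
  bounded at 100× the requested cohort size (explicit failure beyond
  that). Odds ratios are invariant to this outcome-dependent sampling.
- **Proteomics**: log2 abundance = per-protein baseline (N(20, 2²)) +
  role shift·1[case or tumor] + Σ β·dosage + N(0, noise_sd). The tissue
  matrix uses fresh paired subjects (tumor/adjacent sharing a N(0, 0.5²)
  subject effect), since tissue donors are a separate series from the
  GWAS cohort.

Defaults are desk-scale: 500 cases / 500 controls, 65 tissue pairs,
50 loci (20 pQTL loci with planted concordant and discordant effects,
10 LD partners at r² = 0.9, 20 null fillers), 200 proteins (12
suppressor and 8 oncogenic at ±1 log2 units, 180 null), noise_sd = 1,
reference panel of 200. Everything is deterministic under `seed`
(byte-identical output files).

What the generator does **not** emulate: LC-MS/MS missingness and batch
effects, population stratification, genotyping error and imputation
uncertainty, X-chromosome inheritance, trans-pQTL architecture, and
realistic genome-wide LD (only block-wise star-structured LD). Passing
tests therefore demonstrate correctness of the statistical machinery
under the stated model, not robustness to real-data artefacts.

## Calibration and planted-effect scales used by the tests

- Type-I error of the additive significance flag: 1000 null replicates
  at 500/500, acceptance band 0.05 ± 3·√(0.05·0.95/1000).
- Planted per-allele OR 1.5 recovered within 3 SE at 20,000 per arm;
  planted β = −0.5 recovered within ±0.05 at n = 5000.
- End-to-end recovery plants |log OR| = ln 1.8 at MAF 0.30 with 500/500:
  closed-form Wald power ≈ 0.999 per SNP, so all three concordant SNPs
  are expected in ≈ 99.7% of seeds; the test requires 19/20 seeds. The
  protein shifts (±1 at σ = 1) give essentially unit power for role
  labelling at 500/500 plasma samples and 65 tissue pairs.

## Bundled seven-SNP fixture (`datasets`)

Published genotype counts for the seven significant pQTL-SNPs from the
FLCCA GWAS, plus each SNP's catalogued protein-effect sign and the
suppressor role labels, ship in-source so the association and
concordance stages run offline. OR directions are recomputed from the
counts by an unadjusted additive logistic fit at run time. Because
individual ages are not distributed, the fixture cannot reproduce the
age-adjusted significance screen; the seven SNPs are treated as the
pre-screened significant set, and crude cross-product ORs are compared
with the published values only for contrasts where age adjustment does
not shift the second decimal.

## Known limitations

- Crude (unadjusted) ORs stand in for age-adjusted ones wherever
  individual covariates are unavailable.
- Greedy LD pruning is order-dependent by design (best-p-first); it does
  not minimize the number of tags.
- The intersection stage's raw p < 0.05 screen inflates the family-wise
  error rate by construction; it reproduces a screening convention, not
  a recommended inferential procedure.
- Combined-marker AUCs are in-sample; expect shrinkage out of sample.
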