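# pqtl-screen

Multi-stage screening of protein quantitative trait loci (pQTL-SNPs) for
lung-adenocarcinoma (LUAD) risk, built for epidemiologists and
statistical geneticists who want the full screen — from proteomics to
candidate variants — as a tested, reproducible pipeline rather than a
one-off analysis script.

The screen links three layers of evidence:

1. **Differential proteins.** Proteins consistently differentially
   expressed in *both* plasma (case vs control, pooled-variance
   Student's t) and tumor tissue (tumor vs adjacent, paired t), with
   matching direction, are retained and role-labelled: *suppressor*
   (down in both) or *oncogenic* (up in both).
2. **Candidate variants.** pQTL catalogs restricted to those proteins
   are merged and filtered: cis (±1 Mb of the target gene's TSS), minor
   allele frequency > 0.05 in a reference panel, and greedy LD pruning
   at r² < 0.80 (composite LD on dosages).
3. **Association and concordance.** Each candidate SNP is tested under
   codominant, dominant, recessive and additive genetic models — crude
   cross-product odds ratios with 95% Wald CIs, and covariate-adjusted
   logistic regression fitted by IRLS. Significant SNPs (additive
   p < 0.05) pass through the regulation-pattern rule: with s = −1 for a
   suppressor and +1 for an oncogenic protein, a SNP is *biologically
   plausible* iff

   sign(ln OR) = s · sign(β),

   where β is the variant's per-allele effect on its target protein and
   OR its additive-model disease odds ratio. Lowering a tumor suppressor
   should raise risk; raising it should lower risk — everything else is
   discordant.

Validation-phase utilities (group comparison, Mann-Whitney AUC with
stratified bootstrap CIs, combined logistic marker scores) evaluate the
resulting proteins as plasma biomarkers.

Because the underlying GWAS genotypes are access-controlled, the package
includes a synthetic-cohort generator (`pqtl_screen.simulate`) producing
genotypes in Hardy-Weinberg equilibrium with calibrated block-wise LD,
logistic disease status with an age covariate, and two-compartment
proteomics with planted shifts and per-allele pQTL effects — everything
the pipeline consumes, deterministic under a seed. See
`docs/methods.md` for models, assumptions and limitations.

## Worked example

The bundled fixture carries the published genotype counts of seven
pQTL-SNPs from the FLCCA GWAS (3453 never-smoking female LUAD cases,
3710 controls), each SNP's catalogued protein-effect sign, and the
suppressor role labels of the six target proteins:

```python
from pqtl_screen import datasets

plausible, table = datasets.evaluate_flcca()
print(table[["snp_id", "protein_id", "role", "beta_sign",
             "or_direction", "verdict"]].to_string(index=False))
```

```
    snp_id protein_id       role beta_sign or_direction              verdict
 rs2646260     COL6A3 suppressor         -   protective           discordant
 rs7683000       BST1 suppressor         -         risk       plausible_risk
rs73224660       BST1 suppressor         -         risk       plausible_risk
 rs7674623     ANTXR2 suppressor         +         risk           discordant
 rs7671511    SPARCL1 suppressor         +         risk           discordant
 rs2776937       NRP1 suppressor         -         risk       plausible_risk
rs62069916       APOH suppressor         +   protective plausible_protective
```

Four SNPs satisfy the plausibility rule (`rs7683000`, `rs73224660`,
`rs2776937`, `rs62069916`): three where the variant lowers a suppressor
protein and raises risk, one (`rs62069916`) where it raises APOH and
lowers risk. The odds-ratio directions are recomputed from the counts by
an unadjusted additive logistic fit, not copied from any table. A single
crude contrast, for comparison with the published genotype-level
estimates:

```python
from pqtl_screen import association
t = {x.snp_id: x for x in datasets.flcca_tables()}["rs2646260"]
r = association.crude_or(t, "hom_vs_ref")
print(f"OR={r.or_estimate:.2f} (95% CI {r.ci_low:.2f}-{r.ci_high:.2f})")
# OR=0.82 (95% CI 0.69-0.97)
```

## Command line

```sh
pqtl-screen simulate --out cohort/ --seed 42        # synthetic cohort
pqtl-screen run-all --cohort-dir cohort/ --out run/ --seed 42
```

`run-all` executes every stage in order and writes per-stage TSVs plus a
machine-readable `summary.json` manifest (per-stage record counts, final
candidate list). Individual stages are exposed as `diffexpr`,
`select-snps`, `associate`, `concord` and `roc`; input formats are VCF
4.2 (GT field) for genotypes and documented TSV dialects for matrices,
covariates, catalogs and annotation (columns listed in the module
docstrings of `pqtl_screen.io`). Coordinates are 1-based inclusive
throughout.

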