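# osteovar

Family-based rare-variant prioritization and case-control replication for
low bone mineral density (BMD), with synthetic-data generators that carry
known ground truth.

## Scientific background

Severe familial osteoporosis can be driven by rare variants of large
effect that segregate with the phenotype inside a pedigree. A common
two-arm design is:

1. **Discovery** — whole-genome sequence several affected relatives and
   at least one unaffected relative, merge the per-sample variant calls
   into one annotated table, and shrink tens of thousands of variants to
   a handful of candidates with six sequential filters:
   *segregation* (heterozygous in every confirmed affected relative,
   non-carrier in the unaffected control, i.e. a dominant model),
   *consequence* (protein-altering or near-splice only),
   *rarity* (alternative allele frequency ≤ 1% in every population
   database), *deleteriousness* (consensus of in-silico predictors, a
   scaled CADD score > 15, ACMG/AMP class ≥ 4, evolutionary
   conservation), a *frequent-hitter blacklist*, and a
   *bone-biology gene panel*.
2. **Replication** — genotype the shortlisted variants in a large
   case-control collection of postmenopausal women (fracture cases plus
   non-fracture controls stratified by BMD T-score) and test for
   association: genotype/allele frequencies per subgroup, an exact
   Hardy-Weinberg test in the normal-BMD controls, carrier-collapsed
   odds ratios for low BMD and low-trauma fracture with Wald intervals
   and covariate-adjusted logistic models, Mann-Whitney
   genotype-phenotype comparisons, and odds ratios across
   control-anchored tertiles of biochemical phenotypes.

This package implements both arms as a reusable library. The
`osteovar.mofs` module additionally carries the published summary counts
of the Malta Osteoporotic Fracture Study (MOFS) — a 1045-woman
replication collection in which three pedigree-shortlisted missense
variants (*SELP* c.2177T>C, *TGF-β2* c.1136C>T, *ADAMTS20* c.4090A>T)
were genotyped — so the headline replication statistics can be recomputed
from scratch; the individual-level data themselves are not public.

Because raw pedigree and cohort data are unavailable, the package ships
generators (`osteovar.simulate`) that emulate both datasets at realistic
scale with per-variant ground truth: every synthetic background variant
is tagged with the filter stage that should remove it, and every
synthetic cohort carries its exact genotype counts and planted phenotype
effects.

## Worked example

Simulate a study-scale pedigree dataset and run the six-stage
prioritization (`examples/01_prioritize_family.py`):

```python
from osteovar import (
    FilterConfig, PedigreeSimConfig,
    run_prioritization, simulate_pedigree_dataset,
)

config = PedigreeSimConfig(seed=0)   # defaults: 42,854 SNVs + 1,957 indels
table, pedigree, truth = simulate_pedigree_dataset(config)

filter_config = FilterConfig.from_pedigree(
    pedigree, blacklist=config.blacklist, gene_panel=config.gene_panel
)
shortlist, trace = run_prioritization(table, pedigree, filter_config)
```

Printed output of the example script:

```text
simulated 44811 variants across 12 sequenced relatives
affected (heterozygous carriers required): ['III1', 'III4', 'III5']
unaffected (carriers excluded):            ['II10']

stage            SNVs   indels
input            42854    1957
segregation       1902      55
consequence        936      18
rarity              34      18
deleteriousness     33      18
blacklist           32      18
gene_panel           3       0

shortlisted variants:
  1:169564040:T>C  SELP      missense  CADD=23.5  ACMG=4
  1:218610804:C>T  TGFB2     missense  CADD=25.0  ACMG=4
  12:43821128:A>T  ADAMTS20  missense  CADD=24.3  ACMG=4

3/3 planted causal variants recovered, 0 background variants retained.
```

Recompute the MOFS replication statistics from the stored summary counts
(`examples/02_replicate_from_counts.py`):

```text
allele frequencies (whole collection) and HWE in normal-BMD controls
  SELP      AAF=0.011 (n=1045 genotyped)   HWE p=1.00
  TGFB2     AAF=0.002 (n=1045 genotyped)   HWE p=1.00
  ADAMTS20  AAF=0.028 (n=1012 genotyped)   HWE p=1.00

crude odds ratios (carrier vs hom-ref), Wald 95% CI and p
  selp_ls              OR=1.53 (0.46-5.11) p=0.494
  adamts20_ls          OR=0.81 (0.43-1.51) p=0.507
  selp_fn              OR=0.71 (0.23-2.23) p=0.558
  adamts20_fn          OR=1.14 (0.60-2.17) p=0.685
  selp_th              OR=0.75 (0.22-2.51) p=0.641
  adamts20_th          OR=1.13 (0.60-2.11) p=0.714
  selp_fracture        OR=1.21 (0.42-3.47) p=0.720
  adamts20_fracture    OR=1.03 (0.56-1.90) p=0.912
  adamts20_wrist       OR=1.11 (0.48-2.52) p=0.811

ADAMTS20 carriers across control-anchored serum-calcium tertiles
  (reference: highest tertile, 342 hom-ref / 10 het)
  intermediate  OR=3.00 (1.42-6.35) p=0.004
  lowest        OR=2.29 (1.07-4.92) p=0.033
```

A third example (`examples/03_simulate_cohort.py`) simulates a full
1045-woman cohort, runs `association_report`, and writes the rendered
TSV report tables.

## Command-line interface

A thin CLI wraps the library:

```bash
osteovar simulate pedigree --seed 0 --out sim/          # synthetic data + truth.json
osteovar prioritize --table sim/variants.tsv --pedigree sim/pedigree.ped \
    --out-shortlist shortlist.tsv --out-trace trace.tsv
osteovar associate --cohort cohort.csv --out report/
osteovar full-run --seed 0 --out run/                   # end-to-end demo
```

Variant tables are read/written in two dialects: a flat TSV with fixed
annotation columns, and VCF plus an annotation sidecar TSV
(`<file>.annot.tsv`). Pipeline options live in a validated YAML config
with `filter`, `association` and `simulate` sections; unknown keys are
rejected.

## Limitations

- The generators emulate marginal distributions and the planted effects;
  they do not model linkage, genotyping batch effects, relatedness
  beyond the pedigree structure, or covariance between phenotypes.
- Only the dominant segregation model of the original design is
  implemented for filtering.
- Association p-values are Wald-based (plus exact HWE and exact
  small-sample Mann-Whitney); no multiple-testing correction is applied,
  matching the hypothesis-driven replication design.

See `docs/methods.md` for the precise statistical definitions and
generator parameters.
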