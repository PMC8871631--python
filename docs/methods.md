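# Methods

Precise definitions of the filters, statistics and generators implemented
in `osteovar`. All defaults quoted here are package choices; units are
given where applicable.

## 1. Data model

A variant is keyed by `(chrom, pos, ref, alt)` with 1-based positions;
multiallelic VCF sites are decomposed into one biallelic record per
alternative allele. Genotypes are categorical
(`hom_ref`, `het`, `hom_alt`, `missing`); a sample without a call at a
merged site is `missing`, never assumed hom-ref. Annotations carry the
consequence class, splice offset (nt, signed, relative to the intron-exon
junction), per-database alternative allele frequencies (AAF, fraction),
five amino-acid-effect predictor calls (SIFT, Polyphen2, MutationTaster,
MutationAssessor, VEST3: deleterious / benign / unknown), scaled CADD
(phred-like), GERP++ RS (conservation), and an ACMG/AMP class (ordinal
1-5).

## 2. Prioritization filters

Applied strictly in order; each is a pure subset operation, hence
idempotent, and the stage trace is non-increasing.

1. **Segregation** (dominant): retain a variant iff every affected
   relative is heterozygous and no unaffected relative carries the
   alternative allele. A missing call in an affected relative fails the
   filter under the default policy (`fail_segregation`); the alternative
   policy `ignore_sample` drops that sample from the test. A missing
   call in an unaffected relative never excludes.
2. **Consequence**: retain missense, start-loss, stop-gain, stop-loss,
   frameshift and inframe indels, plus splice acceptor/donor variants
   within 10 nt of the junction (`splice_window`, inclusive).
3. **Rarity**: retain iff AAF ≤ 1% (`aaf_threshold`, inclusive) in
   *every* reporting database. A variant absent from all databases is
   treated as rare by default (`missing_aaf_policy = treat_as_rare`).
4. **Deleteriousness** (missense only; other retained classes pass
   through): a strict majority of the informative predictor calls must
   be deleterious (no informative calls fails), CADD > 15 (strict),
   ACMG class ≥ 4, GERP RS ≥ 2.0 (inclusive).
5. **Blacklist**: remove frequent-hitter genes or specific variant keys.
6. **Gene panel**: retain only variants in bone-relevant panel genes.

## 3. Statistics

- **Genotype/allele frequencies.** Missing genotypes are excluded from
  the denominator. AAF = (het + 2·hom_alt) / (2·n genotyped).
- **Exact HWE test.** Conditional on the observed allele counts, the
  null probability of h heterozygotes is
  `n! / (n_AA! h! n_aa!) · 2^h · n_A! n_a! / (2n)!`; the two-sided p
  sums P(h) over all h (same parity as the rare-allele count) with
  P(h) ≤ P(h_obs). Implemented in log space via `gammaln` with a
  relative tolerance of 1e-12 at the boundary; verified against a
  rational-arithmetic oracle in the tests.
- **2×2 odds ratio.** Cells `[[a, b], [c, d]]`, rows = exposure
  (reference row first), columns = outcome (control, case);
  OR = a·d / (b·c), Wald 95% CI `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`,
  Wald p from the normal reference. A zero cell yields NaN unless a
  continuity correction (e.g. Haldane-Anscombe 0.5) is requested, which
  is applied to all cells only when a zero cell is present.
- **Mann-Whitney U.** Mid-rank U of the first group. For pooled
  n ≤ 16 (`exact_limit`) the null distribution is enumerated exactly
  over all group assignments, ties included, and the two-sided p is
  P(|U − n_a·n_b/2| ≥ |U_obs − n_a·n_b/2|); this reduces to the usual
  doubled one-sided exact p for tie-free data. Larger samples use the
  tie-corrected normal approximation without continuity correction.
  Identical pooled values give p = 1.
- **Tertiles.** Cut points are the 1/3 and 2/3 quantiles (linear
  interpolation, numpy default/type 7) of the *reference* distribution
  (normal-BMD controls); values are labelled against these anchored
  boundaries, with boundary ties assigned to the lower interval. Tertile
  odds ratios contrast each tertile against the highest (reference)
  tertile with genotype as the outcome axis.
- **Logistic regression.** Maximum-likelihood fit via statsmodels
  `Logit` (established IRLS/Newton implementation; re-deriving the
  optimizer is not the point of this package), Wald ORs/CIs/p per term.
  Non-convergence or |coef| > 15 flags separation; the affected term's
  OR and CI are reported non-finite. With a lone binary exposure the fit
  equals the closed-form 2×2 arithmetic to ≤ 1e-6 (tested).
- **BMD classification.** Postmenopausal women or age > 50 are graded on
  the worst available T-score (osteoporosis T ≤ −2.5; osteopenia
  −2.5 < T < −1.0; normal otherwise). Younger subjects are graded on
  Z-scores (osteoporosis Z ≤ −2.0 at any site), falling back to the
  T-score cutoffs with T ≤ −2.5 alone downgraded to osteopenia, since a
  low T-score is not diagnostic before age 50.

## 4. Association report

Per variant (default panel: SELP, TGFB2, ADAMTS20), with carrier
collapsing (het + hom_alt as one exposure class) and a minimum of 6
informative carriers for any regression/test (below which the analysis
is rendered "NC" with a note):

- frequencies per subgroup and whole collection; exact HWE in the
  normal-BMD controls;
- crude and adjusted ORs for low BMD at each site (T < −1.0 among
  non-fracture women; adjusted for age), all-type fracture and wrist
  fracture (adjusted for age and LS/FN/TH BMD);
- genotype-phenotype medians and Mann-Whitney p in normal-BMD controls
  for the three site BMDs (g/cm²), serum calcium (mmol/L), alkaline
  phosphatase (U/L) and albumin (g/L);
- ORs across control-anchored tertiles of the biochemical phenotypes,
  adjusted for age and calcium supplement intake.

Display rounding is half-up: ORs and CI bounds to 2 decimal places,
p-values and AAFs to 3.

## 5. Synthetic data generators

All randomness flows from a single `numpy.random.default_rng(seed)`;
identical configs and seeds reproduce outputs byte-for-byte.

**Pedigree generator.** Defaults: a 15-member two-generation pedigree
with 12 sequenced members (3 affected: III1, III4, III5; 1 unaffected
control: II10), 42,851 background SNVs + 3 planted causal missense SNVs
(42,854 total) and 1,957 background indels. Each background variant is
assigned a *first-failing stage* by largest-remainder allocation of
per-stage fractions, then constructed to survive every earlier stage and
fail exactly there; the allocation fractions are chosen so the default
full-scale run reproduces the attrition profile of the real filtering
run exactly (SNVs 42,854 → 1,902 → 936 → 34 → 33 → 32 → 3; indels
1,957 → 55 → 18 → 18 → 18 → 18 → 0). The truth record maps every key to
its tagged stage, which the tests verify stage-by-stage.

**Cohort generator.** Defaults: 1,045 subjects in four subgroups
(normal 229 / osteopenic 266 / osteoporotic 282 / fracture 268);
genotypes drawn per variant from Hardy-Weinberg proportions at AAFs
SELP 0.011, TGFB2 0.002, ADAMTS20 0.028, with an ADAMTS20 missing-call
rate of 33/1045; subgroup-consistent T-scores from truncated normals
(worst LS/FN site respects the subgroup's WHO category); phenotypes from
per-subgroup normals parameterized by median and IQR (σ = IQR/1.349);
planted additive carrier effects (ADAMTS20: −0.09 g/cm² total-hip BMD
and −0.03 mmol/L serum calcium per alternative allele). The planted
total-hip effect is detectable by the Mann-Whitney test in ≥ 80% of
seeds at n = 1000 within a single stratum (tested), while SELP carries
no effect and rejects at the nominal rate.

## 6. What the generators do and do not emulate

They emulate: the scale and attrition profile of the discovery
filtering, marginal genotype frequencies and HWE, subgroup structure,
phenotype location/spread, and monogenic-style carrier effects.
They do not emulate: linkage disequilibrium, sequencing/genotyping
error processes, relatedness beyond the fixed pedigree, covariance
between phenotypes, or age structure beyond truncated-normal subgroup
ages (41-79 years, older in the osteoporotic and fracture subgroups).
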