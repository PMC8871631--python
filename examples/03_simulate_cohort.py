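"""Simulate a replication cohort and run the full association report.

Generates a 1045-woman case-control cohort (fracture cases plus
BMD-stratified controls) with a planted total-hip BMD deficit in
ADAMTS20 carriers, then computes frequencies, HWE, odds ratios,
genotype-phenotype comparisons and calcium tertile analyses, and writes
the rendered report tables to ./cohort_report/.
"""

from osteovar import CohortSimConfig, simulate_cohort
from osteovar.report import association_report, render_report

config = CohortSimConfig(seed=0)  # defaults mirror the real collection layout
subjects, truth = simulate_cohort(config)
sizes = {}
for s in subjects:
    sizes[s.subgroup.value] = sizes.get(s.subgroup.value, 0) + 1
print(f"simulated {len(subjects)} subjects: {sizes}")

tables = association_report(subjects)

print("\nHardy-Weinberg (normal-BMD controls):")
print(tables["hwe"].to_string(index=False))

print("\ngenotype-phenotype comparisons for ADAMTS20 (normal-BMD controls):")
pheno = tables["phenotypes"]
print(pheno[pheno.variant == "ADAMTS20"].to_string(index=False))

written = render_report("cohort_report", tables=tables)
print(f"\nwrote {len(written)} report tables to ./cohort_report/")
print("Interpretation: the planted carrier deficit in total-hip BMD and "
      "serum calcium is detectable in the ADAMTS20 rows; TGFB2 analyses "
      "are skipped because too few carriers are simulated at its allele "
      "frequency, matching how rare variants behave at this cohort size.")
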