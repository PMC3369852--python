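"""Enumerate the admissible dichotomy tests of the STXBP6 microsatellite.

From the published 156-patient genotype distribution, builds every allele
grouping (length thresholds and one-vs-all singletons), applies dominant
and recessive models, deduplicates identical patient partitions within the
threshold kind, and drops tests whose smaller genotype group holds fewer
than 10% of patients.  The count of survivors is N_test, the per-amplicon
Bonferroni multiplier.
"""

from indelassoc import admissible_tests, bonferroni_threshold
from indelassoc.studydata import table3_calls

calls = table3_calls()
tests = admissible_tests(calls)

print(f"{len(calls)} genotyped patients, "
      f"{len({a for g in calls for a in g})} alleles")
print(f"{'test':22s} {'model':10s} {'positive':>9s} {'negative':>9s}")
for t in tests:
    print(f"{t.label:22s} {t.model:10s} {t.positive_count:9d} "
          f"{t.negative_count:9d}")
print(f"\nN_test = {len(tests)}")
print(f"single-test family threshold 0.05/(202*{len(tests)}) = "
      f"{bonferroni_threshold(202, len(tests)):.3e}")
print("\nEach row is one admissible genotype dichotomy; the counts are the")
print("sizes of the two patient groups the Fisher test will compare.")
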