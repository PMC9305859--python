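"""Load the packaged table of clinically relevant variants and reproduce
its printed aggregates.

The package ships the published list of 50 pathogenic / likely
pathogenic / VUS variants (gene, cDNA and protein change, type,
mutated-sample count, exposure arm) as a cohort fragment with
deterministic synthetic sample identities.
"""

from collections import Counter

from panelmut import load_table2_fixture, recurrence_table

cohort = load_table2_fixture()
keys = {v.key for v in cohort.variants}
print(f"distinct variants: {len(keys)}; occurrences: {len(cohort.variants)}")

tp53 = [v for v in cohort.variants if v.gene == "TP53"]
by_class = Counter(v.consequence.value for v in tp53)
print(f"TP53 occurrences: {len(tp53)} -> {dict(by_class)}")
# 17/28 missense vs 9/28 frameshift+nonsense, plus two splice variants

top = recurrence_table(cohort).iloc[0]
print(f"max recurrence: {top['gene']} {top['protein_change']} "
      f"in {top['n_samples']} samples")
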