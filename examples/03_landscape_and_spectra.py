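"""Mutational landscape: gene frequencies, recurrence, spectra,
co-occurrence.

Substitution spectra use the six pyrimidine-collapsed classes; the
exposed arm is generated T>G-enriched and the unexposed arm T>C-enriched,
mirroring a pesticide-associated transversion shift.
"""

from panelmut import (
    Exposure, GeneratorConfig, apply_filters, build_matrix, cooccurrence,
    gene_frequencies, generate, recurrence_table, substitution_spectrum,
)

cohort, fixture, _ = generate(GeneratorConfig(seed=7))
filtered, _ = apply_filters(cohort)
matrix = build_matrix(filtered)

print("gene frequencies among variant-positive samples:")
print(gene_frequencies(matrix).to_string(index=False))

top = recurrence_table(filtered).head(3)
print("\nmost recurrent variants:")
print(top[["gene", "protein_change", "n_samples"]].to_string(index=False))

for arm in Exposure:
    spec = substitution_spectrum(filtered, arm=arm)
    frac = {c: round(n / spec.n_snv, 3) for c, n in spec.class_counts.items()}
    print(f"\n{arm.value} spectrum fractions: {frac}")
    print(f"  Ti/Tv = {spec.ti_count}/{spec.tv_count}")

pair = cooccurrence(matrix).pair("BRCA1", "TP53")
print(f"\nBRCA1-TP53: OR={pair['odds_ratio']:.2f}, p={pair['p']:.4f}, "
      f"{pair['direction']}")
# The generator plants a shared latent indicator for BRCA1/TP53, so the
# pair should usually test co-occurring at alpha = 0.05.
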