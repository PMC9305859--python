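"""Generate a seeded synthetic two-arm cohort and inspect its shape.

The generator emulates a 158-patient panel-sequencing study (91
pesticide-exposed / 67 unexposed, of whom 68 / 52 carry variants) over
BRCA1, BRCA2, PALB2, TP53 and RAD51D.
"""

from panelmut import Exposure, GeneratorConfig, generate

cohort, fixture, truth = generate(GeneratorConfig(seed=7))

print(f"samples enrolled:        {len(cohort.clinical)}")
print(f"  exposed / unexposed:   {len(cohort.arm(Exposure.EXPOSED))} / "
      f"{len(cohort.arm(Exposure.UNEXPOSED))}")
print(f"variant calls emitted:   {len(cohort.variants)}")
print(f"  true somatic calls:    {truth.n_true_variants}")
print(f"  filter-rule decoys:    {sum(truth.decoy_counts.values())}")
print(f"panel target size:       {cohort.panel.target_bp} bp "
      f"({cohort.panel.target_mb} Mb)")

# The decoys are built to fail exactly one enrichment rule each, so the
# filter chain should recover exactly the true calls (see example 02).
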