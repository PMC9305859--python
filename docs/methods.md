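# Methods

## Data model and conventions

A cohort is three tables: somatic variant calls (one row per variant
per sample), clinical metadata (one row per enrolled patient), and the
panel definition. Variants are 1-based inclusive internally (MAF
convention); BED intervals are 0-based half-open, converted at the file
boundary. The panel's target size is the length of the union of its
intervals (overlaps merged), so splitting or reordering intervals never
changes the TMB denominator. Variant identity for annotation lookup is
the transcript-anchored key `GENE:c.change` (uppercased, whitespace
stripped); protein-level matching is deliberately not used because the
fixture tables are transcript-anchored. When a variant table lacks a
VAF column it is derived as alt reads / depth, rounded to 4 decimals.

Disease onset is derived deterministically from age at diagnosis
(early < 50 years, late ≥ 50) and never stored, so the two can never
disagree.

## Enrichment filter

Six rules, one pass, inclusive thresholds (depth 20 and VAF 0.02 both
pass): common-SNP panel membership, population allele frequency > 0.5%,
depth < 20, VAF < 0.02, missing alt support on either strand, and
non-protein-affecting consequence. "Both strands" is read minimally as
≥ 1 alt read per strand (configurable). A variant absent from
population databases passes the frequency rule: that rule exists to
remove known common polymorphisms, not novel variants. The synonymous
exclusion and the pre-classification exclusion of intronic / 5′-flank /
3′-UTR classes have identical effect and are merged into the single
consequence rule. Removed variants are attributed to the *first*
failing rule in the order above, which makes the attrition report
deterministic and exactly conservative (input = pass + Σ removals).
Heterozygosity is not filtered on; calls with VAF outside [0.2, 0.8]
are merely counted in a diagnostic field.

## Pathogenicity classification

Decision order (first match wins), with every consultation recorded in
a trail:

1. ClinVar entry, one side only → that verdict; benign and
   likely-benign lump into benign; a lone VUS stays VUS; when both
   pathogenic and likely-pathogenic appear without benign-side reports
   the stronger label wins.
2. ClinVar entry with both benign-side and pathogenic-side reports →
   predominance count ignoring VUS entries; strict benign majority →
   benign, strict pathogenic majority → likely pathogenic, exact tie →
   VUS. The tie rule is a design choice: the source procedure defines
   only strict predominance, and VUS is the conservative neutral state.
3. Nonsense/frameshift registered in none of ClinVar, COSMIC, IARC →
   pathogenic (truncating default).
4. Novel splice-site variant whose intron-boundary key carries a known
   pathogenic variant → likely pathogenic.
5. COSMIC pathogenic (no ClinVar) → likely pathogenic — deliberately
   *not* pathogenic, so that COSMIC stays subordinate to ClinVar (the
   RAD51D c.137C>G case requires a ClinVar VUS to survive a COSMIC
   pathogenic prediction).
6. TP53 with IARC functional class "non-functional" → likely
   pathogenic. Whether IARC alone may upgrade a ClinVar-absent variant
   is an interpretation; the rule is on by default, visible in the
   trail, and can be switched off (`use_iarc_upgrade=False`).
7. Otherwise unclassified (source `none`).

Invariants: determinism, ClinVar precedence (never overridden by
COSMIC/IARC), permutation-invariant conflict resolution, and a closed
verdict set in which likely-benign is unreachable.

Class-fraction summaries are reported at *both* plausible denominators
(all calls vs distinct variants) because summary percentages of this
kind are ambiguous between the two; the package never guesses.

## Landscape statistics

Substitution spectra use the pyrimidine-reference collapse (maftools
convention): each SNV is represented on the strand whose reference base
is C or T, giving six classes; transitions are C>T and T>C. Records
with ref = alt or non-ACGT alleles are rejected into a diagnostics
counter. Per-sample class fractions are computed only for samples with
≥ 1 SNV rather than imputing zeros.

The two-sided Fisher exact p uses the probability-mass definition (sum
of hypergeometric probabilities of all tables with the observed margins
that are no more probable than the observed table) — the classical
definition used by the standard R implementation. The odds ratio is the
sample estimate ad/bc, reported as infinite/zero at degenerate margins;
the all-zero table returns p = 1 by convention.

Co-occurrence tests every unordered gene pair on the 2×2 table of
carrier indicators; direction is co-occurring iff OR > 1. Raw p-values
drive significance at α = 0.05 (matching figure-style reporting that
uses uncorrected p); a Benjamini–Hochberg column is always emitted for
transparency. The default sample universe is variant-positive samples,
switchable to all enrolled samples (`cooccurrence_all_samples`), and the
choice is recorded in the run manifest — the source analysis does not
state which universe it used, so both are first-class. Genes mutated in
zero or all samples give p = 1 with a degeneracy flag.

## TMB and group comparisons

TMB = non-synonymous calls / target megabases. "Non-synonymous"
includes missense, nonsense, frameshift and splice-site (splice
variants are protein-altering in this panel context); the set is a
parameter. The median is computed over whatever cohort is passed in —
the analysis scope is the caller's choice and is recorded in the
manifest. Samples with TMB equal to the median go to the *low* group;
the rule is arbitrary but deterministic and stated in output metadata.

Rank-sum tests are exact (full enumeration, via the standard
implementation's exact mode) when the combined sample size is ≤ 12 and
the pooled data are tie-free, else the normal approximation with tie
correction — exactness where it is cheap, standard approximation
elsewhere. Constant pooled data give p = 1. Shapiro–Wilk is computed
only to annotate reports; every group contrast is nonparametric
regardless, matching the source scheme.

The association battery: TMB by exposure; within each arm, TMB by
onset, per-gene carrier status, and deleterious-variant (pathogenic or
likely pathogenic) carrier status; and Table-1-style categorical
covariates compared between arms by Fisher's exact test on 2×2 layouts
(multi-level subtype is reduced to binary indicators). Strata with an
empty group are skipped with the reason recorded.

## Synthetic cohort generator

The generator's defaults are the emulated study conditions: 158
enrolled (91 exposed / 67 unexposed), 68 + 52 variant-positive;
per-gene carrier frequencies BRCA2 0.65, PALB2 0.391, BRCA1 0.30, TP53
0.225, RAD51D 0.108 *among variant-positive samples*; arm-specific
six-class weights (exposed T>G-enriched at 0.30, unexposed T>C-enriched
at 0.45); arm-specific verdict mixes whose pooled fractions land near
the reported overall class distribution (~72% benign, ~15% pathogenic,
~4% likely pathogenic, ~5% VUS, ~4% unclassified) while planting a
deleterious-enrichment contrast (P+LP 0.25 exposed vs 0.115 unexposed);
evidence fields drawn around the reported sequencing depth (mean ≈ 520×,
clipped to 102–1068×) with near-heterozygous VAFs (Beta(35, 65)).

Because the configured gene frequencies are conditional on being
variant-positive, the unconditional per-sample hit probabilities are
scaled by the fixed-point factor s = P(≥ 1 hit) and samples are
rejection-sampled to ≥ 1 hit, which makes the conditional marginals
equal the targets exactly in expectation.

Planted structure, all recoverable by the pipeline and checked against
independent oracles in the tests:

- **BRCA1–TP53 dependence** via a shared latent indicator (q = 0.10)
  with base probabilities adjusted to preserve both marginals.
- **Recurrence** via per-gene hotspot template pools (reuse probability
  0.08) plus one planted recurrent PALB2 frameshift carried by exactly
  6 exposed samples, mimicking a coiled-coil-domain hotspot.
- **TMB shift**: exposed early-onset samples gain Poisson(3) extra
  non-synonymous variants, placed in genes the sample already carries
  so carrier marginals are untouched.
- **Filter decoys**: 8 variants per rule constructed to fail exactly
  that rule (and pass all earlier ones), so attrition attribution is
  exactly predictable.
- **Verdict ground truth**: fixture tables are constructed per planted
  verdict (ClinVar direct entries, conflicting lists with the right
  predominance, COSMIC-only pathogenic, IARC non-functional, registered
  splice sites, or absence for the truncating default), so the
  classifier must recover 100% of planted verdicts; any miss is an
  implementation defect, not noise.
- Variant positions are uniform within gene intervals with alleles on a
  random strand, so complement collapse is exercised; clinical
  covariates follow the printed per-arm marginals, ages are
  N(57.66, 14.5²) / N(55.63, 11.7²) clipped to the reported 31–86 range.

What the generator does **not** emulate: read-level data, FFPE
artifacts, clonal structure, linkage between co-mutations within a
sample beyond the one latent indicator, trinucleotide context (so no
mutational-signature fitting), and germline/somatic origin ambiguity.
Passing tests therefore demonstrate correctness of the statistical
machinery under the study's marginal structure, not robustness to those
real-data complications.

The packaged in-print table of 50 clinically relevant variants expands
its printed multiplicities into one record per synthesized sample
(deterministic ids `T2_E###`/`T2_U###`; rows attributed to both arms
contribute one occurrence per arm — the only reading consistent with
the printed counts). The source does not publish which co-mutations
share a sample, so the fixture claims no sample-sharing structure, and
its clinical records are placeholders carrying only the exposure arm.
One printed row (PALB2 c.1240C>T, p.R414\*) is typed "DEL" although the
change is a substitution; the fixture preserves the row verbatim and
derives the consequence (nonsense) from the protein change. The
enrolled-vs-variant-positive totals (158 vs 120) are both carried and
never silently reconciled.

## Problem sizes and numerical choices

The acceptance checks compare the Fisher implementation with full
hypergeometric enumeration over every 2×2 table with total ≤ 40
(135,751 tables) and the rank-sum exact mode with full rank-assignment
enumeration for all tie-free inputs with combined n ≤ 10. The
co-occurrence type-I calibration uses 2,000 replicates of 5 independent
genes at the study marginals over 120 samples; discrete exact tests are
conservative, so the observed rate sits slightly below α. The power
study runs the full pipeline over 40 generator seeds and compares
detection rates with 2,000-replicate direct simulations of the
generative model (a two-proportion model for the deleterious
enrichment, the analytic four-cell latent-indicator model for the
carrier dependence), with a 3-SD tolerance combining both Monte Carlo
errors. Oracle comparisons use absolute tolerance 1e-9; enumeration
ties use a 1 + 1e-12 relative guard, matching the classical handling of
floating-point ties in "≤ observed probability" sums.

## Known limitations

- The classifier is a faithful small rule engine, not a full ACMG
  28-criterion evaluator; fixtures are local tables, never live
  database queries.
- Panel TMB on a 0.0216 Mb target is extremely coarse (one variant ≈ 46
  variants/Mb); values are comparable within the cohort but not
  calibrated to WES-scale TMB.
- HGVS parsing covers the notation patterns that occur in these tables
  (substitutions, deletions, frameshifts, intronic ±1/±2 offsets); it
  is not a general HGVS validator against transcript sequences.
- The study's per-sample TMB vector and median are unpublished, so
  TMB-related findings are recovered on synthetic data as planted
  effects, not reproduced numerically.
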