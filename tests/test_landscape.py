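"""Landscape analytics: matrices, spectra, recurrence, exact tests."""

import itertools
import math

import numpy as np
import pytest

from panelmut import (
    Cohort,
    Consequence,
    Exposure,
    GeneratorConfig,
    VariantRecord,
    VariantType,
    apply_filters,
    build_matrix,
    cooccurrence,
    default_panel,
    fisher_exact_2x2,
    gene_frequencies,
    generate,
    recurrence_table,
    substitution_class,
    substitution_spectrum,
)
from panelmut.landscape import SIX_CLASSES, GeneSampleMatrix
from panelmut.model import ClinicalRecord

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# -- substitution classes ---------------------------------------------------

@pytest.mark.parametrize(
    "ref,alt,expected,is_ti",
    [
        ("A", "G", "T>C", True),   # purine ref collapses to pyrimidine strand
        ("G", "T", "C>A", False),
        ("T", "G", "T>G", False),
        ("C", "T", "C>T", True),
        ("G", "A", "C>T", True),
    ],
)
def test_pyrimidine_collapse(ref, alt, expected, is_ti):
    cls = substitution_class(ref, alt)
    assert cls == expected
    assert (cls in {"C>T", "T>C"}) == is_ti


def test_identical_alleles_rejected():
    with pytest.raises(ValueError):
        substitution_class("A", "A")


def _snv(sample, pos, ref, alt, gene="TP53"):
    return VariantRecord(
        sample_id=sample, gene=gene, chrom="chr17", pos=pos, ref=ref, alt=alt,
        variant_type=VariantType.SNP, consequence=Consequence.MISSENSE,
        cdna_change=f"c.{pos}{ref}>{alt}", protein_change="p.A1S",
        depth=100, alt_fwd=20, alt_rev=15, vaf=0.35,
    )


def _tiny_cohort(variants, n_samples=4):
    clin = {
        f"S{i}": ClinicalRecord(f"S{i}", Exposure.EXPOSED, 60.0)
        for i in range(1, n_samples + 1)
    }
    return Cohort(variants, clin, default_panel())


def test_spectrum_conservation_and_complement_invariance(default_sim):
    cohort, _, _ = default_sim
    filtered, _ = apply_filters(cohort)
    spec = substitution_spectrum(filtered)
    n_snv = sum(
        1 for v in filtered.variants if v.variant_type is VariantType.SNP
    )
    assert sum(spec.class_counts.values()) == n_snv
    assert spec.ti_count + spec.tv_count == n_snv
    # complementing every allele pair leaves all six classes unchanged
    flipped = filtered.with_variants(
        [
            v if v.variant_type is not VariantType.SNP
            else VariantRecord(
                **{**v.__dict__, "ref": _COMP[v.ref], "alt": _COMP[v.alt]}
            )
            for v in filtered.variants
        ]
    )
    assert substitution_spectrum(flipped).class_counts == spec.class_counts


def test_per_sample_fractions_sum_to_one(default_sim):
    cohort, _, _ = default_sim
    filtered, _ = apply_filters(cohort)
    frac = substitution_spectrum(filtered).per_sample_fractions
    assert not frac.empty
    sums = frac[list(SIX_CLASSES)].sum(axis=1)
    assert np.allclose(sums, 1.0)


def test_spectrum_binomial_oracle():
    """5,000 SNVs drawn with known class weights land within 3 binomial
    SDs of those weights."""
    weights = (0.05, 0.05, 0.2, 0.1, 0.35, 0.25)
    rng = np.random.default_rng(5)
    variants = []
    for i in range(5000):
        cls = SIX_CLASSES[rng.choice(6, p=weights)]
        ref, alt = cls[0], cls[2]
        if rng.random() < 0.5:
            ref, alt = _COMP[ref], _COMP[alt]
        variants.append(_snv(f"S{1 + i % 4}", 10001 + i % 1000, ref, alt))
    spec = substitution_spectrum(_tiny_cohort(variants))
    for w, cls in zip(weights, SIX_CLASSES):
        frac = spec.class_counts[cls] / 5000
        assert abs(frac - w) <= 3 * math.sqrt(w * (1 - w) / 5000)


def test_arm_restricted_spectrum(default_sim):
    cohort, _, _ = default_sim
    filtered, _ = apply_filters(cohort)
    total = substitution_spectrum(filtered).n_snv
    by_arm = sum(
        substitution_spectrum(filtered, arm=a).n_snv for a in Exposure
    )
    assert by_arm == total


# -- matrix and frequencies -------------------------------------------------

def test_matrix_recount_oracle(default_sim):
    cohort, _, _ = default_sim
    filtered, _ = apply_filters(cohort)
    matrix = build_matrix(filtered)
    for gene in matrix.genes:
        independent = {v.sample_id for v in filtered.variants if v.gene == gene}
        assert matrix.mutated_samples(gene) == independent
    # ordering: descending mutated-sample counts, ties alphabetical
    counts = [len(matrix.mutated_samples(g)) for g in matrix.genes]
    assert counts == sorted(counts, reverse=True)


def test_matrix_variant_negative_padding(default_sim):
    cohort, _, _ = default_sim
    filtered, _ = apply_filters(cohort)
    padded = build_matrix(filtered, include_variant_negative=True)
    assert len(padded.samples) == 158
    assert len(build_matrix(filtered).samples) == len(
        filtered.variant_positive_samples
    )


def test_empty_cohort_matrix():
    matrix = build_matrix(_tiny_cohort([]))
    assert matrix.samples == []
    assert all(not matrix.mutated_samples(g) for g in matrix.genes)


def test_gene_frequency_worked_values():
    """78/120 -> 65.0%; 27/158 -> 17% at integer precision."""
    samples = [f"S{i}" for i in range(120)]
    cells = {("BRCA2", s): {Consequence.MISSENSE} for s in samples[:78]}
    cells.update({("TP53", s): {Consequence.MISSENSE} for s in samples[:27]})
    m = GeneSampleMatrix(genes=["BRCA2", "TP53"], samples=samples, cells=cells)
    freq = gene_frequencies(m).set_index("gene")
    assert freq.loc["BRCA2", "pct"] == 65.0
    assert freq.loc["TP53", "pct"] == 22.5
    freq_all = gene_frequencies(m, denominator="all_samples", total_samples=158)
    assert freq_all.set_index("gene").loc["TP53", "pct_int"] == 17


def test_gene_frequency_scale_free():
    samples = [f"S{i}" for i in range(10)]
    cells = {("BRCA1", s): {Consequence.MISSENSE} for s in samples[:4]}
    m = GeneSampleMatrix(["BRCA1"], samples, cells)
    base = gene_frequencies(m).loc[0, "pct"]
    doubled_samples = samples + [f"D{i}" for i in range(10)]
    doubled_cells = dict(cells)
    doubled_cells.update(
        {("BRCA1", f"D{i}"): {Consequence.MISSENSE} for i in range(4)}
    )
    m2 = GeneSampleMatrix(["BRCA1"], doubled_samples, doubled_cells)
    assert gene_frequencies(m2).loc[0, "pct"] == base


def test_gene_frequency_empty_denominator():
    m = GeneSampleMatrix(["BRCA1"], [], {})
    with pytest.raises(ZeroDivisionError):
        gene_frequencies(m)


# -- recurrence -------------------------------------------------------------

def test_table2_max_recurrence(table2_cohort):
    table = recurrence_table(table2_cohort)
    assert table.loc[0, "n_samples"] == 6
    assert table.loc[0, "protein_change"] == "p.M296fs"


def test_singleton_recurrence():
    variants = [_snv(f"S{i}", 10100 + i, "G", "T") for i in range(1, 4)]
    assert recurrence_table(_tiny_cohort(variants))["n_samples"].max() == 1


def test_planted_recurrence_recovered():
    cfg = GeneratorConfig(seed=9, planted_recurrence=4, hotspot_reuse_prob=0.0)
    cohort, _, _ = generate(cfg)
    filtered, _ = apply_filters(cohort)
    table = recurrence_table(filtered)
    assert table.loc[0, "n_samples"] == 4
    assert table.loc[0, "gene"] == "PALB2"


# -- Fisher exact -----------------------------------------------------------

def _fisher_oracle(a, b, c, d):
    """Two-sided p by full hypergeometric enumeration with fixed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)

    def prob(x):
        return (
            math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
        )

    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


@pytest.mark.parametrize(
    "table,expected",
    [
        ([[3, 1], [1, 3]], 34 / 70),
        ([[0, 4], [4, 0]], 2 / 70),
        ([[2, 3], [2, 3]], 1.0),
    ],
)
def test_fisher_small_tables(table, expected):
    odds, p = fisher_exact_2x2(table)
    assert p == pytest.approx(expected, rel=1e-9)


def test_fisher_all_zero_table_convention():
    odds, p = fisher_exact_2x2([[0, 0], [0, 0]])
    assert p == 1.0
    assert math.isnan(odds)


def test_fisher_degenerate_odds():
    odds, p = fisher_exact_2x2([[4, 0], [0, 4]])
    assert math.isinf(odds)
    odds, _ = fisher_exact_2x2([[0, 4], [4, 0]])
    assert odds == 0.0


def test_fisher_matches_enumeration_oracle():
    """Agreement with the full-enumeration oracle over all tables with
    total <= 18 (the acceptance run extends this to 40)."""
    for n in range(0, 19):
        for a, b, c in itertools.product(range(n + 1), repeat=3):
            d = n - a - b - c
            if d < 0:
                continue
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(_fisher_oracle(a, b, c, d), abs=1e-9)


# -- co-occurrence ----------------------------------------------------------

def _two_gene_matrix(set1, set2, samples):
    cells = {("G1", s): {Consequence.MISSENSE} for s in set1}
    cells.update({("G2", s): {Consequence.MISSENSE} for s in set2})
    return GeneSampleMatrix(["G1", "G2"], list(samples), cells)


def test_perfect_overlap_co_occurring():
    samples = [f"S{i}" for i in range(20)]
    hits = samples[:8]
    res = cooccurrence(_two_gene_matrix(hits, hits, samples))
    row = res.pair("G1", "G2")
    assert math.isinf(row["odds_ratio"])
    assert row["direction"] == "co_occurring"
    _, p_min = fisher_exact_2x2([[8, 0], [0, 12]])
    assert row["p"] == pytest.approx(p_min)


def test_disjoint_cover_mutually_exclusive():
    samples = [f"S{i}" for i in range(20)]
    res = cooccurrence(_two_gene_matrix(samples[:10], samples[10:], samples))
    assert res.pair("G1", "G2")["direction"] == "mutually_exclusive"


def test_degenerate_gene_flagged():
    samples = [f"S{i}" for i in range(10)]
    res = cooccurrence(_two_gene_matrix(samples, samples[:4], samples))
    row = res.pair("G1", "G2")
    assert row["degenerate"] and row["p"] == 1.0


def test_cooccurrence_symmetry(default_sim):
    cohort, _, _ = default_sim
    filtered, _ = apply_filters(cohort)
    res = cooccurrence(build_matrix(filtered))
    for _, row in res.table.iterrows():
        assert res.pair(row.gene2, row.gene1)["p"] == row["p"]


def test_cooccurrence_type_one_error_quick():
    """Under independent mutation indicators the raw-p rejection rate
    stays near alpha (400 replicates; the acceptance run uses 2,000)."""
    rng = np.random.default_rng(17)
    n, reps, alpha = 120, 400, 0.05
    samples = [f"S{i}" for i in range(n)]
    rejections = 0
    for _ in range(reps):
        hit1 = rng.random(n) < 0.3
        hit2 = rng.random(n) < 0.25
        m = _two_gene_matrix(
            [s for s, h in zip(samples, hit1) if h],
            [s for s, h in zip(samples, hit2) if h],
            samples,
        )
        if cooccurrence(m).pair("G1", "G2")["p"] < alpha:
            rejections += 1
    rate = rejections / reps
    # Fisher is conservative: never above alpha by 3 SDs
    assert rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / reps)
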