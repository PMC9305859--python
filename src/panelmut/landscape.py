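"""Mutational landscape analytics: gene x sample matrices, per-gene
frequencies, recurrence, six-class substitution spectra with Ti/Tv, and
pairwise co-occurrence / mutual-exclusivity exact tests.

Spectra use the pyrimidine-reference convention: every SNV is represented
on the strand whose reference base is C or T, collapsing complementary
changes (A>G and T>C are the same event) into the six classes C>A, C>G,
C>T, T>A, T>C, T>G.  Transitions are C>T and T>C; the other four classes
are transversions.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import Cohort, Consequence, Exposure, VariantType

SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITIONS = frozenset({"C>T", "T>C"})

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def substitution_class(ref: str, alt: str) -> str:
    """Six-class label after pyrimidine collapse; raises on ref == alt or
    non-ACGT alleles."""
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError(f"ref == alt ({ref})")
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT substitution {ref}>{alt}")
    if ref in "AG":  # purine reference: flip to the complementary strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


# ---------------------------------------------------------------------------
# gene x sample matrix

@dataclass
class GeneSampleMatrix:
    """Oncoplot-style matrix: per (gene, sample) the set of consequence
    classes observed; an empty set is wild-type.  Genes are ordered by
    descending number of mutated samples, ties alphabetical."""

    genes: list[str]
    samples: list[str]
    cells: dict[tuple[str, str], set[Consequence]] = field(default_factory=dict)

    def mutated_samples(self, gene: str) -> set[str]:
        return {s for (g, s), c in self.cells.items() if g == gene and c}

    def indicator(self) -> pd.DataFrame:
        """Boolean genes x samples mutation-status DataFrame."""
        data = np.zeros((len(self.genes), len(self.samples)), dtype=bool)
        sample_ix = {s: j for j, s in enumerate(self.samples)}
        gene_ix = {g: i for i, g in enumerate(self.genes)}
        for (g, s), classes in self.cells.items():
            if classes:
                data[gene_ix[g], sample_ix[s]] = True
        return pd.DataFrame(data, index=self.genes, columns=self.samples)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for g in self.genes:
            row = {"gene": g}
            for s in self.samples:
                classes = self.cells.get((g, s), set())
                row[s] = ";".join(sorted(c.value for c in classes)) if classes else "."
            rows.append(row)
        pd.DataFrame(rows, columns=["gene", *self.samples]).to_csv(
            path, sep="\t", index=False
        )


def build_matrix(cohort: Cohort, include_variant_negative: bool = False) -> GeneSampleMatrix:
    """Gene x sample matrix over variant-positive samples, optionally
    padded with all-empty columns for variant-negative samples."""
    samples = (
        cohort.samples if include_variant_negative else cohort.variant_positive_samples
    )
    cells: dict[tuple[str, str], set[Consequence]] = defaultdict(set)
    for v in cohort.variants:
        cells[(v.gene, v.sample_id)].add(v.consequence)
    counts = {
        g: len({s for (gg, s) in cells if gg == g}) for g in cohort.panel.genes
    }
    genes = sorted(cohort.panel.genes, key=lambda g: (-counts[g], g))
    return GeneSampleMatrix(genes=genes, samples=list(samples), cells=dict(cells))


def gene_frequencies(
    matrix: GeneSampleMatrix,
    denominator: str = "variant_positive",
    total_samples: Optional[int] = None,
) -> pd.DataFrame:
    """Percent of samples mutated per gene, at one-decimal and integer
    precision.  ``denominator`` is 'variant_positive' (the matrix's own
    columns) or 'all_samples' (pass ``total_samples``, e.g. the enrolled
    cohort size)."""
    if denominator == "variant_positive":
        denom = len(matrix.samples)
    elif denominator == "all_samples":
        if total_samples is None:
            raise ValueError("all_samples denominator requires total_samples")
        denom = total_samples
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ZeroDivisionError("gene frequency undefined for empty denominator")
    rows = []
    for g in matrix.genes:
        n = len(matrix.mutated_samples(g))
        pct = n / denom * 100.0
        rows.append(
            {
                "gene": g,
                "n_mutated": n,
                "denominator": denom,
                "pct": round(pct, 1),
                "pct_int": int(round(pct)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# substitution spectrum

@dataclass
class SpectrumSummary:
    class_counts: dict[str, int]
    ti_count: int
    tv_count: int
    #: per sample, fraction of its SNVs in each class (samples with >=1 SNV)
    per_sample_fractions: pd.DataFrame
    n_rejected: int = 0  # records with ref == alt or non-ACGT alleles

    @property
    def n_snv(self) -> int:
        return sum(self.class_counts.values())

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"class": c, "count": self.class_counts[c]} for c in SIX_CLASSES]
        rows.append({"class": "Ti", "count": self.ti_count})
        rows.append({"class": "Tv", "count": self.tv_count})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def substitution_spectrum(
    cohort: Cohort, arm: Optional[Exposure] = None
) -> SpectrumSummary:
    """Six-class spectrum over the cohort's SNVs (DNP/INS/DEL excluded),
    optionally restricted to one exposure arm."""
    counts: Counter = Counter({c: 0 for c in SIX_CLASSES})
    per_sample: dict[str, Counter] = defaultdict(Counter)
    rejected = 0
    for v in cohort.variants:
        if v.variant_type is not VariantType.SNP:
            continue
        if arm is not None and cohort.clinical[v.sample_id].exposure is not arm:
            continue
        try:
            cls = substitution_class(v.ref, v.alt)
        except ValueError:
            rejected += 1
            continue
        counts[cls] += 1
        per_sample[v.sample_id][cls] += 1

    frac_rows = []
    for sid in sorted(per_sample):
        total = sum(per_sample[sid].values())
        row = {"sample_id": sid}
        row.update({c: per_sample[sid][c] / total for c in SIX_CLASSES})
        frac_rows.append(row)
    fractions = pd.DataFrame(frac_rows, columns=["sample_id", *SIX_CLASSES])

    ti = sum(counts[c] for c in SIX_CLASSES if c in TRANSITIONS)
    tv = sum(counts[c] for c in SIX_CLASSES if c not in TRANSITIONS)
    return SpectrumSummary(
        class_counts={c: counts[c] for c in SIX_CLASSES},
        ti_count=ti,
        tv_count=tv,
        per_sample_fractions=fractions,
        n_rejected=rejected,
    )


# ---------------------------------------------------------------------------
# recurrence

def recurrence_table(cohort: Cohort) -> pd.DataFrame:
    """Mutated-sample count per distinct variant, sorted descending
    (ties by variant key)."""
    samples_per_key: dict[str, set[str]] = defaultdict(set)
    meta: dict[str, tuple[str, str, str]] = {}
    for v in cohort.variants:
        samples_per_key[v.key].add(v.sample_id)
        meta.setdefault(v.key, (v.gene, v.cdna_change, v.protein_change))
    rows = [
        {
            "variant_key": key,
            "gene": meta[key][0],
            "cdna_change": meta[key][1],
            "protein_change": meta[key][2],
            "n_samples": len(samples),
        }
        for key, samples in samples_per_key.items()
    ]
    df = pd.DataFrame(
        rows,
        columns=["variant_key", "gene", "cdna_change", "protein_change", "n_samples"],
    )
    return df.sort_values(
        ["n_samples", "variant_key"], ascending=[False, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# exact tests

def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table [[a, b], [c, d]].

    p is the probability-mass two-sided definition (sum over all tables
    with the observed margins whose hypergeometric probability does not
    exceed the observed one).  The odds ratio is the sample estimate
    a*d / (b*c), infinite or zero when a margin product vanishes; the
    all-zero table returns p = 1 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    ad, bc = a * d, b * c
    if bc > 0:
        odds = ad / bc
    elif ad > 0:
        odds = float("inf")
    else:
        odds = float("nan")  # degenerate margins, association undefined
    if a + b + c + d == 0:
        return odds, 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


@dataclass
class CooccurrenceResult:
    """Pairwise gene co-occurrence / mutual-exclusivity table."""

    table: pd.DataFrame  # gene1, gene2, a..d, odds_ratio, p, p_bh, direction, ...
    n_samples: int
    alpha: float

    def pair(self, g1: str, g2: str) -> pd.Series:
        lo, hi = sorted((g1, g2))
        hit = self.table[(self.table.gene1 == lo) & (self.table.gene2 == hi)]
        if hit.empty:
            raise KeyError((g1, g2))
        return hit.iloc[0]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def cooccurrence(matrix: GeneSampleMatrix, alpha: float = 0.05) -> CooccurrenceResult:
    """Exact test of pairwise dependence between gene mutation indicators.

    For each unordered gene pair, the 2x2 table counts samples mutated in
    both / only one / neither gene; direction is co-occurring when the
    odds ratio exceeds 1, mutually exclusive otherwise.  Raw p-values
    drive the ``significant`` flag (no correction, matching figure-style
    reporting); a Benjamini-Hochberg column is emitted for transparency.
    A gene mutated in zero or all samples yields p = 1 with a degeneracy
    flag.
    """
    if len(matrix.genes) < 2:
        raise ValueError("co-occurrence needs at least two genes")
    ind = matrix.indicator()
    n = len(matrix.samples)
    rows = []
    for g1, g2 in combinations(sorted(matrix.genes), 2):
        x, y = ind.loc[g1].to_numpy(), ind.loc[g2].to_numpy()
        a = int(np.sum(x & y))
        b = int(np.sum(x & ~y))
        c = int(np.sum(~x & y))
        d = int(np.sum(~x & ~y))
        degenerate = x.all() or (~x).all() or y.all() or (~y).all()
        if degenerate:
            odds, p = fisher_exact_2x2([[a, b], [c, d]])[0], 1.0
        else:
            odds, p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append(
            {
                "gene1": g1,
                "gene2": g2,
                "a_both": a,
                "b_g1_only": b,
                "c_g2_only": c,
                "d_neither": d,
                "odds_ratio": odds,
                "p": p,
                "direction": "co_occurring" if odds > 1 else "mutually_exclusive",
                "degenerate": degenerate,
            }
        )
    df = pd.DataFrame(rows)
    df["p_bh"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["p"] < alpha
    df = df[
        [
            "gene1", "gene2", "a_both", "b_g1_only", "c_g2_only", "d_neither",
            "odds_ratio", "p", "p_bh", "direction", "significant", "degenerate",
        ]
    ]
    return CooccurrenceResult(table=df, n_samples=n, alpha=alpha)
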