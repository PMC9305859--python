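"""Rule-based somatic variant pathogenicity classification.

The verdict for each variant is determined predominantly from ClinVar-style
clinical interpretations held in local fixture tables, with COSMIC and (for
TP53) IARC functional data as subordinate evidence, and two ACMG-inspired
default rules for unregistered truncating and splice-site variants:

1. ClinVar entry with interpretations on one side only -> that verdict
   (benign and likely-benign are lumped into benign).
2. ClinVar entry with both benign-side and pathogenic-side reports ->
   predominance count (VUS entries ignored); strict majority wins, a tie
   is VUS.
3. Nonsense or frameshift variant registered in none of ClinVar, COSMIC,
   or IARC -> pathogenic (truncating default).
4. Novel splice-site variant at an intron boundary that already carries a
   known pathogenic variant -> likely pathogenic.
5. No ClinVar entry, COSMIC calls it pathogenic -> likely pathogenic.
6. TP53 variant that IARC scores non-functional -> likely pathogenic.
7. Otherwise unclassified.

A ClinVar-derived verdict — including VUS — is never overridden by COSMIC
or IARC.  Every verdict carries an ordered trail of the rules consulted.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import Cohort, Consequence, Exposure, VariantRecord, variant_key


class Verdict(str, enum.Enum):
    BENIGN = "benign"
    VUS = "VUS"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"
    UNCLASSIFIED = "unclassified"


#: verdicts counted as deleterious in downstream group comparisons
DELETERIOUS: frozenset[Verdict] = frozenset(
    {Verdict.PATHOGENIC, Verdict.LIKELY_PATHOGENIC}
)


class Source(str, enum.Enum):
    CLINVAR_DIRECT = "clinvar_direct"
    CLINVAR_CONFLICT = "clinvar_conflict_resolved"
    COSMIC_FALLBACK = "cosmic_fallback"
    IARC_FALLBACK = "iarc_fallback"
    ACMG_TRUNCATING = "acmg_truncating_default"
    SPLICE_INFERENCE = "splice_site_inference"
    NONE = "none"


CLINVAR_LABELS = {"benign", "likely_benign", "VUS", "likely_pathogenic", "pathogenic"}
_BENIGN_SIDE = {"benign", "likely_benign"}
_PATHOGENIC_SIDE = {"pathogenic", "likely_pathogenic"}

TRUNCATING = {Consequence.NONSENSE, Consequence.FRAMESHIFT}

_SPLICE_SITE_RE = re.compile(r"^c\.(\d+(?:_\d+)?[+-]\d+)")


def splice_site_key(cdna_change: str) -> str | None:
    """Intron-boundary key of a splice-region c. string, e.g.
    'c.559+1G>C' -> '559+1'; None for exonic changes."""
    m = _SPLICE_SITE_RE.match(cdna_change.strip())
    return m.group(1) if m else None


@dataclass
class AnnotationFixture:
    """Local ClinVar / COSMIC / IARC-TP53 style lookup tables, keyed by
    the normalized ``gene:c.change`` variant key."""

    clinvar: dict[str, list[str]] = field(default_factory=dict)
    cosmic: dict[str, str] = field(default_factory=dict)  # pathogenic|neutral|unknown
    iarc_tp53: dict[str, str] = field(default_factory=dict)  # functional tiers
    splice_pathogenic_sites: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for key, labels in self.clinvar.items():
            bad = set(labels) - CLINVAR_LABELS
            if bad:
                raise ValueError(f"unknown ClinVar label(s) {bad} for {key}")

    # -- TSV round trip -----------------------------------------------
    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "clinvar.tsv", "w") as fh:
            fh.write("variant_key\tinterpretations\n")
            for key in sorted(self.clinvar):
                fh.write(f"{key}\t{';'.join(self.clinvar[key])}\n")
        for name, table in (("cosmic", self.cosmic), ("iarc_tp53", self.iarc_tp53)):
            with open(d / f"{name}.tsv", "w") as fh:
                fh.write("variant_key\tstatus\n")
                for key in sorted(table):
                    fh.write(f"{key}\t{table[key]}\n")
        with open(d / "splice_sites.tsv", "w") as fh:
            fh.write("gene\tsite_key\n")
            for gene, site in sorted(self.splice_pathogenic_sites):
                fh.write(f"{gene}\t{site}\n")

    @classmethod
    def read(cls, directory: str | Path) -> "AnnotationFixture":
        d = Path(directory)
        clinvar: dict[str, list[str]] = {}
        cv = pd.read_csv(d / "clinvar.tsv", sep="\t", dtype=str, keep_default_na=False)
        for _, row in cv.iterrows():
            labels = [s for s in row["interpretations"].split(";") if s]
            clinvar[row["variant_key"]] = labels
        cosmic = dict(
            pd.read_csv(d / "cosmic.tsv", sep="\t", dtype=str).itertuples(
                index=False, name=None
            )
        )
        iarc = dict(
            pd.read_csv(d / "iarc_tp53.tsv", sep="\t", dtype=str).itertuples(
                index=False, name=None
            )
        )
        sp = pd.read_csv(d / "splice_sites.tsv", sep="\t", dtype=str)
        sites = set(sp.itertuples(index=False, name=None))
        return cls(clinvar, cosmic, iarc, sites)


@dataclass(frozen=True)
class Classification:
    verdict: Verdict
    source: Source
    trail: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.verdict is Verdict.UNCLASSIFIED) != (self.source is Source.NONE):
            raise ValueError("unclassified <-> source none violated")


def resolve_conflicting(interpretations: list[str]) -> Verdict:
    """Predominance count over a conflicting ClinVar interpretation list.

    Benign-side = {benign, likely_benign}; pathogenic-side = {pathogenic,
    likely_pathogenic}; VUS entries are ignored.  A strict benign majority
    gives benign, a strict pathogenic majority gives likely pathogenic,
    and an exact tie gives VUS (the conservative neutral state — the rule
    text requires strict predominance).
    """
    counts = Counter(interpretations)
    n_benign = sum(counts[l] for l in _BENIGN_SIDE)
    n_path = sum(counts[l] for l in _PATHOGENIC_SIDE)
    if n_benign == 0 or n_path == 0:
        raise ValueError(
            "not a conflicting list: both benign-side and pathogenic-side "
            "labels must be present"
        )
    if n_benign > n_path:
        return Verdict.BENIGN
    if n_path > n_benign:
        return Verdict.LIKELY_PATHOGENIC
    return Verdict.VUS


def _clinvar_direct(labels: list[str]) -> Verdict:
    present = set(labels)
    if present & _PATHOGENIC_SIDE:
        return (
            Verdict.PATHOGENIC
            if "pathogenic" in present
            else Verdict.LIKELY_PATHOGENIC
        )
    if present & _BENIGN_SIDE:
        return Verdict.BENIGN
    return Verdict.VUS


def classify_variant(
    v: VariantRecord,
    fixture: AnnotationFixture,
    use_iarc_upgrade: bool = True,
) -> Classification:
    """Classify a single variant; total function, deterministic, and
    records every rule consulted in the trail."""
    key = v.key
    trail: list[str] = []

    labels = fixture.clinvar.get(key)
    trail.append("clinvar_lookup")
    if labels:
        sides = ({l for l in labels} & _BENIGN_SIDE, {l for l in labels} & _PATHOGENIC_SIDE)
        if sides[0] and sides[1]:
            trail.append("clinvar_conflict_resolution")
            return Classification(
                resolve_conflicting(labels), Source.CLINVAR_CONFLICT, tuple(trail)
            )
        trail.append("clinvar_direct")
        return Classification(_clinvar_direct(labels), Source.CLINVAR_DIRECT, tuple(trail))

    in_cosmic = key in fixture.cosmic
    in_iarc = key in fixture.iarc_tp53

    if v.consequence in TRUNCATING:
        trail.append("acmg_truncating_check")
        if not in_cosmic and not in_iarc:
            return Classification(
                Verdict.PATHOGENIC, Source.ACMG_TRUNCATING, tuple(trail)
            )

    if v.consequence is Consequence.SPLICE_SITE:
        trail.append("splice_site_check")
        site = splice_site_key(v.cdna_change)
        if site is not None and (v.gene, site) in fixture.splice_pathogenic_sites:
            return Classification(
                Verdict.LIKELY_PATHOGENIC, Source.SPLICE_INFERENCE, tuple(trail)
            )

    trail.append("cosmic_lookup")
    if fixture.cosmic.get(key) == "pathogenic":
        return Classification(
            Verdict.LIKELY_PATHOGENIC, Source.COSMIC_FALLBACK, tuple(trail)
        )

    if use_iarc_upgrade and v.gene.upper() == "TP53":
        trail.append("iarc_lookup")
        if fixture.iarc_tp53.get(key) == "non_functional":
            return Classification(
                Verdict.LIKELY_PATHOGENIC, Source.IARC_FALLBACK, tuple(trail)
            )

    trail.append("unclassified")
    return Classification(Verdict.UNCLASSIFIED, Source.NONE, tuple(trail))


@dataclass
class CohortClassification:
    """Per-call verdicts plus disjoint, exhaustive summary partitions."""

    records: list[tuple[VariantRecord, Classification]]
    #: verdict counts over every call (one row per variant per sample)
    call_counts: dict[Verdict, int]
    #: verdict counts over distinct variant keys
    distinct_counts: dict[Verdict, int]
    #: per exposure arm, call-level verdict counts
    arm_counts: dict[Exposure, dict[Verdict, int]]

    def fractions(self, denominator: str = "calls") -> dict[Verdict, float]:
        """Verdict fractions; ``denominator`` is 'calls' or 'distinct'
        (the two plausible denominators for class-frequency summaries —
        both are reported rather than guessing)."""
        counts = self.call_counts if denominator == "calls" else self.distinct_counts
        total = sum(counts.values())
        if total == 0:
            return {v: 0.0 for v in Verdict}
        return {v: counts.get(v, 0) / total for v in Verdict}

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for v, cls in sorted(
            self.records, key=lambda rc: (rc[0].sample_id, rc[0].chrom, rc[0].pos)
        ):
            rows.append(
                {
                    "sample_id": v.sample_id,
                    "variant_key": v.key,
                    "verdict": cls.verdict.value,
                    "source": cls.source.value,
                    "trail": ";".join(cls.trail),
                }
            )
        pd.DataFrame(
            rows, columns=["sample_id", "variant_key", "verdict", "source", "trail"]
        ).to_csv(path, sep="\t", index=False)


def classify_cohort(
    cohort: Cohort,
    fixture: AnnotationFixture,
    use_iarc_upgrade: bool = True,
) -> CohortClassification:
    records: list[tuple[VariantRecord, Classification]] = []
    call_counts: Counter = Counter()
    distinct: dict[str, Verdict] = {}
    arm_counts: dict[Exposure, Counter] = {e: Counter() for e in Exposure}
    for v in cohort.variants:
        cls = classify_variant(v, fixture, use_iarc_upgrade=use_iarc_upgrade)
        records.append((v, cls))
        call_counts[cls.verdict] += 1
        distinct[v.key] = cls.verdict  # deterministic per key
        arm_counts[cohort.clinical[v.sample_id].exposure][cls.verdict] += 1
    return CohortClassification(
        records=records,
        call_counts=dict(call_counts),
        distinct_counts=dict(Counter(distinct.values())),
        arm_counts={e: dict(c) for e, c in arm_counts.items()},
    )
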