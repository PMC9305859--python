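"""Shared data model for panel somatic-variant cohorts.

A cohort ties together three tables: per-sample somatic variant calls
(MAF-like), clinical metadata for every enrolled patient, and the targeted
panel definition (BED intervals whose union gives the denominator for
tumor mutational burden).

Coordinate conventions: variants are 1-based inclusive (MAF convention),
panel intervals are 0-based half-open (BED convention); conversion happens
only at file boundaries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional


class VariantType(str, enum.Enum):
    SNP = "SNP"
    DNP = "DNP"
    INS = "INS"
    DEL = "DEL"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    SILENT = "silent"
    INTRONIC = "intronic"
    FLANK5 = "flank5"
    UTR3 = "utr3"
    OTHER = "other"


#: consequences counted as protein-altering (enter TMB and classification)
NONSYNONYMOUS: frozenset[Consequence] = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE_SITE,
    }
)


class Exposure(str, enum.Enum):
    EXPOSED = "exposed"
    UNEXPOSED = "unexposed"


class Onset(str, enum.Enum):
    EARLY = "early"  # diagnosis before 50 years
    LATE = "late"


EARLY_ONSET_CUTOFF = 50.0


def onset_from_age(age_dx: float) -> Onset:
    """Early disease onset is diagnosis before 50 years; 50 itself is late."""
    return Onset.EARLY if age_dx < EARLY_ONSET_CUTOFF else Onset.LATE


@dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic call in one sample.

    ``pos`` is 1-based. ``vaf`` is the variant allele fraction; when the
    input table lacks it, readers derive ``(alt_fwd + alt_rev) / depth``
    rounded to 4 decimals. ``pop_af`` is the maximum population allele
    frequency across the consulted population databases, ``None`` when the
    variant is absent from all of them. ``in_common_panel`` marks variants
    seen in the 1000 Genomes / ExAC common-SNP sets.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: VariantType
    consequence: Consequence
    cdna_change: str
    protein_change: str = ""
    depth: int = 0
    alt_fwd: int = 0
    alt_rev: int = 0
    vaf: float = 0.0
    pop_af: Optional[float] = None
    in_common_panel: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1] for {self.key}")
        if self.alt_fwd + self.alt_rev > self.depth:
            raise ValueError(
                f"strand alt counts {self.alt_fwd}+{self.alt_rev} exceed "
                f"depth {self.depth} for {self.key}"
            )
        if self.pop_af is not None and not 0.0 <= self.pop_af <= 1.0:
            raise ValueError(f"pop_af {self.pop_af} outside [0, 1]")
        if self.variant_type is VariantType.SNP and not (
            len(self.ref) == 1 and len(self.alt) == 1
        ):
            raise ValueError(
                f"SNP with multi-base alleles {self.ref}>{self.alt} at {self.key}"
            )

    @property
    def key(self) -> str:
        """Normalized variant identity: gene + c. change, uppercased."""
        return variant_key(self.gene, self.cdna_change)

    @property
    def alt_count(self) -> int:
        return self.alt_fwd + self.alt_rev


def variant_key(gene: str, cdna_change: str) -> str:
    """Transcript-anchored lookup key used by the annotation fixtures."""
    return f"{gene.strip().upper()}:{cdna_change.strip().upper().replace(' ', '')}"


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    exposure: Exposure
    age_dx: float
    grade_iii: Optional[bool] = None  # tumor grade III vs I/II
    er: Optional[bool] = None  # estrogen receptor positive
    pr: Optional[bool] = None
    her2: Optional[bool] = None
    subtype: Optional[str] = None  # LumA | LumB | HER2 | TNBC
    nodal: Optional[bool] = None
    metastasis: Optional[bool] = None
    chemoresistance: Optional[bool] = None
    relapse: Optional[bool] = None
    deceased: Optional[bool] = None
    premenopause: Optional[bool] = None

    @property
    def onset(self) -> Onset:
        return onset_from_age(self.age_dx)


@dataclass(frozen=True)
class PanelDefinition:
    """Target intervals of the panel; 0-based half-open, overlaps merged.

    ``target_bp`` is the length of the union of intervals and
    ``target_mb`` the same in megabases — the TMB denominator.
    """

    intervals: tuple[tuple[str, int, int, str], ...]

    def __post_init__(self) -> None:
        for chrom, start, end, _gene in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")

    @property
    def target_bp(self) -> int:
        return sum(e - s for _, s, e in merge_intervals(
            [(c, s, e) for c, s, e, _ in self.intervals]
        ))

    @property
    def target_mb(self) -> float:
        return self.target_bp / 1e6

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, _, _, g in self.intervals:
            seen.setdefault(g)
        return tuple(seen)

    def gene_interval(self, gene: str) -> tuple[str, int, int]:
        for c, s, e, g in self.intervals:
            if g == gene:
                return c, s, e
        raise KeyError(gene)


def merge_intervals(
    intervals: list[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Union of 0-based half-open intervals, merged per chromosome."""
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out


@dataclass
class Cohort:
    """Variants + clinical metadata + panel, with referential integrity."""

    variants: list[VariantRecord]
    clinical: dict[str, ClinicalRecord]
    panel: PanelDefinition

    def __post_init__(self) -> None:
        panel_genes = set(self.panel.genes)
        for v in self.variants:
            if v.sample_id not in self.clinical:
                raise ValueError(f"variant sample {v.sample_id!r} not in clinical table")
            if v.gene not in panel_genes:
                raise ValueError(f"variant gene {v.gene!r} not in panel")

    @property
    def samples(self) -> list[str]:
        return sorted(self.clinical)

    @property
    def variant_positive_samples(self) -> list[str]:
        return sorted({v.sample_id for v in self.variants})

    def arm(self, exposure: Exposure) -> list[str]:
        return sorted(
            s for s, c in self.clinical.items() if c.exposure is exposure
        )

    def with_variants(self, variants: list[VariantRecord]) -> "Cohort":
        return Cohort(list(variants), self.clinical, self.panel)

    def subset_samples(self, sample_ids) -> "Cohort":
        keep = set(sample_ids)
        return Cohort(
            [v for v in self.variants if v.sample_id in keep],
            {s: c for s, c in self.clinical.items() if s in keep},
            self.panel,
        )


__all__ = [
    "VariantType",
    "Consequence",
    "NONSYNONYMOUS",
    "Exposure",
    "Onset",
    "onset_from_age",
    "VariantRecord",
    "variant_key",
    "ClinicalRecord",
    "PanelDefinition",
    "merge_intervals",
    "Cohort",
]
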