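"""Enrichment-in-true-positives filter chain for called somatic variants.

Five rules, applied as one pass with each removed variant attributed to
the first rule it fails (fixed order: common-SNP panel, population allele
frequency, read depth, VAF, strand support, consequence class).  The
consequence rule folds the synonymous exclusion together with the
intronic / 5'-flank / 3'-UTR exclusion applied before classification —
one filter, identical effect.

A variant absent from the population databases (``pop_af`` missing) is
treated as somatic-compatible: the frequency rule removes known common
polymorphisms only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .model import Cohort, Consequence, VariantRecord

#: attribution order for the per-rule removal report
RULE_ORDER = (
    "common_panel",
    "pop_af",
    "depth",
    "vaf",
    "strand",
    "consequence",
)

#: diagnostic heterozygosity band (flag only, never filters)
HET_VAF_BAND = (0.2, 0.8)


@dataclass(frozen=True)
class FilterThresholds:
    """Defaults mirror the study conditions: drop common 1000G/ExAC SNPs
    and population variants above 0.5% MAF, require >=20 tumor reads,
    VAF >= 0.02, alt support on both strands, and remove non-coding /
    synonymous classes."""

    max_pop_af: float = 0.005
    min_depth: int = 20
    min_vaf: float = 0.02
    require_both_strands: bool = True
    drop_common_panel: bool = True
    drop_consequences: frozenset[Consequence] = frozenset(
        {
            Consequence.SILENT,
            Consequence.INTRONIC,
            Consequence.FLANK5,
            Consequence.UTR3,
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_pop_af <= 1.0:
            raise ValueError("max_pop_af must be in [0, 1]")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must be in [0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class FilterReport:
    n_input: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in RULE_ORDER}
    )
    n_pass: int = 0
    #: variants kept but outside the heterozygous VAF band (diagnostic only)
    n_outside_het_band: int = 0

    def check_conservation(self) -> bool:
        return self.n_input == self.n_pass + sum(self.removed.values())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_input": self.n_input,
                    "removed": self.removed,
                    "n_pass": self.n_pass,
                    "n_outside_het_band": self.n_outside_het_band,
                },
                indent=2,
            )
            + "\n"
        )

    def to_tsv(self, path: str | Path) -> None:
        lines = ["rule\tcount", f"input\t{self.n_input}"]
        lines += [f"{rule}\t{self.removed[rule]}" for rule in RULE_ORDER]
        lines.append(f"pass\t{self.n_pass}")
        Path(path).write_text("\n".join(lines) + "\n")


def failing_rule(v: VariantRecord, t: FilterThresholds) -> str | None:
    """First rule the variant fails, or None if it passes all of them.
    Thresholds are inclusive: depth 20 and VAF 0.02 both pass."""
    if t.drop_common_panel and v.in_common_panel:
        return "common_panel"
    if v.pop_af is not None and v.pop_af > t.max_pop_af:
        return "pop_af"
    if v.depth < t.min_depth:
        return "depth"
    if v.vaf < t.min_vaf:
        return "vaf"
    if t.require_both_strands and (v.alt_fwd < 1 or v.alt_rev < 1):
        return "strand"
    if v.consequence in t.drop_consequences:
        return "consequence"
    return None


def apply_filters(
    cohort: Cohort, thresholds: FilterThresholds | None = None
) -> tuple[Cohort, FilterReport]:
    """Filter the cohort's variants; clinical and panel pass through."""
    t = thresholds or FilterThresholds()
    report = FilterReport(n_input=len(cohort.variants))
    kept: list[VariantRecord] = []
    lo, hi = HET_VAF_BAND
    for v in cohort.variants:
        rule = failing_rule(v, t)
        if rule is None:
            kept.append(v)
            if not lo <= v.vaf <= hi:
                report.n_outside_het_band += 1
        else:
            report.removed[rule] += 1
    report.n_pass = len(kept)
    return cohort.with_variants(kept), report
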