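"""End-to-end orchestration: filter -> classify -> landscape -> TMB ->
report bundle, with config validation and a deterministic manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .classify import AnnotationFixture, classify_cohort
from .filters import FilterThresholds, apply_filters
from .io import read_cohort
from .landscape import (
    build_matrix,
    cooccurrence,
    gene_frequencies,
    recurrence_table,
    substitution_spectrum,
)
from .model import Cohort, Exposure
from .tmb import clinical_associations, compute_tmb


@dataclass
class RunConfig:
    variants: str
    clinical: str
    panel: str
    fixtures_dir: str
    out_dir: str
    dialect: str = "maf"
    seed: int = 0
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    #: run co-occurrence over variant-positive samples only (the default)
    #: or over every enrolled sample
    cooccurrence_all_samples: bool = False
    use_iarc_upgrade: bool = True

    def validate(self) -> list[str]:
        """Empty list iff run() can start; each problem names its path/key."""
        problems: list[str] = []
        for key in ("variants", "clinical", "panel"):
            path = getattr(self, key)
            if not Path(path).is_file():
                problems.append(f"{key}: file not found: {path}")
        fdir = Path(self.fixtures_dir)
        if not fdir.is_dir():
            problems.append(f"fixtures_dir: directory not found: {fdir}")
        else:
            for name in ("clinvar.tsv", "cosmic.tsv", "iarc_tp53.tsv", "splice_sites.tsv"):
                if not (fdir / name).is_file():
                    problems.append(f"fixtures_dir: missing table {name}")
        for key, lo, hi in (
            ("min_vaf", 0.0, 1.0),
            ("max_pop_af", 0.0, 1.0),
        ):
            val = getattr(self.thresholds, key, None)
            if val is not None and not lo <= val <= hi:
                problems.append(f"thresholds.{key}: {val} outside [{lo}, {hi}]")
        if self.thresholds.min_depth < 0:
            problems.append("thresholds.min_depth: must be >= 0")
        if self.dialect not in {"maf", "tsv"}:
            problems.append(f"dialect: unknown dialect {self.dialect!r}")
        return problems


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write the report bundle; returns the
    bundle directory.  Identical inputs and config give a byte-identical
    bundle."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort(
        config.variants, config.clinical, config.panel, dialect=config.dialect
    )
    fixture = AnnotationFixture.read(config.fixtures_dir)

    filtered, report = apply_filters(cohort, config.thresholds)
    report.to_json(out / "filter_report.json")
    report.to_tsv(out / "filter_report.tsv")

    classification = classify_cohort(
        filtered, fixture, use_iarc_upgrade=config.use_iarc_upgrade
    )
    classification.to_tsv(out / "verdicts.tsv")

    matrix = build_matrix(
        filtered, include_variant_negative=config.cooccurrence_all_samples
    )
    matrix.to_tsv(out / "matrix.tsv")
    gene_frequencies(matrix).to_csv(out / "gene_frequencies.tsv", sep="\t", index=False)
    recurrence_table(filtered).to_csv(out / "recurrence.tsv", sep="\t", index=False)

    substitution_spectrum(filtered).to_tsv(out / "spectrum_all.tsv")
    for arm in Exposure:
        substitution_spectrum(filtered, arm=arm).to_tsv(
            out / f"spectrum_{arm.value}.tsv"
        )

    if len(matrix.genes) >= 2 and matrix.samples:
        cooccurrence(matrix).to_tsv(out / "cooccurrence.tsv")

    profile = compute_tmb(filtered)
    profile.to_tsv(out / "tmb.tsv")
    associations = clinical_associations(profile, filtered, classification)
    associations.to_tsv(out / "comparisons.tsv")

    manifest = _manifest(config, cohort, filtered, out)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _manifest(config: RunConfig, cohort: Cohort, filtered: Cohort, out: Path) -> dict:
    cfg = asdict(config)
    cfg.pop("out_dir")  # bundle location must not break rerun identity
    cfg["thresholds"]["drop_consequences"] = sorted(
        c.value for c in config.thresholds.drop_consequences
    )
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    row_counts = {}
    for path in sorted(out.glob("*.tsv")):
        with open(path) as fh:
            row_counts[path.name] = sum(1 for _ in fh) - 1  # minus header
    return {
        "tool_version": __version__,
        "config": cfg,
        "config_sha256": cfg_hash,
        "n_samples": len(cohort.clinical),
        "n_variants_input": len(cohort.variants),
        "n_variants_pass": len(filtered.variants),
        "median_split_rule": "tmb equal to the median goes to the low group",
        "cooccurrence_scope": (
            "all_samples" if config.cooccurrence_all_samples else "variant_positive"
        ),
        "row_counts": row_counts,
    }
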