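"""Seeded synthetic cohort generator and the packaged in-print fixture.

The generator emulates a two-arm breast-tumor panel-sequencing study:
158 enrolled patients (91 occupationally exposed to pesticides, 67
unexposed), of whom 68 exposed and 52 unexposed carry at least one
somatic variant in the five-gene homologous-recombination / damage-response
panel (BRCA1, BRCA2, PALB2, TP53, RAD51D).  Defaults reproduce the study
conditions: per-gene carrier frequencies (BRCA2 0.65, PALB2 0.391, BRCA1
0.30, TP53 0.225, RAD51D 0.108 of variant-positive samples), arm-specific
six-class substitution weights (T>G-enriched in the exposed arm,
T>C-enriched in the unexposed arm), a deleterious-verdict enrichment in
the exposed arm, a shared latent BRCA1-TP53 co-mutation indicator, a
recurrent PALB2 hotspot, and a TMB boost for exposed early-onset samples.

Every variant carries a planted ground-truth verdict, and the matching
annotation fixture tables are constructed so the rule engine recovers the
planted verdicts exactly.  Filter-rule decoys (variants built to fail
exactly one enrichment rule) exercise the filter chain with a known
pass set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .classify import AnnotationFixture, Verdict
from .filters import RULE_ORDER
from .io import parse_protein_change, write_cohort
from .model import (
    ClinicalRecord,
    Cohort,
    Consequence,
    Exposure,
    PanelDefinition,
    VariantRecord,
    VariantType,
)

GENES = ("BRCA1", "BRCA2", "PALB2", "TP53", "RAD51D")

_AA = "ACDEFGHIKLMNPQRSTVWY"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

TABLE2_SHA256 = "428d8c804ce3a109c1e3998b3c4c85696b785977a527a9e1dad9f0281385083c"


def default_panel() -> PanelDefinition:
    """Synthetic five-gene panel; interval sizes approximate the coding
    footprint of each gene and total 21,600 bp (0.0216 Mb)."""
    return PanelDefinition(
        (
            ("chr17", 0, 5600, "BRCA1"),
            ("chr13", 0, 10200, "BRCA2"),
            ("chr16", 0, 3600, "PALB2"),
            ("chr17", 10000, 11200, "TP53"),
            ("chr17", 20000, 21000, "RAD51D"),
        )
    )


@dataclass
class GeneratorConfig:
    """Study-condition knobs; defaults ARE the emulated study."""

    seed: int = 0
    # variant-positive samples per arm, plus variant-negative padding to
    # the enrolled totals (91 exposed / 67 unexposed = 158)
    n_exposed: int = 68
    n_unexposed: int = 52
    n_padding_exposed: int = 23
    n_padding_unexposed: int = 15
    gene_probs: dict[str, float] = field(
        default_factory=lambda: {
            "BRCA2": 0.65,
            "PALB2": 0.391,
            "BRCA1": 0.30,
            "TP53": 0.225,
            "RAD51D": 0.108,
        }
    )
    #: six-class weights (C>A, C>G, C>T, T>A, T>C, T>G) per arm
    spectrum_weights: dict[Exposure, tuple[float, ...]] = field(
        default_factory=lambda: {
            Exposure.EXPOSED: (0.08, 0.07, 0.20, 0.05, 0.30, 0.30),
            Exposure.UNEXPOSED: (0.08, 0.07, 0.22, 0.05, 0.45, 0.13),
        }
    )
    #: verdict weights (benign, VUS, likely_pathogenic, pathogenic,
    #: unclassified) per arm; exposed arm is deleterious-enriched
    verdict_probs: dict[Exposure, tuple[float, ...]] = field(
        default_factory=lambda: {
            Exposure.EXPOSED: (0.65, 0.055, 0.06, 0.19, 0.045),
            Exposure.UNEXPOSED: (0.805, 0.045, 0.015, 0.10, 0.035),
        }
    )
    #: consequence mix for SNV/indel kinds (missense, frameshift,
    #: nonsense, splice_site)
    consequence_probs: tuple[float, ...] = (0.885, 0.07, 0.035, 0.01)
    #: shared latent indicator probability driving BRCA1-TP53 co-occurrence
    brca1_tp53_latent: float = 0.10
    #: mean extra non-synonymous variants for exposed early-onset samples
    tmb_shift: float = 3.0
    #: probability a drawn variant re-uses one of the gene's hotspot keys
    hotspot_reuse_prob: float = 0.08
    #: exact multiplicity of the planted recurrent PALB2 frameshift
    planted_recurrence: int = 6
    #: decoy variants per filter rule (each fails exactly that rule)
    decoys_per_rule: dict[str, int] = field(
        default_factory=lambda: {rule: 8 for rule in RULE_ORDER}
    )

    def validate(self) -> None:
        for gene, p in self.gene_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"gene probability for {gene} outside [0, 1]")
        for arm, w in self.spectrum_weights.items():
            if len(w) != 6 or abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"{arm.value} spectrum weights must be 6 and sum to 1")
        for arm, w in self.verdict_probs.items():
            if len(w) != 5 or abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"{arm.value} verdict weights must be 5 and sum to 1")
        if min(
            self.n_exposed, self.n_unexposed,
            self.n_padding_exposed, self.n_padding_unexposed,
        ) < 0 or self.n_exposed == 0 or self.n_unexposed == 0:
            raise ValueError("arm sizes must be positive")
        if not 0.0 <= self.brca1_tp53_latent <= min(
            self.gene_probs.get("BRCA1", 1.0), self.gene_probs.get("TP53", 1.0)
        ):
            raise ValueError("latent co-mutation probability exceeds a gene marginal")


@dataclass
class GroundTruth:
    """What the generator planted, for exact downstream recovery tests."""

    planted_verdicts: dict[str, Verdict]  # variant_key -> verdict
    planted_classes: dict[str, str]  # variant_key -> six-class label (SNVs)
    n_true_variants: int  # records that pass the filter chain
    decoy_counts: dict[str, int]  # rule -> decoys planted against it
    latent_q: float
    tmb_boost_samples: list[str]


# ---------------------------------------------------------------------------
# clinical covariate marginals (per arm), matching the printed cohort table

_COVARIATE_P = {
    Exposure.EXPOSED: {
        "age_mean": 57.66, "age_sd": 14.5,
        "grade_iii": 0.353, "er": 0.588, "pr": 0.382, "her2": 0.132,
        "subtype": (0.28, 0.309, 0.131, 0.28),  # LumA, LumB, HER2, TNBC
        "nodal": 0.441, "metastasis": 0.147, "premenopause": 0.28,
        "chemoresistance": 0.323, "relapse": 0.118, "deceased": 0.118,
    },
    Exposure.UNEXPOSED: {
        "age_mean": 55.63, "age_sd": 11.7,
        "grade_iii": 0.231, "er": 0.75, "pr": 0.596, "her2": 0.135,
        "subtype": (0.365, 0.327, 0.135, 0.173),
        "nodal": 0.442, "metastasis": 0.154, "premenopause": 0.308,
        "chemoresistance": 0.27, "relapse": 0.173, "deceased": 0.116,
    },
}

_SUBTYPES = ("LumA", "LumB", "HER2", "TNBC")


def _draw_clinical(rng: np.random.Generator, sid: str, arm: Exposure) -> ClinicalRecord:
    p = _COVARIATE_P[arm]
    age = float(np.clip(rng.normal(p["age_mean"], p["age_sd"]), 31.0, 86.0))
    return ClinicalRecord(
        sample_id=sid,
        exposure=arm,
        age_dx=round(age, 1),
        grade_iii=bool(rng.random() < p["grade_iii"]),
        er=bool(rng.random() < p["er"]),
        pr=bool(rng.random() < p["pr"]),
        her2=bool(rng.random() < p["her2"]),
        subtype=_SUBTYPES[rng.choice(4, p=np.asarray(p["subtype"]) / sum(p["subtype"]))],
        nodal=bool(rng.random() < p["nodal"]),
        metastasis=bool(rng.random() < p["metastasis"]),
        chemoresistance=bool(rng.random() < p["chemoresistance"]),
        relapse=bool(rng.random() < p["relapse"]),
        deceased=bool(rng.random() < p["deceased"]),
        premenopause=bool(rng.random() < p["premenopause"]),
    )


# ---------------------------------------------------------------------------
# variant templates

from .landscape import SIX_CLASSES  # noqa: E402  (six-class order shared)

_CONSEQUENCE_KINDS = (
    Consequence.MISSENSE,
    Consequence.FRAMESHIFT,
    Consequence.NONSENSE,
    Consequence.SPLICE_SITE,
)


@dataclass
class _Template:
    """One distinct variant: identity plus planted truth, shared across
    every sample that carries it."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: VariantType
    consequence: Consequence
    cdna_change: str
    protein_change: str
    verdict: Optional[Verdict]
    six_class: Optional[str]

    @property
    def key(self) -> str:
        from .model import variant_key

        return variant_key(self.gene, self.cdna_change)


class _TemplateFactory:
    def __init__(self, rng: np.random.Generator, panel: PanelDefinition,
                 config: GeneratorConfig) -> None:
        self.rng = rng
        self.panel = panel
        self.config = config
        self.used_cpos: dict[str, set[int]] = {g: set() for g in GENES}

    def _fresh_cpos(self, gene: str) -> int:
        _, start, end = self.panel.gene_interval(gene)
        length = end - start
        for _ in range(1000):
            cpos = int(self.rng.integers(1, length + 1))
            if cpos not in self.used_cpos[gene]:
                self.used_cpos[gene].add(cpos)
                return cpos
        raise RuntimeError(f"gene {gene} interval saturated")

    def _snv_alleles(self, arm: Exposure) -> tuple[str, str, str]:
        """(ref, alt, six-class) with a random strand so complement
        collapse is exercised."""
        w = np.asarray(self.config.spectrum_weights[arm])
        cls = SIX_CLASSES[int(self.rng.choice(6, p=w / w.sum()))]
        ref, alt = cls[0], cls[2]
        if self.rng.random() < 0.5:
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        return ref, alt, cls

    def make(self, gene: str, arm: Exposure, consequence: Consequence,
             verdict: Optional[Verdict]) -> _Template:
        chrom, start, _ = self.panel.gene_interval(gene)
        cpos = self._fresh_cpos(gene)
        pos = start + cpos
        aa = _AA[int(self.rng.integers(len(_AA)))]
        aa_pos = max(1, cpos // 3)
        six_class: Optional[str] = None
        if consequence is Consequence.FRAMESHIFT:
            ref = "ACGT"[int(self.rng.integers(4))]
            alt = "-"
            vtype = VariantType.DEL
            cdna = f"c.{cpos}del{ref}"
            protein = f"p.{aa}{aa_pos}fs"
        elif consequence is Consequence.SPLICE_SITE:
            ref, alt, six_class = self._snv_alleles(arm)
            vtype = VariantType.SNP
            offset = "+1" if self.rng.random() < 0.5 else "+2"
            cdna = f"c.{cpos}{offset}{ref}>{alt}"
            protein = ""
        else:  # missense / nonsense / silent / non-coding decoys: SNV
            ref, alt, six_class = self._snv_alleles(arm)
            vtype = VariantType.SNP
            cdna = f"c.{cpos}{ref}>{alt}"
            if consequence is Consequence.MISSENSE:
                aa2 = _AA[(int(_AA.index(aa)) + 1) % len(_AA)]
                protein = f"p.{aa}{aa_pos}{aa2}"
            elif consequence is Consequence.NONSENSE:
                protein = f"p.{aa}{aa_pos}*"
            elif consequence is Consequence.SILENT:
                protein = f"p.{aa}{aa_pos}{aa}"
            else:
                protein = ""
        return _Template(
            gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
            variant_type=vtype, consequence=consequence, cdna_change=cdna,
            protein_change=protein, verdict=verdict, six_class=six_class,
        )


# ---------------------------------------------------------------------------
# fixture construction from planted verdicts

def _register_verdict(
    rng: np.random.Generator, fixture: AnnotationFixture, t: _Template
) -> None:
    """Add fixture entries so the rule engine recovers t.verdict."""
    key = t.key
    v = t.verdict
    if v is Verdict.BENIGN:
        fixture.clinvar[key] = ["benign"] if rng.random() < 0.7 else ["likely_benign"]
    elif v is Verdict.VUS:
        fixture.clinvar[key] = ["VUS"]
    elif v is Verdict.PATHOGENIC:
        if t.consequence in {Consequence.NONSENSE, Consequence.FRAMESHIFT}:
            # half via the truncating default (absent everywhere), half ClinVar
            if rng.random() < 0.5:
                fixture.clinvar[key] = ["pathogenic"]
        else:
            fixture.clinvar[key] = ["pathogenic"]
    elif v is Verdict.LIKELY_PATHOGENIC:
        if t.consequence is Consequence.SPLICE_SITE:
            from .classify import splice_site_key

            site = splice_site_key(t.cdna_change)
            fixture.splice_pathogenic_sites.add((t.gene, site))
        else:
            route = rng.random()
            if route < 0.4:
                fixture.clinvar[key] = ["pathogenic", "likely_pathogenic", "benign"]
            elif route < 0.8 or t.gene != "TP53":
                fixture.cosmic[key] = "pathogenic"
            else:
                fixture.iarc_tp53[key] = "non_functional"
    # Verdict.UNCLASSIFIED: registered nowhere by construction


def _evidence(rng: np.random.Generator) -> dict:
    """Evidence fields that pass every filter rule."""
    depth = int(np.clip(rng.normal(520, 150), 102, 1068))
    vaf_true = float(rng.beta(35, 65))
    alt = max(2, int(rng.binomial(depth, vaf_true)))
    fwd = int(rng.binomial(alt, 0.5))
    fwd = min(max(fwd, 1), alt - 1)
    return {
        "depth": depth,
        "alt_fwd": fwd,
        "alt_rev": alt - fwd,
        "vaf": round(alt / depth, 4),
        "pop_af": None if rng.random() < 0.85 else float(rng.uniform(0, 0.005)),
        "in_common_panel": False,
    }


def _record(t: _Template, sid: str, ev: dict) -> VariantRecord:
    return VariantRecord(
        sample_id=sid, gene=t.gene, chrom=t.chrom, pos=t.pos, ref=t.ref,
        alt=t.alt, variant_type=t.variant_type, consequence=t.consequence,
        cdna_change=t.cdna_change, protein_change=t.protein_change, **ev,
    )


def generate(
    config: GeneratorConfig | None = None,
) -> tuple[Cohort, AnnotationFixture, GroundTruth]:
    """Deterministic (seeded) synthetic cohort + annotation fixture +
    ground truth."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    panel = default_panel()
    factory = _TemplateFactory(rng, panel, cfg)
    fixture = AnnotationFixture()

    # --- samples ------------------------------------------------------
    clinical: dict[str, ClinicalRecord] = {}
    arm_positive: dict[Exposure, list[str]] = {}
    for arm, n_pos, n_pad, prefix in (
        (Exposure.EXPOSED, cfg.n_exposed, cfg.n_padding_exposed, "E"),
        (Exposure.UNEXPOSED, cfg.n_unexposed, cfg.n_padding_unexposed, "U"),
    ):
        ids = [f"{prefix}{i:03d}" for i in range(1, n_pos + n_pad + 1)]
        for sid in ids:
            clinical[sid] = _draw_clinical(rng, sid, arm)
        arm_positive[arm] = ids[:n_pos]

    # --- gene carrier structure (latent BRCA1-TP53 dependence) --------
    # The configured gene_probs are carrier fractions among
    # variant-positive samples (the printed frequencies are conditional
    # on carrying >=1 variant).  Scale the unconditional hit
    # probabilities by s = P(>=1 hit) so that after rejection sampling
    # to >=1 the conditional marginals equal the targets exactly.
    q = cfg.brca1_tp53_latent
    targets = {g: cfg.gene_probs.get(g, 0.0) for g in GENES}

    def _base_probs(s: float) -> tuple[float, dict[str, float]]:
        qq = s * q
        bases = {}
        for g in GENES:
            pg = s * targets[g]
            if g in ("BRCA1", "TP53") and qq < 1.0:
                bases[g] = max(0.0, (pg - qq) / (1.0 - qq))
            else:
                bases[g] = pg
        return qq, bases

    s = 1.0
    for _ in range(100):
        qq, bases = _base_probs(s)
        p_none = (1.0 - qq) * float(np.prod([1.0 - b for b in bases.values()]))
        s_new = 1.0 - p_none
        if abs(s_new - s) < 1e-12:
            s = s_new
            break
        s = s_new
    qq, bases = _base_probs(s)

    carriers: dict[tuple[str, str], bool] = {}
    for arm, ids in arm_positive.items():
        for sid in ids:
            genes_hit: list[str] = []
            while not genes_hit:  # variant-positive by construction
                latent = rng.random() < qq
                genes_hit = [
                    g for g in GENES
                    if (latent and g in ("BRCA1", "TP53")) or rng.random() < bases[g]
                ]
            for gene in genes_hit:
                carriers[(sid, gene)] = True

    # --- hotspot pools (recurrence) -----------------------------------
    def draw_template(gene: str, arm: Exposure) -> _Template:
        kind = _CONSEQUENCE_KINDS[
            int(rng.choice(4, p=np.asarray(cfg.consequence_probs)))
        ]
        verdict_w = np.asarray(cfg.verdict_probs[arm])
        verdict = (
            Verdict.BENIGN, Verdict.VUS, Verdict.LIKELY_PATHOGENIC,
            Verdict.PATHOGENIC, Verdict.UNCLASSIFIED,
        )[int(rng.choice(5, p=verdict_w / verdict_w.sum()))]
        if verdict is Verdict.UNCLASSIFIED and kind in {
            Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.SPLICE_SITE,
        }:
            kind = Consequence.MISSENSE  # truncating/splice can't stay unregistered
        t = factory.make(gene, arm, kind, verdict)
        _register_verdict(rng, fixture, t)
        return t

    hotspots: dict[str, list[_Template]] = {
        g: [draw_template(g, Exposure.EXPOSED), draw_template(g, Exposure.UNEXPOSED)]
        for g in GENES
    }

    # planted recurrent PALB2 frameshift (mimics a coiled-coil hotspot)
    planted_hotspot = factory.make(
        "PALB2", Exposure.EXPOSED, Consequence.FRAMESHIFT, Verdict.PATHOGENIC
    )
    _register_verdict(rng, fixture, planted_hotspot)

    # --- emit variant records ----------------------------------------
    variants: list[VariantRecord] = []
    truth_verdicts: dict[str, Verdict] = {}
    truth_classes: dict[str, str] = {}

    def emit(t: _Template, sid: str) -> None:
        variants.append(_record(t, sid, _evidence(rng)))
        truth_verdicts[t.key] = t.verdict
        if t.six_class is not None:
            truth_classes[t.key] = t.six_class

    planted_carriers = [
        s for s in arm_positive[Exposure.EXPOSED] if (s, "PALB2") in carriers
    ]
    planted_carriers = planted_carriers[: cfg.planted_recurrence]
    for sid in planted_carriers:
        emit(planted_hotspot, sid)

    for arm, ids in arm_positive.items():
        for sid in ids:
            for gene in GENES:
                if not carriers.get((sid, gene)):
                    continue
                if gene == "PALB2" and sid in planted_carriers:
                    continue  # hotspot already emitted for this carrier
                if rng.random() < cfg.hotspot_reuse_prob:
                    t = hotspots[gene][int(rng.integers(2))]
                else:
                    t = draw_template(gene, arm)
                emit(t, sid)

    # --- TMB boost for exposed early-onset samples --------------------
    # extra variants land in genes the sample already carries, so the
    # per-gene carrier marginals stay at their configured values
    boosted: list[str] = []
    for sid in arm_positive[Exposure.EXPOSED]:
        if clinical[sid].age_dx < 50:
            own_genes = [g for g in GENES if carriers.get((sid, g))]
            extra = int(rng.poisson(cfg.tmb_shift))
            for _ in range(extra):
                gene = own_genes[int(rng.integers(len(own_genes)))]
                emit(draw_template(gene, Exposure.EXPOSED), sid)
            if extra:
                boosted.append(sid)

    n_true = len(variants)

    # --- filter-rule decoys ------------------------------------------
    decoy_counts = dict(cfg.decoys_per_rule)
    all_positive = arm_positive[Exposure.EXPOSED] + arm_positive[Exposure.UNEXPOSED]
    for rule, n in decoy_counts.items():
        for _ in range(n):
            sid = all_positive[int(rng.integers(len(all_positive)))]
            arm = clinical[sid].exposure
            gene = GENES[int(rng.integers(5))]
            if rule == "consequence":
                kind = (
                    Consequence.SILENT, Consequence.INTRONIC,
                    Consequence.FLANK5, Consequence.UTR3,
                )[int(rng.integers(4))]
            else:
                kind = Consequence.MISSENSE
            t = factory.make(gene, arm, kind, None)
            ev = _evidence(rng)
            if rule == "common_panel":
                ev["in_common_panel"] = True
            elif rule == "pop_af":
                ev["pop_af"] = float(rng.uniform(0.01, 0.2))
            elif rule == "depth":
                depth = int(rng.integers(5, 20))
                ev.update(depth=depth, alt_fwd=2, alt_rev=2, vaf=round(4 / depth, 4))
            elif rule == "vaf":
                ev.update(depth=400, alt_fwd=2, alt_rev=1, vaf=round(3 / 400, 4))
            elif rule == "strand":
                ev.update(alt_rev=0, alt_fwd=ev["alt_fwd"] + ev["alt_rev"])
            variants.append(_record(t, sid, ev))

    cohort = Cohort(variants=variants, clinical=clinical, panel=panel)
    truth = GroundTruth(
        planted_verdicts=truth_verdicts,
        planted_classes=truth_classes,
        n_true_variants=n_true,
        decoy_counts=decoy_counts,
        latent_q=q,
        tmb_boost_samples=boosted,
    )
    return cohort, fixture, truth


def generate_files(
    config: GeneratorConfig, out_dir: str | Path
) -> tuple[Cohort, AnnotationFixture, GroundTruth]:
    """Generate and write the MAF-like / clinical / BED / fixture files
    plus a manifest with seed and checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, fixture, truth = generate(config)
    paths = {
        "variants": out / "variants.maf.tsv",
        "clinical": out / "clinical.tsv",
        "panel": out / "panel.bed",
    }
    write_cohort(cohort, paths["variants"], paths["clinical"], paths["panel"])
    fixture.write(out / "fixtures")
    manifest = {
        "seed": config.seed,
        "n_samples": len(cohort.clinical),
        "n_variants": len(cohort.variants),
        "checksums": {
            name: hashlib.sha256(p.read_bytes()).hexdigest()
            for name, p in paths.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return cohort, fixture, truth


# ---------------------------------------------------------------------------
# packaged in-print fixture

def load_table2_fixture() -> Cohort:
    """The packaged table of the study's pathogenic / likely pathogenic /
    VUS variants as a cohort fragment.

    50 distinct variants; each printed multiplicity expands into one
    record per synthesized sample (the source publishes no sample
    identities, so deterministic synthetic ids T2_E###/T2_U### are used
    and no sample-sharing structure is claimed).  Rows attributed to both
    arms contribute one occurrence per arm.  Evidence fields are
    synthetic filter-passing placeholders.  Clinical records are
    placeholders carrying only the exposure arm.
    """
    ref_file = resources.files("panelmut").joinpath("data/table2_variants.tsv")
    raw = ref_file.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE2_SHA256:
        raise RuntimeError(
            f"packaged table2_variants.tsv checksum mismatch: {digest}"
        )
    df = pd.read_csv(ref_file.open("r"), sep="\t", dtype=str)
    panel = default_panel()
    variants: list[VariantRecord] = []
    clinical: dict[str, ClinicalRecord] = {}
    counters = {Exposure.EXPOSED: 0, Exposure.UNEXPOSED: 0}

    def new_sample(arm: Exposure) -> str:
        counters[arm] += 1
        prefix = "T2_E" if arm is Exposure.EXPOSED else "T2_U"
        sid = f"{prefix}{counters[arm]:03d}"
        clinical[sid] = ClinicalRecord(
            sample_id=sid, exposure=arm, age_dx=55.0
        )
        return sid

    import re as _re

    for _, row in df.iterrows():
        gene = row["gene"]
        cdna = row["cdna_change"]
        protein = row["protein_change"]
        vtype = VariantType(row["variant_type"])
        mult = int(row["mutated_samples"])
        arm_label = row["exposure_arm"]
        consequence = parse_protein_change(protein, cdna)

        chrom, start, _ = panel.gene_interval(gene)
        m = _re.match(r"c\.(\d+)", cdna)
        pos = start + int(m.group(1))
        sub = _re.search(r"([ACGT])>([ACGT]+)$", cdna)
        if "del" in cdna:
            deleted = cdna.split("del", 1)[1] or "N"
            ref, alt = deleted, "-"
        elif sub:
            ref, alt = sub.group(1), sub.group(2)
        else:
            ref, alt = "N", "N"
        if vtype is VariantType.SNP and (len(ref) != 1 or len(alt) != 1):
            ref, alt = ref[0], alt[0]

        if arm_label == "Exposed/unexposed":
            arms = [Exposure.EXPOSED, Exposure.UNEXPOSED]
            arms += [Exposure.EXPOSED] * (mult - 2)  # printed counts allow only 2 here
        else:
            arm = Exposure(arm_label.lower())
            arms = [arm] * mult
        for occurrence_arm in arms:
            sid = new_sample(occurrence_arm)
            variants.append(
                VariantRecord(
                    sample_id=sid, gene=gene, chrom=chrom, pos=pos, ref=ref,
                    alt=alt, variant_type=vtype, consequence=consequence,
                    cdna_change=cdna, protein_change=protein,
                    depth=500, alt_fwd=90, alt_rev=85, vaf=0.35,
                    pop_af=None, in_common_panel=False,
                )
            )
    return Cohort(variants=variants, clinical=clinical, panel=panel)
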