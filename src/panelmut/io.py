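"""Readers and writers for the cohort tables.

Three on-disk formats: a MAF-like variant table (GDC column names, tab
delimited, ``#`` comments), a clinical metadata TSV, and a BED panel
definition.  A plain ``tsv`` variant dialect with the internal field names
is also supported and is the round-trip format.  All writers emit a fixed
column order and sort rows by (sample_id, chrom, pos) so identical cohorts
serialize byte-identically.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .model import (
    ClinicalRecord,
    Cohort,
    Consequence,
    Exposure,
    PanelDefinition,
    VariantRecord,
    VariantType,
)


class FormatError(ValueError):
    """A table does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# HGVS-style change parsing

_FS_RE = re.compile(r"fs\*?\d*$")
_MISSENSE_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z])$")
_NONSENSE_RE = re.compile(r"\*$")
_SPLICE_C_RE = re.compile(r"^c\.\d+(?:_\d+)?([+-][12])(?!\d)")


def parse_protein_change(p_string: str, c_string: str) -> Consequence:
    """Infer the consequence class from HGVS p. / c. change strings.

    Precedence: frameshift (``fs`` suffix) > nonsense (terminal ``*``) >
    missense / silent (single amino-acid substitution) > splice site
    (empty p. with a c. offset of +/-1 or +/-2 into the intron).  Anything
    unrecognized — including two empty strings — is ``other``.
    """
    p = (p_string or "").strip()
    c = (c_string or "").strip()
    if p and p.lower() not in {"splice site", "splice_site"}:
        if _FS_RE.search(p):
            return Consequence.FRAMESHIFT
        if _NONSENSE_RE.search(p):
            return Consequence.NONSENSE
        m = _MISSENSE_RE.match(p)
        if m:
            return (
                Consequence.SILENT
                if m.group(1) == m.group(3)
                else Consequence.MISSENSE
            )
        if re.search(r"=$", p):  # p.(=) style synonymous
            return Consequence.SILENT
        return Consequence.OTHER
    if c and _SPLICE_C_RE.match(c):
        return Consequence.SPLICE_SITE
    if not p and not c:
        warnings.warn("variant with empty protein and cDNA change -> other")
    return Consequence.OTHER


# ---------------------------------------------------------------------------
# variant tables

#: internal field name -> GDC MAF column
_MAF_COLUMNS = {
    "sample_id": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "variant_type": "Variant_Type",
    "consequence": "Variant_Classification",
    "cdna_change": "HGVSc",
    "protein_change": "HGVSp_Short",
    "depth": "t_depth",
    "alt_fwd": "t_alt_fwd",
    "alt_rev": "t_alt_rev",
    "vaf": "tumor_vaf",
    "pop_af": "pop_af_max",
    "in_common_panel": "common_panel_flag",
}

_CLASSIFICATION_TO_CONSEQUENCE = {
    "Missense_Mutation": Consequence.MISSENSE,
    "Nonsense_Mutation": Consequence.NONSENSE,
    "Frame_Shift_Del": Consequence.FRAMESHIFT,
    "Frame_Shift_Ins": Consequence.FRAMESHIFT,
    "Splice_Site": Consequence.SPLICE_SITE,
    "Silent": Consequence.SILENT,
    "Intron": Consequence.INTRONIC,
    "5'Flank": Consequence.FLANK5,
    "3'UTR": Consequence.UTR3,
}
_CONSEQUENCE_TO_CLASSIFICATION = {
    Consequence.MISSENSE: "Missense_Mutation",
    Consequence.NONSENSE: "Nonsense_Mutation",
    Consequence.FRAMESHIFT: "Frame_Shift_Del",
    Consequence.SPLICE_SITE: "Splice_Site",
    Consequence.SILENT: "Silent",
    Consequence.INTRONIC: "Intron",
    Consequence.FLANK5: "5'Flank",
    Consequence.UTR3: "3'UTR",
    Consequence.OTHER: "Other",
}

_REQUIRED = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt",
    "variant_type", "cdna_change",
]


def _column_map(dialect: str) -> dict[str, str]:
    if dialect == "maf":
        return _MAF_COLUMNS
    if dialect == "tsv":
        return {k: k for k in _MAF_COLUMNS}
    raise ValueError(f"unknown dialect {dialect!r}")


def read_variants(path: str | Path, dialect: str = "maf") -> list[VariantRecord]:
    """Read a variant table; frameshift Frame_Shift_* suffixes collapse to
    one frameshift class and consequence falls back to the HGVS strings
    when the classification column is absent.
    """
    cols = _column_map(dialect)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [cols[f] for f in _REQUIRED if cols[f] not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        warnings.warn(f"{path}: no data rows")
        return []

    records: list[VariantRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            records.append(_row_to_record(row, cols))
        except (ValueError, KeyError) as exc:
            bad_rows.append((int(idx), str(exc)))
    if bad_rows:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:5])
        raise FormatError(f"{len(bad_rows)} unparseable row(s): {detail}")
    return records


def _get(row: pd.Series, cols: dict[str, str], field: str, default: str = "") -> str:
    col = cols[field]
    return str(row[col]).strip() if col in row.index else default


def _row_to_record(row: pd.Series, cols: dict[str, str]) -> VariantRecord:
    cdna = _get(row, cols, "cdna_change")
    protein = _get(row, cols, "protein_change")
    raw_cons = _get(row, cols, "consequence")
    if raw_cons in _CLASSIFICATION_TO_CONSEQUENCE:
        consequence = _CLASSIFICATION_TO_CONSEQUENCE[raw_cons]
    elif raw_cons in {c.value for c in Consequence}:
        consequence = Consequence(raw_cons)
    else:
        consequence = parse_protein_change(protein, cdna)

    depth = int(_get(row, cols, "depth", "0") or 0)
    alt_fwd = int(_get(row, cols, "alt_fwd", "0") or 0)
    alt_rev = int(_get(row, cols, "alt_rev", "0") or 0)
    vaf_raw = _get(row, cols, "vaf")
    if vaf_raw:
        vaf = float(vaf_raw)
    else:
        vaf = round((alt_fwd + alt_rev) / depth, 4) if depth else 0.0
    pop_raw = _get(row, cols, "pop_af")
    pop_af: Optional[float] = float(pop_raw) if pop_raw not in {"", ".", "NA"} else None
    common_raw = _get(row, cols, "in_common_panel").lower()

    return VariantRecord(
        sample_id=_get(row, cols, "sample_id"),
        gene=_get(row, cols, "gene"),
        chrom=_get(row, cols, "chrom"),
        pos=int(_get(row, cols, "pos")),
        ref=_get(row, cols, "ref"),
        alt=_get(row, cols, "alt"),
        variant_type=VariantType(_get(row, cols, "variant_type")),
        consequence=consequence,
        cdna_change=cdna,
        protein_change=protein,
        depth=depth,
        alt_fwd=alt_fwd,
        alt_rev=alt_rev,
        vaf=vaf,
        pop_af=pop_af,
        in_common_panel=common_raw in {"true", "1", "yes"},
    )


def write_variants(
    variants: Iterable[VariantRecord], path: str | Path, dialect: str = "maf"
) -> None:
    cols = _column_map(dialect)
    rows = []
    for v in sorted(variants, key=lambda v: (v.sample_id, v.chrom, v.pos, v.alt)):
        cons = (
            _CONSEQUENCE_TO_CLASSIFICATION[v.consequence]
            if dialect == "maf"
            else v.consequence.value
        )
        if dialect == "maf" and v.consequence is Consequence.FRAMESHIFT:
            cons = (
                "Frame_Shift_Ins"
                if v.variant_type is VariantType.INS
                else "Frame_Shift_Del"
            )
        rows.append(
            {
                cols["sample_id"]: v.sample_id,
                cols["gene"]: v.gene,
                cols["chrom"]: v.chrom,
                cols["pos"]: v.pos,
                cols["ref"]: v.ref,
                cols["alt"]: v.alt,
                cols["variant_type"]: v.variant_type.value,
                cols["consequence"]: cons,
                cols["cdna_change"]: v.cdna_change,
                cols["protein_change"]: v.protein_change,
                cols["depth"]: v.depth,
                cols["alt_fwd"]: v.alt_fwd,
                cols["alt_rev"]: v.alt_rev,
                cols["vaf"]: f"{v.vaf:.4f}",
                cols["pop_af"]: "" if v.pop_af is None else repr(v.pop_af),
                cols["in_common_panel"]: str(v.in_common_panel).lower(),
            }
        )
    pd.DataFrame(rows, columns=[cols[k] for k in _MAF_COLUMNS]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# clinical table

_CLIN_COLUMNS = [
    "sample_id", "exposure", "age_dx", "grade", "er", "pr", "her2",
    "subtype", "nodal", "metastasis", "chemoresistance", "relapse",
    "deceased", "menopause",
]

_MISSING_TOKENS = {"", "na", "nan", ".", "not informed", "not_informed"}


def _tri_bool(raw: str, true_token: str, false_token: str) -> Optional[bool]:
    low = raw.strip().lower()
    if low in _MISSING_TOKENS:
        return None
    if low == true_token:
        return True
    if low == false_token:
        return False
    raise FormatError(f"unrecognized value {raw!r} (expected {true_token}/{false_token})")


def read_clinical(path: str | Path) -> dict[str, ClinicalRecord]:
    """Read the clinical TSV; disease onset is derived from age at
    diagnosis, never stored, and 'Not informed' hormonal status is kept
    as missing."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in ("sample_id", "exposure", "age_dx"):
        if col not in df.columns:
            raise FormatError(f"missing required column(s): {col}")
    out: dict[str, ClinicalRecord] = {}
    for idx, row in df.iterrows():
        sid = row["sample_id"].strip()
        if sid in out:
            raise FormatError(f"duplicate sample_id {sid!r} at row {idx}")
        try:
            age = float(row["age_dx"])
        except ValueError as exc:
            raise FormatError(f"row {idx}: non-numeric age_dx {row['age_dx']!r}") from exc

        def col(name: str) -> str:
            return str(row[name]) if name in df.columns else ""

        out[sid] = ClinicalRecord(
            sample_id=sid,
            exposure=Exposure(row["exposure"].strip().lower()),
            age_dx=age,
            grade_iii=_tri_bool(col("grade"), "iii", "i_ii"),
            er=_tri_bool(col("er"), "positive", "negative"),
            pr=_tri_bool(col("pr"), "positive", "negative"),
            her2=_tri_bool(col("her2"), "positive", "negative"),
            subtype=col("subtype").strip() or None,
            nodal=_tri_bool(col("nodal"), "true", "false"),
            metastasis=_tri_bool(col("metastasis"), "true", "false"),
            chemoresistance=_tri_bool(col("chemoresistance"), "true", "false"),
            relapse=_tri_bool(col("relapse"), "true", "false"),
            deceased=_tri_bool(col("deceased"), "true", "false"),
            premenopause=_tri_bool(col("menopause"), "pre", "post"),
        )
    return out


def write_clinical(clinical: dict[str, ClinicalRecord], path: str | Path) -> None:
    def fmt(val: Optional[bool], true_token: str, false_token: str) -> str:
        if val is None:
            return ""
        return true_token if val else false_token

    rows = []
    for sid in sorted(clinical):
        c = clinical[sid]
        rows.append(
            {
                "sample_id": sid,
                "exposure": c.exposure.value,
                "age_dx": f"{c.age_dx:g}",
                "grade": fmt(c.grade_iii, "III", "I_II"),
                "er": fmt(c.er, "positive", "negative"),
                "pr": fmt(c.pr, "positive", "negative"),
                "her2": fmt(c.her2, "positive", "negative"),
                "subtype": c.subtype or "",
                "nodal": fmt(c.nodal, "true", "false"),
                "metastasis": fmt(c.metastasis, "true", "false"),
                "chemoresistance": fmt(c.chemoresistance, "true", "false"),
                "relapse": fmt(c.relapse, "true", "false"),
                "deceased": fmt(c.deceased, "true", "false"),
                "menopause": fmt(c.premenopause, "pre", "post"),
            }
        )
    pd.DataFrame(rows, columns=_CLIN_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# panel BED

def read_panel(path: str | Path) -> PanelDefinition:
    """Read a 4-column BED (chrom, start, end, gene), 0-based half-open."""
    intervals: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"line {lineno}: expected 4 BED columns")
            chrom, start_s, end_s, gene = parts[:4]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise FormatError(f"line {lineno}: start {start} >= end {end}")
            intervals.append((chrom, start, end, gene))
    return PanelDefinition(tuple(intervals))


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, gene in sorted(panel.intervals):
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")


# ---------------------------------------------------------------------------
# whole cohort

def read_cohort(
    variants_path: str | Path,
    clinical_path: str | Path,
    panel_path: str | Path,
    dialect: str = "maf",
) -> Cohort:
    return Cohort(
        variants=read_variants(variants_path, dialect=dialect),
        clinical=read_clinical(clinical_path),
        panel=read_panel(panel_path),
    )


def write_cohort(
    cohort: Cohort,
    variants_path: str | Path,
    clinical_path: str | Path,
    panel_path: str | Path,
    dialect: str = "maf",
) -> None:
    write_variants(cohort.variants, variants_path, dialect=dialect)
    write_clinical(cohort.clinical, clinical_path)
    write_panel(cohort.panel, panel_path)
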