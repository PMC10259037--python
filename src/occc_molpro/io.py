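"""Readers and writers for the pipeline's external formats.

Variants travel as VCF 4.2 (annotation carried in INFO tags, documented
below) or as a flat TSV with named headers.  All tables are UTF-8,
tab-delimited, with ``.`` for missing values.

VCF INFO tag scheme::

    SAMPLE   sample identifier (one sample per record)
    GENE     HGNC-like gene symbol
    TX       transcript accession
    CSQ      consequence token (see Consequence enum)
    AF       variant allele frequency in [0, 1]
    HGVSC    HGVS c. string
    HGVSP    HGVS p. string
    CLNSIG   ClinVar-style class (see ClinVarClass enum)
    DB       flag: present in a population polymorphism database
    DRIVER   flag: known or probable driver mutation
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .types import ClinicalRecord, ClinVarClass, Consequence, MarkerStatus, VariantRecord


class ParseError(Exception):
    """Malformed input file; the message names the offending line."""


class SchemaError(Exception):
    """Input file is parseable but lacks a mandatory column."""


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to half-open BED coordinates."""
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based interval [{start}, {end}]")
    return start - 1, end


def from_bed_interval(start: int, end: int) -> tuple[int, int]:
    """Convert a half-open BED interval to 1-based inclusive coordinates."""
    if start < 0 or end <= start:
        raise ValueError(f"invalid BED interval [{start}, {end})")
    return start + 1, end


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "sample_id",
    "gene",
    "transcript_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "allele_frequency",
    "clinvar_class",
    "in_polymorphism_db",
    "known_driver",
]

_MANDATORY_VARIANT_COLUMNS = ["sample_id", "gene", "chrom", "pos", "ref", "alt", "consequence"]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample identifier">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=TX,Number=1,Type=String,Description="Transcript accession">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence token">
##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele frequency">
##INFO=<ID=HGVSC,Number=1,Type=String,Description="HGVS c. notation">
##INFO=<ID=HGVSP,Number=1,Type=String,Description="HGVS p. notation">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar-style classification">
##INFO=<ID=DB,Number=0,Type=Flag,Description="Present in polymorphism database">
##INFO=<ID=DRIVER,Number=0,Type=Flag,Description="Known or probable driver">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def read_variants(path: str | Path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read variant calls from ``path`` in the named dialect (``vcf``/``tsv``).

    Every row becomes exactly one :class:`VariantRecord`, preserving input
    order.  Unparseable optional annotations become explicit missing values
    (``None`` AF, ``absent`` ClinVar class), never silent defaults.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'vcf' or 'tsv'")


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return str(value).strip().lower() in {"1", "true", "yes", "y"}


def _read_variants_tsv(path: Path) -> list[VariantRecord]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _MANDATORY_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    def clean(value: object) -> str | None:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return str(value)

    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = {k: clean(v) for k, v in row._asdict().items()}
        try:
            af = d.get("allele_frequency")
            records.append(
                VariantRecord(
                    sample_id=d["sample_id"],
                    gene=d["gene"],
                    transcript_id=d.get("transcript_id") or "",
                    chrom=d["chrom"],
                    pos=int(d["pos"]),
                    ref=d["ref"],
                    alt=d["alt"],
                    hgvs_c=d.get("hgvs_c") or "",
                    hgvs_p=d.get("hgvs_p") or "",
                    consequence=Consequence(d["consequence"]),
                    allele_frequency=float(af) if af not in (None, "") else None,
                    clinvar_class=ClinVarClass(d["clinvar_class"])
                    if d.get("clinvar_class") not in (None, "")
                    else ClinVarClass.ABSENT,
                    in_polymorphism_db=_parse_bool(d.get("in_polymorphism_db")),
                    known_driver=_parse_bool(d.get("known_driver")),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc
    return records


def _read_variants_vcf(path: Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: not a parseable VCF ({exc})") from exc
    records: list[VariantRecord] = []
    for i, v in enumerate(vcf, start=1):
        info = dict(v.INFO)
        csq = info.get("CSQ")
        if csq is None:
            raise ParseError(f"{path} record {i}: missing CSQ consequence tag")
        try:
            consequence = Consequence(csq)
        except ValueError as exc:
            raise ParseError(f"{path} record {i}: unknown consequence {csq!r}") from exc
        try:
            clnsig = ClinVarClass(info["CLNSIG"]) if "CLNSIG" in info else ClinVarClass.ABSENT
        except ValueError:
            clnsig = ClinVarClass.ABSENT
        af = info.get("AF")
        records.append(
            VariantRecord(
                sample_id=str(info.get("SAMPLE", "")),
                gene=str(info.get("GENE", "")),
                transcript_id=str(info.get("TX", "")),
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else "",
                hgvs_c=str(info.get("HGVSC", "")),
                hgvs_p=str(info.get("HGVSP", "")),
                consequence=consequence,
                allele_frequency=round(float(af), 6) if af is not None else None,
                clinvar_class=clnsig,
                in_polymorphism_db="DB" in info,
                known_driver="DRIVER" in info,
            )
        )
    return records


def write_variants(records: list[VariantRecord], path: str | Path, dialect: str = "tsv") -> None:
    """Write variant records in the named dialect; inverse of :func:`read_variants`."""
    path = Path(path)
    if dialect == "tsv":
        rows = []
        for r in records:
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "gene": r.gene,
                    "transcript_id": r.transcript_id or ".",
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "ref": r.ref,
                    "alt": r.alt,
                    "hgvs_c": r.hgvs_c or ".",
                    "hgvs_p": r.hgvs_p or ".",
                    "consequence": r.consequence.value,
                    "allele_frequency": r.allele_frequency if r.allele_frequency is not None else ".",
                    "clinvar_class": r.clinvar_class.value,
                    "in_polymorphism_db": int(r.in_polymorphism_db),
                    "known_driver": int(r.known_driver),
                }
            )
        pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)
    elif dialect == "vcf":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_VCF_HEADER)
            for r in records:
                info = [
                    f"SAMPLE={r.sample_id}",
                    f"GENE={r.gene}",
                    f"CSQ={r.consequence.value}",
                ]
                if r.transcript_id:
                    info.append(f"TX={r.transcript_id}")
                if r.allele_frequency is not None:
                    info.append(f"AF={r.allele_frequency:.6g}")
                if r.hgvs_c:
                    info.append(f"HGVSC={r.hgvs_c}")
                if r.hgvs_p:
                    info.append(f"HGVSP={r.hgvs_p}")
                if r.clinvar_class is not ClinVarClass.ABSENT:
                    info.append(f"CLNSIG={r.clinvar_class.value}")
                if r.in_polymorphism_db:
                    info.append("DB")
                if r.known_driver:
                    info.append("DRIVER")
                fh.write(
                    f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t{';'.join(info)}\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = [
    "sample_id",
    "age",
    "figo_stage",
    "t_stage_high",
    "resection_r0",
    "adjuvant_therapy",
    "recurrence",
    "recurrence_type",
    "survival_status",
    "followup_months",
    "recurrence_months",
]


def _tri(value: object) -> bool | None:
    if value in (None, "", "."):
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return str(value).strip().lower() in {"1", "true", "yes", "y"}


def _tri_out(value: bool | None) -> str:
    return "." if value is None else ("yes" if value else "no")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    missing = [c for c in ("sample_id", "survival_status", "followup_months") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    def clean(value: object) -> str | None:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return str(value)

    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = {k: clean(v) for k, v in row._asdict().items()}

        def num(key: str) -> float | None:
            v = d.get(key)
            return float(v) if v not in (None, "") else None

        try:
            out.append(
                ClinicalRecord(
                    sample_id=d["sample_id"],
                    age=num("age"),
                    figo_stage=d.get("figo_stage") or "NA",
                    t_stage_high=_tri(d.get("t_stage_high")),
                    resection_r0=_tri(d.get("resection_r0")),
                    adjuvant_therapy=_tri(d.get("adjuvant_therapy")),
                    recurrence=_tri(d.get("recurrence")),
                    recurrence_type=d.get("recurrence_type") or "NA",
                    survival_status=d.get("survival_status") or "NA",
                    followup_months=num("followup_months"),
                    recurrence_months=num("recurrence_months"),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc
    return out


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "age": r.age if r.age is not None else ".",
                "figo_stage": r.figo_stage.value,
                "t_stage_high": _tri_out(r.t_stage_high),
                "resection_r0": _tri_out(r.resection_r0),
                "adjuvant_therapy": _tri_out(r.adjuvant_therapy),
                "recurrence": _tri_out(r.recurrence),
                "recurrence_type": r.recurrence_type.value,
                "survival_status": r.survival_status.value,
                "followup_months": r.followup_months if r.followup_months is not None else ".",
                "recurrence_months": r.recurrence_months if r.recurrence_months is not None else ".",
            }
        )
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MSI marker table
# ---------------------------------------------------------------------------

N_MSI_MARKERS = 17
MSI_MARKER_COLUMNS = [f"marker_{i:02d}" for i in range(1, N_MSI_MARKERS + 1)]


def read_msi_markers(path: str | Path) -> dict[str, list[MarkerStatus]]:
    """Read the per-sample MSI marker status table.

    Returns a mapping ``sample_id -> list of 17 MarkerStatus``; ``.`` cells
    become ``not_evaluated``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing mandatory column(s) ['sample_id']")
    marker_cols = [c for c in df.columns if c.startswith("marker_")]
    if not marker_cols:
        raise SchemaError(f"{path}: no marker_* columns found")
    out: dict[str, list[MarkerStatus]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        statuses = []
        for c in marker_cols:
            v = d.get(c)
            if v in (None, "") or (isinstance(v, float) and math.isnan(v)):
                statuses.append(MarkerStatus.NOT_EVALUATED)
            else:
                try:
                    statuses.append(MarkerStatus(v))
                except ValueError as exc:
                    raise ParseError(f"{path} line {i}: bad marker status {v!r}") from exc
        out[d["sample_id"]] = statuses
    return out


def write_msi_markers(table: dict[str, list[MarkerStatus]], path: str | Path) -> None:
    rows = []
    for sample_id, statuses in table.items():
        row = {"sample_id": sample_id}
        for i, s in enumerate(statuses, start=1):
            row[f"marker_{i:02d}"] = "." if s is MarkerStatus.NOT_EVALUATED else s.value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tumor purity table
# ---------------------------------------------------------------------------

def read_purity(path: str | Path) -> dict[str, float | None]:
    """Read per-sample tumor cell fractions (columns sample_id, tumor_cell_fraction)."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    missing = [c for c in ("sample_id", "tumor_cell_fraction") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    out: dict[str, float | None] = {}
    for row in df.itertuples(index=False):
        v = row.tumor_cell_fraction
        out[row.sample_id] = float(v) if v not in (None, "") else None
    return out


def write_purity(purity: dict[str, float | None], path: str | Path) -> None:
    rows = [
        {"sample_id": s, "tumor_cell_fraction": v if v is not None else "."}
        for s, v in purity.items()
    ]
    pd.DataFrame(rows, columns=["sample_id", "tumor_cell_fraction"]).to_csv(
        path, sep="\t", index=False
    )
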