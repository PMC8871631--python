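"""Readers and writers for variant tables, pedigrees, cohorts and traces.

Two variant-table dialects are supported:

``flat_tsv``
    One row per biallelic variant. Fixed columns ``chrom, pos, ref, alt,
    gene, transcript, consequence, splice_offset, cadd_phred, gerp_rs,
    acmg_class, clinvar``; any column named ``aaf_<db>`` carries that
    database's alternative allele frequency (blank = absent from the
    database); predictor columns (``sift``, ``polyphen2``,
    ``mutation_taster``, ``mutation_assessor``, ``vest3``, ``metalr``,
    ``metasvm``, ``provean``) hold ``D``/``B``/``.``; genotype columns are
    named ``gt_<sample>`` with VCF-style ``0/0``, ``0/1``, ``1/1``, ``./.``.
    Unrecognised columns are preserved as opaque extras.

``vcf_plus_sidecar``
    A VCF 4.x file for the genotypes plus a tab-separated annotation
    sidecar keyed by ``chrom, pos, ref, alt`` carrying the same annotation
    columns as the flat dialect. Multi-allelic VCF sites are decomposed
    into biallelic records at read time.

Positions are 1-based in every text format (pysam's 0-based internals are
converted at the boundary).

The pedigree format is PED-like, whitespace-separated, eight columns:
family, id, father, mother, sex (1=male, 2=female, 0=unknown), affection
(1=unaffected, 2=affected, 0=unknown), sequenced (0/1), generation label.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .model import (
    Affection,
    AnnotationProfile,
    ClinvarStatus,
    Consequence,
    CohortSubject,
    FilterTrace,
    MergedVariantTable,
    Pedigree,
    PedigreeMember,
    Subgroup,
    VariantKey,
    VariantRecord,
    Zygosity,
)

log = logging.getLogger(__name__)

_PREDICTOR_COLUMNS = {
    "sift": "SIFT",
    "polyphen2": "Polyphen2",
    "mutation_taster": "MutationTaster",
    "mutation_assessor": "MutationAssessor",
    "vest3": "VEST3",
    "metalr": "MetaLR",
    "metasvm": "MetaSVM",
    "provean": "PROVEAN",
}
_PREDICTOR_CODES = {"D": "deleterious", "B": "benign", ".": "unknown", "": "unknown"}
_PREDICTOR_CODES_INV = {"deleterious": "D", "benign": "B", "unknown": "."}

_CLINVAR_CODES = {
    "NR": ClinvarStatus.NOT_REPORTED,
    "B": ClinvarStatus.BENIGN,
    "US": ClinvarStatus.UNCERTAIN_SIGNIFICANCE,
    "LP": ClinvarStatus.LIKELY_PATHOGENIC,
    "P": ClinvarStatus.PATHOGENIC,
}
_CLINVAR_CODES_INV = {v: k for k, v in _CLINVAR_CODES.items()}

_GT_STRINGS = {
    "0/0": Zygosity.HOM_REF,
    "0/1": Zygosity.HET,
    "1/0": Zygosity.HET,
    "1/1": Zygosity.HOM_ALT,
    "./.": Zygosity.MISSING,
    ".": Zygosity.MISSING,
    "": Zygosity.MISSING,
}
_GT_STRINGS_INV = {
    Zygosity.HOM_REF: "0/0",
    Zygosity.HET: "0/1",
    Zygosity.HOM_ALT: "1/1",
    Zygosity.MISSING: "./.",
}

_FIXED_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "consequence",
    "splice_offset",
    "cadd_phred",
    "gerp_rs",
    "acmg_class",
    "clinvar",
]


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


# ---------------------------------------------------------------------------
# annotation row <-> AnnotationProfile

def _annotation_from_row(row: dict, line_no: int, path) -> AnnotationProfile:
    def bad(msg: str) -> FormatError:
        return FormatError(f"{path}, line {line_no}: {msg}")

    try:
        consequence = Consequence(row.get("consequence", "other") or "other")
    except ValueError:
        raise bad(f"unknown consequence {row.get('consequence')!r}") from None
    splice_raw = row.get("splice_offset", "")
    splice_offset = None
    if splice_raw not in ("", ".", None) and not pd.isna(splice_raw):
        try:
            splice_offset = int(float(splice_raw))
        except ValueError:
            raise bad(f"bad splice_offset {splice_raw!r}") from None
    aaf_by_db: dict[str, float] = {}
    predictor_calls = {}
    extras: dict[str, str] = {}
    for col, value in row.items():
        if col in _FIXED_COLUMNS or col.startswith("gt_"):
            continue
        blank = value in ("", None) or (not isinstance(value, str) and pd.isna(value))
        if col.startswith("aaf_"):
            if not blank:
                try:
                    aaf_by_db[col[4:]] = float(value)
                except ValueError:
                    raise bad(f"bad AAF {value!r} in column {col}") from None
        elif col in _PREDICTOR_COLUMNS:
            code = "." if blank else str(value).strip()
            if code not in _PREDICTOR_CODES:
                raise bad(f"bad predictor code {value!r} in column {col}")
            from .model import PredictorCall

            call = PredictorCall(_PREDICTOR_CODES[code])
            # "." means no call was made; keep only informative entries so a
            # written table reads back equal to its in-memory source.
            if call is not PredictorCall.UNKNOWN:
                predictor_calls[_PREDICTOR_COLUMNS[col]] = call
        else:
            if not blank:
                extras[col] = str(value)
    clinvar_code = str(row.get("clinvar", "NR") or "NR").strip()
    if clinvar_code not in _CLINVAR_CODES:
        raise bad(f"unknown ClinVar code {clinvar_code!r}")

    def num(name: str, default: float) -> float:
        raw = row.get(name, "")
        if raw in ("", None) or (not isinstance(raw, str) and pd.isna(raw)):
            return default
        try:
            return float(raw)
        except ValueError:
            raise bad(f"bad {name} {raw!r}") from None

    try:
        return AnnotationProfile(
            gene=str(row.get("gene", "") or ""),
            transcript=str(row.get("transcript", "") or ""),
            consequence=consequence,
            splice_offset=splice_offset,
            aaf_by_db=aaf_by_db,
            predictor_calls=predictor_calls,
            cadd_phred=num("cadd_phred", 0.0),
            gerp_rs=num("gerp_rs", 0.0),
            acmg_class=int(num("acmg_class", 3)),
            clinvar_status=_CLINVAR_CODES[clinvar_code],
            extras=extras,
        )
    except ValueError as exc:
        raise bad(str(exc)) from None


def _annotation_to_row(ann: AnnotationProfile) -> dict[str, str]:
    row = {
        "gene": ann.gene,
        "transcript": ann.transcript,
        "consequence": ann.consequence.value,
        "splice_offset": "" if ann.splice_offset is None else str(ann.splice_offset),
        "cadd_phred": repr(ann.cadd_phred),
        "gerp_rs": repr(ann.gerp_rs),
        "acmg_class": str(ann.acmg_class),
        "clinvar": _CLINVAR_CODES_INV[ann.clinvar_status],
    }
    for db, aaf in sorted(ann.aaf_by_db.items()):
        row[f"aaf_{db}"] = repr(aaf)
    for col, name in _PREDICTOR_COLUMNS.items():
        if name in ann.predictor_calls:
            row[col] = _PREDICTOR_CODES_INV[ann.predictor_calls[name].value]
    row.update(ann.extras)
    return row


# ---------------------------------------------------------------------------
# variant tables

def read_variant_table(path, dialect: str = "flat_tsv", sidecar=None) -> MergedVariantTable:
    """Read a (merged) variant table.

    Parameters
    ----------
    path
        The TSV file (``flat_tsv``) or the VCF file (``vcf_plus_sidecar``).
    dialect
        ``"flat_tsv"`` or ``"vcf_plus_sidecar"``.
    sidecar
        Path to the annotation sidecar; defaults to ``<path>.annot.tsv``
        for the VCF dialect.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "flat_tsv":
        return _read_flat_tsv(path)
    if dialect == "vcf_plus_sidecar":
        sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".annot.tsv")
        return _read_vcf_sidecar(path, sidecar)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_flat_tsv(path: Path) -> MergedVariantTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    gt_cols = [c for c in df.columns if c.startswith("gt_")]
    sample_ids = [c[3:] for c in gt_cols]
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    table = MergedVariantTable(sample_ids)
    for i, row in enumerate(df.to_dict(orient="records")):
        line_no = i + 2  # header is line 1
        try:
            key = VariantKey(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
            )
        except ValueError as exc:
            raise FormatError(f"{path}, line {line_no}: {exc}") from None
        ann = _annotation_from_row(row, line_no, path)
        genotypes = {}
        for sid, col in zip(sample_ids, gt_cols):
            raw = str(row.get(col, "")).strip()
            if raw not in _GT_STRINGS:
                raise FormatError(f"{path}, line {line_no}: bad genotype {raw!r}")
            if raw in ("", ".", "./."):
                if raw == "":
                    log.warning("%s line %d: missing call for %s", path, line_no, sid)
            genotypes[sid] = _GT_STRINGS[raw]
        try:
            table.add(VariantRecord(key, ann, genotypes))
        except ValueError as exc:
            raise FormatError(f"{path}, line {line_no}: {exc}") from None
    return table


def _read_vcf_sidecar(vcf_path: Path, sidecar_path: Path) -> MergedVariantTable:
    ann_df = pd.read_csv(sidecar_path, sep="\t", dtype=str, keep_default_na=False)
    annotations: dict[VariantKey, AnnotationProfile] = {}
    for i, row in enumerate(ann_df.to_dict(orient="records")):
        line_no = i + 2
        key = VariantKey(str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        annotations[key] = _annotation_from_row(row, line_no, sidecar_path)
    with pysam.VariantFile(str(vcf_path)) as vf:
        sample_ids = list(vf.header.samples)
        table = MergedVariantTable(sample_ids)
        for rec in vf:
            # decompose multi-allelic sites into biallelic records
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                key = VariantKey(rec.contig, rec.pos, rec.ref, alt)
                genotypes = {}
                for sid in sample_ids:
                    gt = rec.samples[sid].get("GT")
                    if gt is None or any(a is None for a in gt):
                        genotypes[sid] = Zygosity.MISSING
                    else:
                        copies = sum(1 for a in gt if a == alt_index)
                        genotypes[sid] = (
                            Zygosity.HOM_REF,
                            Zygosity.HET,
                            Zygosity.HOM_ALT,
                        )[copies]
                ann = annotations.get(key)
                if ann is None:
                    log.warning("no sidecar annotation for %s; using empty profile", key)
                    ann = AnnotationProfile(gene="")
                table.add(VariantRecord(key, ann, genotypes))
    return table


def write_variant_table(table: MergedVariantTable, path, dialect: str = "flat_tsv", sidecar=None) -> None:
    """Write a variant table in the given dialect (see :func:`read_variant_table`)."""
    path = Path(path)
    if dialect == "flat_tsv":
        _write_flat_tsv(table, path)
    elif dialect == "vcf_plus_sidecar":
        sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".annot.tsv")
        _write_vcf_sidecar(table, path, sidecar)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _table_rows(table: MergedVariantTable, with_genotypes: bool) -> tuple[list[str], list[dict]]:
    rows = []
    extra_cols: list[str] = []
    for rec in table:
        row = {
            "chrom": rec.key.chrom,
            "pos": str(rec.key.pos),
            "ref": rec.key.ref,
            "alt": rec.key.alt,
        }
        row.update(_annotation_to_row(rec.annotation))
        if with_genotypes:
            for sid in table.sample_ids:
                row[f"gt_{sid}"] = _GT_STRINGS_INV[rec.genotypes[sid]]
        for col in row:
            if col not in extra_cols:
                extra_cols.append(col)
        rows.append(row)
    # stable column order: fixed, then aaf_*, predictors, extras, genotypes
    ordered = [c for c in _FIXED_COLUMNS if c in extra_cols]
    ordered += sorted(c for c in extra_cols if c.startswith("aaf_"))
    ordered += [c for c in _PREDICTOR_COLUMNS if c in extra_cols]
    ordered += [
        c
        for c in extra_cols
        if c not in ordered and not c.startswith("gt_")
    ]
    if with_genotypes:
        ordered += [f"gt_{sid}" for sid in table.sample_ids]
    return ordered, rows


def _write_flat_tsv(table: MergedVariantTable, path: Path) -> None:
    columns, rows = _table_rows(table, with_genotypes=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t", restval="")
        writer.writeheader()
        writer.writerows(rows)


def _write_vcf_sidecar(table: MergedVariantTable, vcf_path: Path, sidecar_path: Path) -> None:
    header = pysam.VariantHeader()
    contigs: list[str] = []
    for rec in table:
        if rec.key.chrom not in contigs:
            contigs.append(rec.key.chrom)
    for contig in contigs:
        header.contigs.add(contig)
    header.formats.add("GT", 1, "String", "Genotype")
    for sid in table.sample_ids:
        header.add_sample(sid)
    gt_tuples = {
        Zygosity.HOM_REF: (0, 0),
        Zygosity.HET: (0, 1),
        Zygosity.HOM_ALT: (1, 1),
        Zygosity.MISSING: (None, None),
    }
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for rec in sorted(table, key=lambda r: (contigs.index(r.key.chrom), r.key.pos)):
            vrec = out.new_record(
                contig=rec.key.chrom,
                start=rec.key.pos - 1,
                alleles=(rec.key.ref, rec.key.alt),
            )
            for sid in table.sample_ids:
                vrec.samples[sid]["GT"] = gt_tuples[rec.genotypes[sid]]
            out.write(vrec)
    columns, rows = _table_rows(table, with_genotypes=False)
    with open(sidecar_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t", restval="")
        writer.writeheader()
        writer.writerows(rows)


def merge_individual_tables(tables: Sequence[MergedVariantTable]) -> MergedVariantTable:
    """Union of single-sample variant tables into one multi-sample table.

    A sample with no record at a variant is coded :attr:`Zygosity.MISSING`
    (single-sample variant files omit confidently-reference sites, so a
    reference call cannot be fabricated). Annotation conflicts for the same
    variant key resolve first-wins with a logged warning.
    """
    sample_ids: list[str] = []
    for t in tables:
        if len(t.sample_ids) != 1:
            raise ValueError("merge_individual_tables expects single-sample tables")
        if t.sample_ids[0] not in sample_ids:
            sample_ids.append(t.sample_ids[0])
    merged = MergedVariantTable(sample_ids)
    for t in tables:
        sid = t.sample_ids[0]
        for rec in t:
            if rec.key in merged:
                target = merged.get(rec.key)
                if (
                    rec.annotation.gene != target.annotation.gene
                    or rec.annotation.consequence != target.annotation.consequence
                ):
                    log.warning(
                        "conflicting annotation for %s (sample %s); keeping first",
                        rec.key,
                        sid,
                    )
                target.genotypes[sid] = rec.genotypes[sid]
            else:
                genotypes = {s: Zygosity.MISSING for s in sample_ids}
                genotypes[sid] = rec.genotypes[sid]
                merged.add(VariantRecord(rec.key, rec.annotation, genotypes))
    return merged


# ---------------------------------------------------------------------------
# pedigree

_SEX_CODES = {"1": "M", "2": "F", "0": "U"}
_SEX_CODES_INV = {"M": "1", "F": "2", "U": "0"}


def read_pedigree(path) -> Pedigree:
    """Read the extended PED format (see module docstring)."""
    members = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 7:
                raise FormatError(f"{path}, line {line_no}: expected >= 7 columns")
            _, member_id, _, _, sex, affection, sequenced = fields[:7]
            generation = fields[7] if len(fields) > 7 else ""
            if affection not in ("0", "1", "2"):
                raise FormatError(
                    f"{path}, line {line_no}: unknown affection code {affection!r}"
                )
            if sequenced not in ("0", "1"):
                raise FormatError(
                    f"{path}, line {line_no}: sequenced flag must be 0/1"
                )
            members.append(
                PedigreeMember(
                    member_id=member_id,
                    sex=_SEX_CODES.get(sex, "U"),
                    generation=generation,
                    affection=Affection(int(affection)),
                    sequenced=sequenced == "1",
                )
            )
    return Pedigree(members)


def write_pedigree(pedigree: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("# fam id father mother sex affection sequenced generation\n")
        for m in pedigree:
            fh.write(
                f"FAM1 {m.member_id} 0 0 {_SEX_CODES_INV.get(m.sex, '0')} "
                f"{m.affection.value} {int(m.sequenced)} {m.generation}\n"
            )


# ---------------------------------------------------------------------------
# cohort

_COHORT_PHENOS = [
    "age",
    "ls_bmd",
    "fn_bmd",
    "th_bmd",
    "ls_t",
    "fn_t",
    "th_t",
    "ls_z",
    "fn_z",
    "calcium",
    "alp",
    "albumin",
]


def read_cohort(path) -> list[CohortSubject]:
    """Read a cohort CSV (header documented in :func:`write_cohort`)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and "subject_id" not in df.columns:
        return []
    gt_cols = [c for c in df.columns if c.startswith("gt_")]
    subjects = []
    for i, row in enumerate(df.to_dict(orient="records")):
        line_no = i + 2
        try:
            subgroup = Subgroup(row["subgroup"])
        except (KeyError, ValueError):
            raise FormatError(
                f"{path}, line {line_no}: unknown subgroup {row.get('subgroup')!r}"
            ) from None
        genotypes = {}
        for col in gt_cols:
            raw = row[col].strip()
            genotypes[col[3:]] = (
                Zygosity.MISSING if raw in ("", "missing") else Zygosity(raw)
            )
        phenos = {}
        for name in _COHORT_PHENOS:
            raw = row.get(name, "")
            phenos[name] = float(raw) if raw not in ("", None) else None
        sites = frozenset(s for s in row.get("fracture_sites", "").split(";") if s)
        subjects.append(
            CohortSubject(
                subject_id=row["subject_id"],
                subgroup=subgroup,
                genotypes=genotypes,
                fracture_sites=sites,
                calcium_supplement=row.get("calcium_supplement", "0") == "1",
                **phenos,
            )
        )
    return subjects


def write_cohort(subjects: Sequence[CohortSubject], path) -> None:
    variant_names: list[str] = []
    for s in subjects:
        for v in s.genotypes:
            if v not in variant_names:
                variant_names.append(v)
    columns = (
        ["subject_id", "subgroup"]
        + _COHORT_PHENOS
        + ["fracture_sites", "calcium_supplement"]
        + [f"gt_{v}" for v in variant_names]
    )
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        for s in subjects:
            row = {"subject_id": s.subject_id, "subgroup": s.subgroup.value}
            for name in _COHORT_PHENOS:
                value = getattr(s, name)
                row[name] = "" if value is None else repr(value)
            row["fracture_sites"] = ";".join(sorted(s.fracture_sites))
            row["calcium_supplement"] = "1" if s.calcium_supplement else "0"
            for v in variant_names:
                zyg = s.genotypes.get(v, Zygosity.MISSING)
                row[f"gt_{v}"] = zyg.value
            writer.writerow(row)


# ---------------------------------------------------------------------------
# gene lists, blacklists, traces

def read_gene_list(path) -> set[str]:
    """One symbol per line; '#' starts a comment. Blacklists may also carry
    exact variant keys written ``chrom:pos:ref>alt``."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    return out


def write_gene_list(symbols: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for sym in sorted(symbols):
            fh.write(f"{sym}\n")


def write_filter_trace(trace: FilterTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tsnvs\tindels\n")
        for name, n_snv, n_indel in trace.stages:
            fh.write(f"{name}\t{n_snv}\t{n_indel}\n")


def read_filter_trace(path) -> FilterTrace:
    trace = FilterTrace()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("stage\t"):
            raise FormatError(f"{path}: missing trace header")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}, line {line_no}: expected 3 columns")
            trace.append(parts[0], int(parts[1]), int(parts[2]))
    return trace
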