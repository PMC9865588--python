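"""Readers and writers for annotated variant tables, gene lists, GMT
collections and ID-mapping tables.

Two input dialects are supported for cohort tables: an ANNOVAR-style
multianno TSV (one row per variant, per-patient genotype columns) and a
VCF 4.2 whose annotations live in INFO fields.  In both, the tokens
``-``, ``.``, ``NA`` and the empty string denote an *absent* annotation,
which is kept distinct from an observed value of 0.0 throughout.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    AnnotatedVariant,
    CohortTable,
    GeneList,
    GeneSetCollection,
    PathoAnnotations,
    PatientRecord,
    PopulationFrequencies,
)

logger = logging.getLogger(__name__)

MISSING_TOKENS = frozenset({"-", ".", "", "NA", "na", "NaN", "nan", "None"})

#: column roles -> column names in the packaged TSV dialect; for the VCF
#: dialect the same roles map to INFO keys (genotypes come from samples).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "chrom": "Chr",
    "pos": "Start",
    "ref": "Ref",
    "alt": "Alt",
    "gene": "Gene.refGene",
    "consequence": "ExonicFunc.refGene",
    "hgvs": "AAChange.refGene",
    "twb": "TWB_AF",
    "kgp_eas": "1KGP_EAS_AF",
    "gnomad_eas": "gnomAD_EAS_AF",
    "exac_eas": "ExAC_EAS_AF",
    "clinvar": "CLNSIG",
    "cadd": "CADD_phred",
    "revel": "REVEL",
}

MANDATORY_ROLES = ("chrom", "pos", "ref", "alt", "gene", "consequence")
FREQ_ROLES = ("twb", "kgp_eas", "gnomad_eas", "exac_eas")
CONSEQUENCE_SEPARATOR = ";"


class ParseError(ValueError):
    """Fatal problem parsing an input file."""


class MissingColumnError(ParseError):
    def __init__(self, column: str, path: object) -> None:
        super().__init__(f"mandatory column {column!r} missing from {path}")
        self.column = column


class RowError(ParseError):
    """A malformed value localized to one data row."""

    def __init__(self, row: int, message: str) -> None:
        super().__init__(f"row {row}: {message}")
        self.row = row


def _is_missing(cell: object) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and np.isnan(cell):
        return True
    return str(cell).strip() in MISSING_TOKENS


def _parse_float(cell: object, row: int, column: str) -> Optional[float]:
    if _is_missing(cell):
        return None
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise RowError(row, f"cannot parse {column!r} value {cell!r} as a number") from None


def _parse_freq(cell: object, row: int, column: str) -> Optional[float]:
    value = _parse_float(cell, row, column)
    if value is not None and not (0.0 <= value <= 1.0):
        raise RowError(row, f"frequency {column!r}={value} outside [0, 1]")
    return value


# ---------------------------------------------------------------------------
# annotated cohort tables
# ---------------------------------------------------------------------------

def read_annotated_table(
    path: str | Path,
    dialect: str = "annovar_tsv",
    column_map: Optional[dict[str, str]] = None,
    patient_columns: Optional[Sequence[str]] = None,
    patients: Optional[Sequence[PatientRecord]] = None,
) -> CohortTable:
    """Read an annotated cohort table.

    Parameters
    ----------
    dialect
        ``"annovar_tsv"`` (multianno-style TSV with per-patient genotype
        columns) or ``"annotated_vcf"`` (VCF 4.2; annotation roles map to
        INFO keys, genotypes come from the sample columns).
    column_map
        Mapping of roles (see :data:`DEFAULT_COLUMN_MAP`) to column/INFO
        names; defaults to the packaged dialect.
    patient_columns
        TSV only: explicit genotype column names.  When omitted, every
        column not named by ``column_map`` is treated as a patient column.
    patients
        Optional clinical metadata; must cover exactly the genotype
        columns when given.
    """
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    if dialect == "annovar_tsv":
        table = _read_annovar_tsv(Path(path), cmap, patient_columns)
    elif dialect == "annotated_vcf":
        table = _read_annotated_vcf(Path(path), cmap)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if patients is not None:
        by_id = {p.patient_id: p for p in patients}
        if set(by_id) != set(table.patient_ids):
            raise ParseError("patient metadata does not match genotype columns")
        table = CohortTable(
            table.variants, [by_id[i] for i in table.patient_ids], table.genotypes
        )
    return table


def _row_to_variant(row: dict, cmap: dict[str, str], idx: int) -> AnnotatedVariant:
    for role in MANDATORY_ROLES:
        if _is_missing(row.get(cmap[role])) and role != "gene":
            raise RowError(idx, f"missing mandatory field {cmap[role]!r}")
    gene_cell = row.get(cmap["gene"])
    hgvs_cell = row.get(cmap.get("hgvs", ""), None)
    clinvar_cell = row.get(cmap["clinvar"], None)
    try:
        return AnnotatedVariant(
            chrom=str(row[cmap["chrom"]]).strip(),
            pos=int(row[cmap["pos"]]),
            ref=str(row[cmap["ref"]]).strip(),
            alt=str(row[cmap["alt"]]).strip(),
            gene=None if _is_missing(gene_cell) else str(gene_cell).strip(),
            transcript_hgvs=None if _is_missing(hgvs_cell) else str(hgvs_cell).strip(),
            consequence=tuple(
                label.strip()
                for label in str(row[cmap["consequence"]]).split(CONSEQUENCE_SEPARATOR)
                if label.strip()
            ),
            freqs=PopulationFrequencies(
                **{
                    role: _parse_freq(row.get(cmap[role]), idx, cmap[role])
                    for role in FREQ_ROLES
                }
            ),
            patho=PathoAnnotations(
                clinvar_label=None if _is_missing(clinvar_cell) else str(clinvar_cell).strip(),
                cadd_phred=_parse_float(row.get(cmap["cadd"]), idx, cmap["cadd"]),
                revel=_parse_float(row.get(cmap["revel"]), idx, cmap["revel"]),
            ),
        )
    except RowError:
        raise
    except ValueError as exc:
        raise RowError(idx, str(exc)) from exc


def _read_annovar_tsv(
    path: Path, cmap: dict[str, str], patient_columns: Optional[Sequence[str]]
) -> CohortTable:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for role in MANDATORY_ROLES + FREQ_ROLES + ("clinvar", "cadd", "revel"):
        if cmap[role] not in df.columns:
            raise MissingColumnError(cmap[role], path)
    mapped = set(cmap.values())
    if patient_columns is None:
        patient_columns = [c for c in df.columns if c not in mapped]
    else:
        for c in patient_columns:
            if c not in df.columns:
                raise MissingColumnError(c, path)
    if not patient_columns:
        raise ParseError(f"no patient genotype columns found in {path}")

    variants: list[AnnotatedVariant] = []
    genotypes = np.zeros((len(df), len(patient_columns)), dtype=np.int8)
    for i, (_, row) in enumerate(df.iterrows()):
        variants.append(_row_to_variant(row.to_dict(), cmap, i))
        for j, col in enumerate(patient_columns):
            cell = row[col]
            if _is_missing(cell):
                continue
            try:
                genotypes[i, j] = int(cell)
            except ValueError:
                raise RowError(i, f"cannot parse genotype {cell!r} in column {col!r}") from None
    patients = [PatientRecord(patient_id=c) for c in patient_columns]
    return CohortTable(variants, patients, genotypes)


def _vcf_safe(key: str) -> str:
    """VCF INFO IDs must not start with a digit; prefix those with 'V'."""
    return key if (key and (key[0].isalpha() or key[0] == "_")) else f"V{key}"


def _read_annotated_vcf(path: Path, cmap: dict[str, str]) -> CohortTable:
    from cyvcf2 import VCF  # deferred: only the VCF dialect needs it

    cmap = {role: _vcf_safe(name) for role, name in cmap.items()}

    vcf = VCF(str(path))
    patient_ids = list(vcf.samples)
    if not patient_ids:
        raise ParseError(f"VCF {path} has no sample columns")
    variants: list[AnnotatedVariant] = []
    rows: list[np.ndarray] = []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise RowError(i, f"multi-allelic record at {rec.CHROM}:{rec.POS}; split first")
        info = dict(rec.INFO)
        row = {
            cmap["chrom"]: rec.CHROM,
            cmap["pos"]: rec.POS,
            cmap["ref"]: rec.REF,
            cmap["alt"]: rec.ALT[0],
        }
        for role in ("gene", "consequence", "hgvs", "clinvar") + FREQ_ROLES + ("cadd", "revel"):
            key = cmap[role]
            if key in info:
                row[key] = info[key]
        # VCF INFO strings encode spaces as underscores
        if cmap["clinvar"] in row:
            row[cmap["clinvar"]] = str(row[cmap["clinvar"]])
        if cmap["consequence"] in row:
            row[cmap["consequence"]] = str(row[cmap["consequence"]]).replace("_", " ")
        variants.append(_row_to_variant(row, cmap, i))
        gts = rec.genotype.array()[:, :2]
        rows.append((gts > 0).sum(axis=1).astype(np.int8))
    genotypes = (
        np.vstack(rows) if rows else np.zeros((0, len(patient_ids)), dtype=np.int8)
    )
    patients = [PatientRecord(patient_id=s) for s in patient_ids]
    return CohortTable(variants, patients, genotypes)


def _fmt(value: Optional[object]) -> str:
    if value is None:
        return "-"
    return str(value)


def write_annotated_table(table: CohortTable, path: str | Path) -> None:
    """Write the packaged multianno-style TSV dialect (round-trips exactly)."""
    cmap = DEFAULT_COLUMN_MAP
    columns = [
        cmap[r]
        for r in (
            "chrom", "pos", "ref", "alt", "gene", "consequence", "hgvs",
            "twb", "kgp_eas", "gnomad_eas", "exac_eas", "clinvar", "cadd", "revel",
        )
    ] + table.patient_ids
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for v, row in zip(table.variants, table.genotypes):
            cells = [
                v.chrom,
                str(v.pos),
                v.ref,
                v.alt,
                _fmt(v.gene),
                CONSEQUENCE_SEPARATOR.join(v.consequence),
                _fmt(v.transcript_hgvs),
                _fmt(v.freqs.twb),
                _fmt(v.freqs.kgp_eas),
                _fmt(v.freqs.gnomad_eas),
                _fmt(v.freqs.exac_eas),
                _fmt(v.patho.clinvar_label),
                _fmt(v.patho.cadd_phred),
                _fmt(v.patho.revel),
            ] + [str(int(g)) if g else "-" for g in row]
            fh.write("\t".join(cells) + "\n")


def write_annotated_vcf(table: CohortTable, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with annotations as INFO fields.

    Spaces in free-text INFO values (ClinVar labels, consequences) are
    encoded as underscores, the convention ClinVar VCFs use.
    """
    cmap = {role: _vcf_safe(name) for role, name in DEFAULT_COLUMN_MAP.items()}
    info_defs = [
        (cmap["gene"], "String", "Gene symbol"),
        (cmap["consequence"], "String", "Transcript consequence labels"),
        (cmap["hgvs"], "String", "Transcript/protein notation"),
        (cmap["twb"], "Float", "Taiwan Biobank allele frequency"),
        (cmap["kgp_eas"], "Float", "1000 Genomes EAS allele frequency"),
        (cmap["gnomad_eas"], "Float", "gnomAD EAS allele frequency"),
        (cmap["exac_eas"], "Float", "ExAC EAS allele frequency"),
        (cmap["clinvar"], "String", "ClinVar clinical significance"),
        (cmap["cadd"], "Float", "CADD Phred score"),
        (cmap["revel"], "Float", "REVEL score"),
    ]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##reference=GRCh38\n")
        for chrom in dict.fromkeys(v.chrom for v in table.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        for key, typ, desc in info_defs:
            fh.write(f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.patient_ids)
            + "\n"
        )
        for v, row in zip(table.variants, table.genotypes):
            info: list[str] = []

            def put(key: str, value: Optional[object], text: bool = False) -> None:
                if value is None:
                    return
                s = str(value).replace(" ", "_") if text else str(value)
                info.append(f"{key}={s}")

            put(cmap["gene"], v.gene, text=True)
            put(cmap["consequence"], CONSEQUENCE_SEPARATOR.join(v.consequence), text=True)
            put(cmap["hgvs"], v.transcript_hgvs, text=True)
            for role in FREQ_ROLES:
                put(cmap[role], v.freqs.get(role))
            put(cmap["clinvar"], v.patho.clinvar_label, text=True)
            put(cmap["cadd"], v.patho.cadd_phred)
            put(cmap["revel"], v.patho.revel)
            gts = {0: "0/0", 1: "0/1", 2: "1/1"}
            fh.write(
                "\t".join(
                    [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS",
                     ";".join(info) or ".", "GT"]
                    + [gts[int(g)] for g in row]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# patient metadata
# ---------------------------------------------------------------------------

def write_patient_table(patients: Sequence[PatientRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tsex\tage\tcurves\n")
        for p in patients:
            curves = ";".join(f"{loc}:{angle:g}" for loc, angle in p.curves)
            fh.write(f"{p.patient_id}\t{_fmt(p.sex)}\t{_fmt(p.age)}\t{curves or '-'}\n")


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    patients = []
    for i, row in df.iterrows():
        curves: list[tuple[str, float]] = []
        if not _is_missing(row["curves"]):
            for part in str(row["curves"]).split(";"):
                loc, _, angle = part.partition(":")
                curves.append((loc, float(angle)))
        patients.append(
            PatientRecord(
                patient_id=row["patient_id"],
                sex=None if _is_missing(row["sex"]) else row["sex"],
                age=None if _is_missing(row["age"]) else int(row["age"]),
                curves=tuple(curves),
            )
        )
    return patients


# ---------------------------------------------------------------------------
# gene lists, GMT collections, ID mappings
# ---------------------------------------------------------------------------

def read_gene_list(
    path: str | Path, name: Optional[str] = None, uppercase: bool = False
) -> GeneList:
    """Read a one-symbol-per-line gene list ('#' comments allowed).

    Symbols are whitespace-trimmed and case-preserved unless
    ``uppercase=True``; duplicates are dropped with a warning.
    """
    symbols: list[str] = []
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if not sym:
                continue
            symbols.append(sym.upper() if uppercase else sym)
    if not symbols:
        raise ParseError(f"gene list {path} is empty")
    seen: set[str] = set()
    unique: list[str] = []
    for sym in symbols:
        if sym in seen:
            logger.warning("duplicate gene symbol %r in %s", sym, path)
        else:
            seen.add(sym)
            unique.append(sym)
    return GeneList(name=name or Path(path).stem, genes=frozenset(unique))


def load_ais_gene_list() -> GeneList:
    """The packaged 56-gene AIS literature panel.

    This is a synthetic stand-in reconstruction: it contains the ten gene
    symbols printed in the cohort's AIS-related-variant table plus 46
    genes re-curated from the AIS genetics literature (the original
    curated appendix is not redistributable).
    """
    ref = resources.files("scoliovar.data") / "ais_related_genes.synthetic.txt"
    with resources.as_file(ref) as p:
        return read_gene_list(p, name="ais_related_genes")


def read_gmt(
    path: str | Path, background: Optional[frozenset[str]] = None
) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line.

    The background universe defaults to the union of all members unless an
    explicit one is supplied (sets are then restricted to it).
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name = fields[0].strip()
            members = frozenset(m.strip() for m in fields[2:] if m.strip())
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return GeneSetCollection.from_sets(sets, background)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column human->mouse symbol mapping TSV.

    Many-to-one (several human symbols to one mouse symbol) is allowed;
    a duplicated human key with conflicting targets is fatal.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(f"{path}:{lineno}: expected two tab-separated symbols")
            human, mouse = fields[0].strip(), fields[1].strip()
            if human in mapping and mapping[human] != mouse:
                raise ParseError(
                    f"{path}:{lineno}: human symbol {human!r} maps to both "
                    f"{mapping[human]!r} and {mouse!r}"
                )
            mapping[human] = mouse
    if not mapping:
        logger.warning("ID mapping %s is empty; all genes will be unmapped", path)
    return mapping


def write_id_mapping(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for human in sorted(mapping):
            fh.write(f"{human}\t{mapping[human]}\n")
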