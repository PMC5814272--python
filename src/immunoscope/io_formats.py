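"""Readers and writers for the tabular/sequence formats the pipeline consumes.

Formats: MAF-like mutation tables (tab-separated, headered, configurable
column mapping), GMT gene sets, gene-by-sample expression TSV, protein
FASTA, HLA genotype TSV and a clinical TSV.  All text I/O is UTF-8 and
gzip is handled transparently by file extension.
"""

from __future__ import annotations

import gzip
import io
import math
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, RecordError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AMINO_ACIDS)

_HLA_ALLELE_RE = re.compile(r"^HLA-([ABC])\*\d{2}:\d{2,3}$")
_PROTEIN_CHANGE_RE = re.compile(r"^p\.([A-Z\*])(\d+)([A-Z\*])$")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

class VariantClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    SILENT = "silent"
    OTHER = "other"


#: Common MAF ``Variant_Classification`` spellings, normalised to the enum.
VARIANT_CLASS_ALIASES: dict[str, VariantClass] = {
    "missense_mutation": VariantClass.MISSENSE,
    "missense": VariantClass.MISSENSE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "nonsense": VariantClass.NONSENSE,
    "nonstop_mutation": VariantClass.OTHER,
    "frame_shift_del": VariantClass.FRAMESHIFT,
    "frame_shift_ins": VariantClass.FRAMESHIFT,
    "frameshift": VariantClass.FRAMESHIFT,
    "splice_site": VariantClass.SPLICE,
    "splice_region": VariantClass.SPLICE,
    "splice": VariantClass.SPLICE,
    "silent": VariantClass.SILENT,
    "synonymous": VariantClass.SILENT,
}

#: Default MAF column mapping (cBioPortal-style headers).
DEFAULT_MAF_COLUMNS: dict[str, str] = {
    "sample_id": "Tumor_Sample_Barcode",
    "hugo_symbol": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref_allele": "Reference_Allele",
    "alt_allele": "Tumor_Seq_Allele2",
    "variant_classification": "Variant_Classification",
    "protein_change": "HGVSp_Short",
    "transcript_id": "Transcript_ID",
}

_OPTIONAL_MAF_FIELDS = {"protein_change", "transcript_id"}


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """Parse an HGVS-short substitution like ``p.G12C`` into (ref, pos, alt)."""
    m = _PROTEIN_CHANGE_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparseable protein change {text!r}")
    return m.group(1), int(m.group(2)), m.group(3)


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call for one sample."""

    sample_id: str
    hugo_symbol: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_classification: VariantClass
    protein_change: str = ""
    transcript_id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"ref_allele == alt_allele ({self.ref_allele!r}) for "
                f"{self.sample_id}/{self.hugo_symbol}"
            )
        if self.variant_classification is VariantClass.MISSENSE:
            ref_aa, _, alt_aa = parse_protein_change(self.protein_change)
            if ref_aa == alt_aa:
                raise ValueError(
                    f"missense protein change {self.protein_change!r} has "
                    "identical reference and alternate residues"
                )

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in "ACGT"
            and self.alt_allele in "ACGT"
        )


def read_maf(path, columns: Mapping[str, str] | None = None) -> list[MutationRecord]:
    """Read a MAF-like tab-separated mutation table.

    Parameters
    ----------
    path
        Tab-separated, headered file.  Lines starting with ``#`` are skipped.
    columns
        Mapping from :class:`MutationRecord` field names to header names;
        defaults to :data:`DEFAULT_MAF_COLUMNS`.  Dialects that lack the
        optional ``protein_change`` / ``transcript_id`` columns may omit them.
    """
    colmap = dict(DEFAULT_MAF_COLUMNS if columns is None else columns)
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for fld, col in colmap.items():
        if col not in df.columns:
            if fld in _OPTIONAL_MAF_FIELDS:
                continue
            raise FormatError(f"{path}: missing mandatory column {col!r} (field {fld})")
    records: list[MutationRecord] = []
    n_silent = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        raw_class = row[colmap["variant_classification"]]
        vclass = VARIANT_CLASS_ALIASES.get(raw_class.strip().lower(), VariantClass.OTHER)
        try:
            pos = int(row[colmap["pos"]])
        except ValueError as exc:
            raise RecordError(f"non-integer position {row[colmap['pos']]!r}", row=i) from exc
        kwargs = dict(
            sample_id=row[colmap["sample_id"]],
            hugo_symbol=row[colmap["hugo_symbol"]],
            chrom=row[colmap["chrom"]],
            pos=pos,
            ref_allele=row[colmap["ref_allele"]],
            alt_allele=row[colmap["alt_allele"]],
            variant_classification=vclass,
        )
        for fld in _OPTIONAL_MAF_FIELDS:
            col = colmap.get(fld)
            if col is not None and col in df.columns:
                kwargs[fld] = row[col]
        try:
            rec = MutationRecord(**kwargs)
        except ValueError as exc:
            raise RecordError(str(exc), row=i) from exc
        if rec.variant_classification is VariantClass.SILENT:
            n_silent += 1
        records.append(rec)
    if n_silent:
        warnings.warn(f"{path}: {n_silent} silent record(s) retained (flagged)")
    return records


def write_maf(records: Iterable[MutationRecord], path,
              columns: Mapping[str, str] | None = None) -> None:
    colmap = dict(DEFAULT_MAF_COLUMNS if columns is None else columns)
    class_names = {
        VariantClass.MISSENSE: "Missense_Mutation",
        VariantClass.NONSENSE: "Nonsense_Mutation",
        VariantClass.FRAMESHIFT: "Frame_Shift_Del",
        VariantClass.SPLICE: "Splice_Site",
        VariantClass.SILENT: "Silent",
        VariantClass.OTHER: "Other",
    }
    rows = []
    for rec in records:
        rows.append({
            colmap["sample_id"]: rec.sample_id,
            colmap["hugo_symbol"]: rec.hugo_symbol,
            colmap["chrom"]: rec.chrom,
            colmap["pos"]: rec.pos,
            colmap["ref_allele"]: rec.ref_allele,
            colmap["alt_allele"]: rec.alt_allele,
            colmap["variant_classification"]: class_names[rec.variant_classification],
            colmap["protein_change"]: rec.protein_change,
            colmap["transcript_id"]: rec.transcript_id,
        })
    df = pd.DataFrame(rows, columns=[colmap[k] for k in DEFAULT_MAF_COLUMNS])
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: ``name TAB description TAB gene [TAB gene ...]``."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >= 3"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            if len(set(genes)) < len(genes):
                warnings.warn(f"{path}:{lineno}: duplicate genes in set {name!r} deduplicated")
            sets.append(GeneSet(name=name, genes=frozenset(genes), description=desc))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with _open_text(path, "wt") as fh:
        for gs in sets:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description or gs.name}\t{genes}\n")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """Genes x samples matrix of linear-scale normalized expression (>= 0).

    The z-score view is always recomputed from the linear values, per gene
    across samples, with sample standard deviation (ddof=1).  A constant
    gene has an all-zero z-score row by definition.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups}")
        arr = values.to_numpy(dtype=float)
        bad = ~np.isfinite(arr)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise FormatError(
                f"non-finite expression value at gene {values.index[g]!r}, "
                f"sample {values.columns[s]!r}"
            )
        neg = arr < 0
        if neg.any():
            g, s = np.argwhere(neg)[0]
            raise FormatError(
                f"negative expression value {arr[g, s]} at gene "
                f"{values.index[g]!r}, sample {values.columns[s]!r}"
            )
        self.values = values.astype(float)
        self._zscores: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def zscores(self) -> pd.DataFrame:
        if self._zscores is None:
            arr = self.values.to_numpy()
            mean = arr.mean(axis=1, keepdims=True)
            if arr.shape[1] > 1:
                sd = arr.std(axis=1, ddof=1, keepdims=True)
            else:
                sd = np.zeros((arr.shape[0], 1))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (arr - mean) / sd
            z[np.broadcast_to(sd == 0, z.shape)] = 0.0
            self._zscores = pd.DataFrame(z, index=self.values.index,
                                         columns=self.values.columns)
        return self._zscores

    def expression_of(self, gene: str, sample: str) -> float:
        """Linear-scale expression, 0.0 for a gene absent from the matrix."""
        if gene not in self.values.index:
            return 0.0
        return float(self.values.at[gene, sample])


def read_expression(path) -> ExpressionMatrix:
    """Read a genes-by-samples TSV (first column gene symbols)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    non_numeric = df.select_dtypes(exclude=[np.number]).columns.tolist()
    if non_numeric:
        raise FormatError(f"{path}: non-numeric expression column(s) {non_numeric}")
    try:
        return ExpressionMatrix(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression(matrix: ExpressionMatrix, path) -> None:
    with _open_text(path, "wt") as fh:
        matrix.values.to_csv(fh, sep="\t", index_label="gene",
                             float_format="%.10g")


# ---------------------------------------------------------------------------
# Protein FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a protein FASTA into ``{identifier: uppercased sequence}``.

    Sequences must use the 20-letter amino-acid alphabet; ``X`` is accepted
    but flagged with a warning.  Duplicate identifiers are an error.
    """
    proteins: dict[str, str] = {}
    n_with_x = 0
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in proteins:
                raise FormatError(f"{path}: duplicate FASTA identifier {rec.id!r}")
            seq = str(rec.seq).upper()
            for i, aa in enumerate(seq, start=1):
                if aa not in _AA_SET and aa != "X":
                    raise FormatError(
                        f"{path}: illegal character {aa!r} at position {i} of {rec.id!r}"
                    )
            if "X" in seq:
                n_with_x += 1
            proteins[rec.id] = seq
    if n_with_x:
        warnings.warn(f"{path}: {n_with_x} sequence(s) contain 'X'")
    return proteins


def write_fasta(proteins: Mapping[str, str], path, width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in proteins.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# HLA genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HlaGenotype:
    """Six class-I alleles for one sample (A, B, C; two each, homozygotes repeat)."""

    sample_id: str
    alleles: tuple[str, ...]

    def __post_init__(self):
        if len(self.alleles) != 6:
            raise ValueError(
                f"{self.sample_id}: expected 6 alleles, got {len(self.alleles)}"
            )
        loci = []
        for a in self.alleles:
            m = _HLA_ALLELE_RE.match(a)
            if not m:
                raise ValueError(f"{self.sample_id}: malformed HLA allele {a!r}")
            loci.append(m.group(1))
        if sorted(loci) != ["A", "A", "B", "B", "C", "C"]:
            raise ValueError(
                f"{self.sample_id}: expected two alleles per locus A/B/C, got {loci}"
            )

    @property
    def distinct_alleles(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.alleles:
            seen.setdefault(a)
        return tuple(seen)


_HLA_COLS = ["A1", "A2", "B1", "B2", "C1", "C2"]


def read_hla(path) -> list[HlaGenotype]:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    missing = [c for c in ["sample_id"] + _HLA_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        try:
            out.append(HlaGenotype(row["sample_id"],
                                   tuple(row[c] for c in _HLA_COLS)))
        except ValueError as exc:
            raise RecordError(str(exc), row=i) from exc
    return out


def write_hla(genotypes: Iterable[HlaGenotype], path) -> None:
    rows = [{"sample_id": g.sample_id, **dict(zip(_HLA_COLS, g.alleles))}
            for g in genotypes]
    with _open_text(path, "wt") as fh:
        pd.DataFrame(rows, columns=["sample_id"] + _HLA_COLS).to_csv(
            fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    os_months: float
    os_event: bool
    smoking_pack_years: float | None = None
    cluster_label: str | None = None
    histology_label: str | None = None
    oncogene_status: str | None = None

    def __post_init__(self):
        if not (self.os_months >= 0) or math.isnan(self.os_months):
            raise ValueError(f"{self.sample_id}: os_months must be >= 0")


_CLINICAL_OPTIONAL = ["smoking_pack_years", "cluster_label",
                      "histology_label", "oncogene_status"]


def read_clinical(path) -> list[ClinicalRecord]:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    for col in ("sample_id", "os_months", "os_event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        extras = {}
        for col in _CLINICAL_OPTIONAL:
            if col in df.columns and not pd.isna(row[col]):
                extras[col] = (float(row[col]) if col == "smoking_pack_years"
                               else str(row[col]))
        try:
            out.append(ClinicalRecord(
                sample_id=str(row["sample_id"]),
                os_months=float(row["os_months"]),
                os_event=bool(int(row["os_event"])),
                **extras,
            ))
        except ValueError as exc:
            raise RecordError(str(exc), row=i) from exc
    return out


def write_clinical(records: Iterable[ClinicalRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "os_months": r.os_months,
            "os_event": int(r.os_event),
            "smoking_pack_years": r.smoking_pack_years,
            "cluster_label": r.cluster_label,
            "histology_label": r.histology_label,
            "oncogene_status": r.oncogene_status,
        })
    df = pd.DataFrame(rows, columns=["sample_id", "os_months", "os_event"]
                      + _CLINICAL_OPTIONAL)
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
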