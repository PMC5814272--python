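"""Candidate mutant-peptide enumeration and neoantigen filtering.

Missense variants are expanded into every k-mer window covering the
mutated residue, paired with the homologous wildtype k-mer, scored
against the sample's six class-I HLA alleles, and filtered with strict
inequalities: mutant IC50 < 500 nM, wildtype IC50 > 500 nM, and positive
linear-scale expression of the mutated gene in that sample.  A variant
is a neoantigen when at least one peptide-allele pair passes; per-sample
load counts neoantigen variants, not passing pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, RecordError, VariantRejectedError
from .io_formats import (ExpressionMatrix, HlaGenotype, MutationRecord,
                         VariantClass, parse_protein_change)


@dataclass(frozen=True)
class ProteinVariant:
    sample_id: str
    gene: str
    transcript_id: str
    position: int  # 1-based residue index
    ref_aa: str
    alt_aa: str

    def __post_init__(self):
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref_aa == alt_aa")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.gene, self.transcript_id,
                self.position, self.ref_aa, self.alt_aa)


@dataclass(frozen=True)
class PeptidePair:
    mutant_peptide: str
    wildtype_peptide: str
    offset: int        # 1-based index of the mutated residue within the peptide
    window_start: int  # 1-based start of the window in the protein

    def __post_init__(self):
        if len(self.mutant_peptide) != len(self.wildtype_peptide):
            raise ValueError("peptide lengths differ")
        diffs = [i for i, (a, b) in enumerate(
            zip(self.mutant_peptide, self.wildtype_peptide), start=1) if a != b]
        if diffs != [self.offset]:
            raise ValueError(
                f"peptides must differ exactly at offset {self.offset}, differ at {diffs}")


@dataclass(frozen=True)
class NeoantigenThresholds:
    k: int = 9
    mutant_ic50_max: float = 500.0   # pass iff mutant IC50 strictly below
    wt_ic50_min: float = 500.0       # pass iff wildtype IC50 strictly above
    expression_min: float = 0.0      # pass iff expression strictly above

    def __post_init__(self):
        if self.k < 8:
            raise ValueError("k must be >= 8")
        if self.mutant_ic50_max <= 0 or self.wt_ic50_min <= 0:
            raise ValueError("IC50 thresholds must be positive")


@dataclass
class NeoantigenCall:
    variant: ProteinVariant
    passing_pairs: list[tuple[PeptidePair, str, float, float]]

    @property
    def is_neoantigen(self) -> bool:
        return bool(self.passing_pairs)


class BindingPredictor(Protocol):
    """Minimal predictor interface: IC50 in nM for a (peptide, allele)."""

    alleles: Sequence[str]

    def predict(self, peptide: str, allele: str) -> float: ...


# ---------------------------------------------------------------------------
# Variant handling
# ---------------------------------------------------------------------------

def apply_variant(protein: str, v: ProteinVariant) -> str:
    """Substitute ``alt_aa`` at the variant position, checking the reference."""
    if v.position > len(protein):
        raise VariantRejectedError(
            f"{v.gene} position {v.position} beyond protein length {len(protein)}")
    if protein[v.position - 1] != v.ref_aa:
        raise VariantRejectedError(
            f"{v.gene} p.{v.ref_aa}{v.position}{v.alt_aa}: reference residue is "
            f"{protein[v.position - 1]!r}, expected {v.ref_aa!r}")
    return protein[: v.position - 1] + v.alt_aa + protein[v.position:]


def variants_from_mutations(muts: Sequence[MutationRecord]) -> list[ProteinVariant]:
    """Missense records with parseable protein changes, as protein variants."""
    out = []
    for rec in muts:
        if rec.variant_classification is not VariantClass.MISSENSE:
            continue
        ref_aa, pos, alt_aa = parse_protein_change(rec.protein_change)
        out.append(ProteinVariant(
            sample_id=rec.sample_id, gene=rec.hugo_symbol,
            transcript_id=rec.transcript_id, position=pos,
            ref_aa=ref_aa, alt_aa=alt_aa))
    return out


def enumerate_peptides(wt_seq: str, mut_seq: str, p: int, k: int = 9
                       ) -> list[PeptidePair]:
    """All k-mer windows of the protein that contain the mutated residue.

    Window starts run from ``max(1, p - k + 1)`` to ``min(p, L - k + 1)``,
    ordered by start; an interior site yields exactly k pairs.  Proteins
    shorter than k yield an empty list with a warning.
    """
    if len(wt_seq) != len(mut_seq):
        raise ValueError("sequences must have equal length")
    L = len(wt_seq)
    if not (1 <= p <= L):
        raise ValueError(f"position {p} outside protein of length {L}")
    if wt_seq[p - 1] == mut_seq[p - 1]:
        raise ValueError("sequences must differ at the mutated position")
    if L < k:
        warnings.warn(f"protein length {L} < peptide length {k}; no windows")
        return []
    pairs = []
    for s in range(max(1, p - k + 1), min(p, L - k + 1) + 1):
        pairs.append(PeptidePair(
            mutant_peptide=mut_seq[s - 1: s - 1 + k],
            wildtype_peptide=wt_seq[s - 1: s - 1 + k],
            offset=p - s + 1,
            window_start=s))
    return pairs


def _clean_pairs(pairs: Sequence[PeptidePair]) -> list[PeptidePair]:
    kept = []
    dropped = 0
    for pair in pairs:
        if any(c in "X*" for c in pair.mutant_peptide + pair.wildtype_peptide):
            dropped += 1
            continue
        kept.append(pair)
    if dropped:
        warnings.warn(f"{dropped} peptide pair(s) containing X or a stop dropped")
    return kept


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_pairs(pairs: Sequence[PeptidePair], hla: HlaGenotype,
                  predictor: BindingPredictor) -> pd.DataFrame:
    """One row per pair x distinct allele with mutant/wildtype IC50.

    Homozygous (duplicate) alleles collapse to a single row; an allele
    the predictor cannot score is skipped with a warning.
    """
    pairs = _clean_pairs(pairs)
    rows = []
    for allele in hla.distinct_alleles:
        try:
            preds = [(predictor.predict(p.mutant_peptide, allele),
                      predictor.predict(p.wildtype_peptide, allele))
                     for p in pairs]
        except Exception as exc:  # predictor failure isolates the allele
            warnings.warn(f"predictor failed for allele {allele}: {exc}; skipped")
            continue
        for pair, (mut_ic50, wt_ic50) in zip(pairs, preds):
            rows.append({"pair": pair, "allele": allele,
                         "mutant_ic50": float(mut_ic50),
                         "wildtype_ic50": float(wt_ic50)})
    return pd.DataFrame(rows, columns=["pair", "allele",
                                       "mutant_ic50", "wildtype_ic50"])


@dataclass
class VariantPrediction:
    """A variant with its peptide-allele prediction table."""

    variant: ProteinVariant
    table: pd.DataFrame  # columns: pair, allele, mutant_ic50, wildtype_ic50


def call_neoantigens(predictions: Sequence[VariantPrediction],
                     expr: ExpressionMatrix,
                     th: NeoantigenThresholds | None = None
                     ) -> tuple[list[NeoantigenCall], pd.Series]:
    """Apply the three strict-inequality filters and count per-sample load.

    A (pair, allele) row passes iff mutant IC50 < ``mutant_ic50_max`` AND
    wildtype IC50 > ``wt_ic50_min`` AND the mutated gene's linear-scale
    expression in that sample > ``expression_min``.  A variant whose gene
    is absent from the matrix is treated as expression 0 (warned).
    """
    th = th or NeoantigenThresholds()
    calls: list[NeoantigenCall] = []
    load: dict[str, int] = {}
    missing_genes: set[str] = set()
    for vp in predictions:
        v = vp.variant
        load.setdefault(v.sample_id, 0)
        if v.gene not in expr.gene_ids:
            missing_genes.add(v.gene)
        expression = expr.expression_of(v.gene, v.sample_id) \
            if v.sample_id in expr.sample_ids else 0.0
        passing = []
        if expression > th.expression_min and len(vp.table):
            ok = ((vp.table["mutant_ic50"] < th.mutant_ic50_max)
                  & (vp.table["wildtype_ic50"] > th.wt_ic50_min))
            for row in vp.table[ok].itertuples(index=False):
                passing.append((row.pair, row.allele,
                                row.mutant_ic50, row.wildtype_ic50))
        call = NeoantigenCall(variant=v, passing_pairs=passing)
        calls.append(call)
        if call.is_neoantigen:
            load[v.sample_id] += 1
    if missing_genes:
        warnings.warn(
            f"{len(missing_genes)} mutated gene(s) absent from the expression "
            "matrix treated as expression 0")
    series = pd.Series(load, dtype=int).sort_index()
    series.index.name = "sample_id"
    series.name = "neoantigen_load"
    return calls, series


def predict_cohort(muts: Sequence[MutationRecord], proteins: Mapping[str, str],
                   hla_map: Mapping[str, HlaGenotype],
                   predictor: BindingPredictor, expr: ExpressionMatrix,
                   th: NeoantigenThresholds | None = None,
                   roster: Sequence[str] | None = None
                   ) -> tuple[list[NeoantigenCall], pd.Series]:
    """End-to-end neoantigen calling for a cohort of missense mutations.

    Variants whose transcript is missing, whose sample has no HLA
    genotype, or whose reference residue mismatches the protein are
    skipped with a warning.  Samples in ``roster`` always appear in the
    load series (0 when nothing passes).
    """
    th = th or NeoantigenThresholds()
    predictions: list[VariantPrediction] = []
    n_skipped = 0
    for v in variants_from_mutations(muts):
        protein = proteins.get(v.transcript_id)
        hla = hla_map.get(v.sample_id)
        if protein is None or hla is None:
            n_skipped += 1
            continue
        try:
            mut_seq = apply_variant(protein, v)
        except VariantRejectedError as exc:
            warnings.warn(str(exc))
            n_skipped += 1
            continue
        pairs = enumerate_peptides(protein, mut_seq, v.position, th.k)
        predictions.append(VariantPrediction(v, predict_pairs(pairs, hla, predictor)))
    if n_skipped:
        warnings.warn(f"{n_skipped} variant(s) skipped (missing transcript/HLA "
                      "or reference mismatch)")
    calls, load = call_neoantigens(predictions, expr, th)
    if roster is not None:
        load = load.reindex(sorted(set(roster) | set(load.index)),
                            fill_value=0).astype(int)
        load.index.name = "sample_id"
        load.name = "neoantigen_load"
    return calls, load


# ---------------------------------------------------------------------------
# External predictor output
# ---------------------------------------------------------------------------

#: Registered tabular dialects for external predictor output:
#: field -> column-name mapping.
PREDICTOR_DIALECTS: dict[str, dict[str, str]] = {
    "generic": {"peptide": "peptide", "allele": "allele", "ic50": "ic50"},
    "netmhcpan": {"peptide": "Peptide", "allele": "HLA", "ic50": "Aff(nM)"},
}


def parse_predictor_output(path, dialect: str = "generic") -> pd.DataFrame:
    """Parse an external predictor's tab-separated affinity table.

    Returns a frame with columns ``peptide``, ``allele``, ``ic50``.
    """
    if dialect not in PREDICTOR_DIALECTS:
        raise FormatError(f"unknown predictor dialect {dialect!r}; "
                          f"registered: {sorted(PREDICTOR_DIALECTS)}")
    colmap = PREDICTOR_DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = pd.DataFrame({
        "peptide": df[colmap["peptide"]].str.upper(),
        "allele": df[colmap["allele"]],
    })
    ic50 = pd.to_numeric(df[colmap["ic50"]], errors="coerce")
    if ic50.isna().any():
        row = int(ic50.index[ic50.isna()][0]) + 2  # 1-based incl. header
        raise RecordError(
            f"non-numeric affinity {df[colmap['ic50']].iloc[row - 2]!r}", row=row)
    out["ic50"] = ic50.astype(float)
    return out


def attach_predictions(pairs: Sequence[PeptidePair], table: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join external predictions back to peptide pairs by exact peptide match.

    Returns ``(joined, unmatched)`` where ``joined`` has one row per
    (pair, allele) with mutant and wildtype IC50 and ``unmatched`` holds
    prediction rows whose peptide matches no pair.
    """
    by_mut: dict[str, list[PeptidePair]] = {}
    peptides: set[str] = set()
    for pair in pairs:
        by_mut.setdefault(pair.mutant_peptide, []).append(pair)
        peptides.add(pair.mutant_peptide)
        peptides.add(pair.wildtype_peptide)
    unmatched = table[~table["peptide"].isin(peptides)]
    lookup: dict[tuple[str, str], float] = {
        (row.peptide, row.allele): row.ic50
        for row in table.itertuples(index=False)}
    rows = []
    for pair in pairs:
        for allele in sorted({a for (_, a) in lookup}):
            mut = lookup.get((pair.mutant_peptide, allele))
            wt = lookup.get((pair.wildtype_peptide, allele))
            if mut is None or wt is None:
                continue
            rows.append({"pair": pair, "allele": allele,
                         "mutant_ic50": mut, "wildtype_ic50": wt})
    joined = pd.DataFrame(rows, columns=["pair", "allele",
                                         "mutant_ic50", "wildtype_ic50"])
    if len(unmatched):
        warnings.warn(f"{len(unmatched)} prediction row(s) matched no peptide pair")
    return joined, unmatched.reset_index(drop=True)
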