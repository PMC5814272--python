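"""Per-sample mutational burden, substitution spectrum, DNA-repair pathway
classification and median/quartile group splits."""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import GeneSet, MutationRecord, VariantClass

#: Default homologous-recombination pathway gene list.
HR_GENES = frozenset({
    "ATR", "ATM", "CHEK1", "CHEK2", "BRCA1", "BRCA2", "BAP1", "BARD1",
    "FANCD2", "FANCE", "FANCC", "FANCA", "RAD50", "RAD51", "PALB2",
})

#: Default mismatch-repair pathway gene list.
MMR_GENES = frozenset({
    "MLH1", "MLH3", "MSH2", "MSH3", "MSH4", "MSH5", "MSH6", "PMS1", "PMS2",
    "PMS2L3", "PCNA", "EXO1", "POLD1", "RFC1", "RFC2", "RFC3", "RFC4", "RFC5",
})

POLE_GENES = frozenset({"POLE"})

#: Variant classes counted as nonsynonymous burden by default.
DEFAULT_COUNTED_CLASSES = frozenset({
    VariantClass.MISSENSE, VariantClass.NONSENSE,
    VariantClass.FRAMESHIFT, VariantClass.SPLICE,
})

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class RepairGeneSets:
    hr: GeneSet = field(default_factory=lambda: GeneSet("HR", HR_GENES))
    mmr: GeneSet = field(default_factory=lambda: GeneSet("MMR", MMR_GENES))
    pole: GeneSet = field(default_factory=lambda: GeneSet("POLE", POLE_GENES))

    @property
    def all_genes(self) -> frozenset[str]:
        return self.hr.genes | self.mmr.genes | self.pole.genes


@dataclass(frozen=True)
class RepairStatus:
    sample_id: str
    hr_mut: bool
    mmr_mut: bool
    pole_mut: bool
    n_hr_genes: int
    n_mmr_genes: int

    def __post_init__(self):
        if self.hr_mut != (self.n_hr_genes >= 1):
            raise ValueError("hr_mut inconsistent with n_hr_genes")
        if self.mmr_mut != (self.n_mmr_genes >= 1):
            raise ValueError("mmr_mut inconsistent with n_mmr_genes")


@dataclass
class BurdenTable:
    counts: pd.Series  # sample_id -> nonsynonymous mutation count

    def __post_init__(self):
        if (self.counts < 0).any():
            raise ValueError("burden counts must be >= 0")
        self.counts = self.counts.astype(int)

    @property
    def median(self) -> float:
        return float(self.counts.median())

    @property
    def quartiles(self) -> tuple[float, float, float]:
        q = np.percentile(self.counts.to_numpy(), [25, 50, 75])
        return tuple(float(v) for v in q)


def mutation_burden(muts: Sequence[MutationRecord],
                    counted_classes: Iterable[VariantClass] = DEFAULT_COUNTED_CLASSES,
                    roster: Sequence[str] | None = None) -> BurdenTable:
    """Per-sample count of mutations whose class is counted.

    Samples listed in ``roster`` but absent from the records get count 0.
    """
    counted = frozenset(counted_classes)
    counts: dict[str, int] = {s: 0 for s in (roster or [])}
    for rec in muts:
        counts.setdefault(rec.sample_id, 0)
        if rec.variant_classification in counted:
            counts[rec.sample_id] += 1
    series = pd.Series(counts, dtype=int).sort_index()
    series.index.name = "sample_id"
    return BurdenTable(series)


def classify_repair(muts: Sequence[MutationRecord],
                    sets: RepairGeneSets | None = None,
                    counted_classes: Iterable[VariantClass] = DEFAULT_COUNTED_CLASSES,
                    roster: Sequence[str] | None = None) -> list[RepairStatus]:
    """Flag each sample's HR/MMR/POLE pathway mutation status.

    A sample is pathway-mutant when it carries >= 1 counted (by default
    nonsynonymous) mutation in a pathway gene; no pathogenicity scoring.
    """
    sets = sets or RepairGeneSets()
    counted = frozenset(counted_classes)
    per_sample: dict[str, dict[str, set[str]]] = {
        s: {"hr": set(), "mmr": set(), "pole": set()} for s in (roster or [])
    }
    for rec in muts:
        bucket = per_sample.setdefault(
            rec.sample_id, {"hr": set(), "mmr": set(), "pole": set()})
        if rec.variant_classification not in counted:
            continue
        if rec.hugo_symbol in sets.hr:
            bucket["hr"].add(rec.hugo_symbol)
        if rec.hugo_symbol in sets.mmr:
            bucket["mmr"].add(rec.hugo_symbol)
        if rec.hugo_symbol in sets.pole:
            bucket["pole"].add(rec.hugo_symbol)
    out = []
    for sample in sorted(per_sample):
        b = per_sample[sample]
        out.append(RepairStatus(
            sample_id=sample,
            hr_mut=bool(b["hr"]), mmr_mut=bool(b["mmr"]), pole_mut=bool(b["pole"]),
            n_hr_genes=len(b["hr"]), n_mmr_genes=len(b["mmr"]),
        ))
    return out


def substitution_spectrum(muts: Sequence[MutationRecord]) -> pd.DataFrame:
    """Per-sample fractions of the six strand-collapsed substitution classes.

    Purine-reference SNVs are complemented onto the pyrimidine-reference
    classes (G>T counts as C>A and so on).  Samples without any SNV get a
    NaN row (flagged undefined); non-SNV records are ignored and their
    count reported via a warning.
    """
    counts: dict[str, np.ndarray] = {}
    n_non_snv = 0
    class_index = {c: i for i, c in enumerate(SUBSTITUTION_CLASSES)}
    for rec in muts:
        counts.setdefault(rec.sample_id, np.zeros(6))
        if not rec.is_snv:
            n_non_snv += 1
            continue
        ref, alt = rec.ref_allele, rec.alt_allele
        if ref in "AG":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[rec.sample_id][class_index[f"{ref}>{alt}"]] += 1
    if n_non_snv:
        warnings.warn(f"{n_non_snv} non-SNV record(s) ignored in spectrum")
    rows = {}
    for sample in sorted(counts):
        c = counts[sample]
        total = c.sum()
        rows[sample] = c / total if total > 0 else np.full(6, np.nan)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=list(SUBSTITUTION_CLASSES))
    df.index.name = "sample_id"
    return df


def median_split(burden: BurdenTable) -> pd.Series:
    """Label samples high/low around the cohort median burden.

    high iff count > median; ties at the median go to low.
    """
    counts = burden.counts
    if counts.size < 2:
        raise ValueError("median split needs >= 2 samples")
    med = counts.median()
    if counts.nunique() == 1:
        warnings.warn("all burden counts identical; every sample labeled low")
    labels = pd.Series(np.where(counts > med, "high", "low"),
                       index=counts.index, name="burden_group")
    return labels


def quartile_split(values: pd.Series) -> pd.Series:
    """Label samples top_quartile/rest around the linear-interpolated P75.

    top_quartile iff value > P75; ties at the threshold are excluded from
    the top.  With all values equal the top is empty (warned).
    """
    if values.size < 4:
        raise ValueError("quartile split needs >= 4 samples")
    p75 = float(np.percentile(values.to_numpy(dtype=float), 75))
    labels = pd.Series(np.where(values > p75, "top_quartile", "rest"),
                       index=values.index, name="quartile_group")
    if (labels == "top_quartile").sum() == 0:
        warnings.warn("empty top quartile (all values tie at the threshold)")
    return labels


def gene_panel_mutation_rates(muts: Sequence[MutationRecord],
                              panel_genes: Iterable[str],
                              groups: Mapping[str, str],
                              group_a: str, group_b: str,
                              counted_classes: Iterable[VariantClass]
                              = DEFAULT_COUNTED_CLASSES) -> pd.DataFrame:
    """Per-gene mutated-sample fractions in two groups + two-proportion z."""
    from .stats import significance_stars, two_proportion_z

    counted = frozenset(counted_classes)
    samples_a = [s for s, g in groups.items() if g == group_a]
    samples_b = [s for s, g in groups.items() if g == group_b]
    if not samples_a or not samples_b:
        raise ValueError("both groups must be nonempty")
    mutated: dict[str, set[str]] = {}
    for rec in muts:
        if rec.variant_classification in counted:
            mutated.setdefault(rec.hugo_symbol, set()).add(rec.sample_id)
    rows = []
    for gene in panel_genes:
        carriers = mutated.get(gene, set())
        x1 = len(carriers & set(samples_a))
        x2 = len(carriers & set(samples_b))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z, p = two_proportion_z(x1, len(samples_a), x2, len(samples_b))
        rows.append({"gene": gene,
                     "frac_a": x1 / len(samples_a), "frac_b": x2 / len(samples_b),
                     "n_a": len(samples_a), "n_b": len(samples_b),
                     "z": z, "p": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows, columns=["gene", "frac_a", "frac_b", "n_a", "n_b",
                                       "z", "p", "stars"])


def oncogene_positive(muts: Sequence[MutationRecord],
                      onco_cfg: Sequence[tuple[str, str]],
                      roster: Sequence[str] | None = None) -> pd.Series:
    """Per-sample oncogene positivity from (gene, pattern) rules.

    A pattern is either a set of variant-class names (comma separated,
    e.g. ``"missense,nonsense"``) or a protein-change glob such as
    ``"p.G12*"``.  A sample is positive when any mutation matches a rule.
    """
    if not onco_cfg:
        raise ConfigError("oncogene configuration must not be empty")
    class_names = {c.value for c in VariantClass}
    rules = []
    for gene, pattern in onco_cfg:
        if not gene or not pattern:
            raise ConfigError(f"malformed oncogene rule ({gene!r}, {pattern!r})")
        if pattern.startswith("p."):
            rules.append((gene, "protein", pattern))
        else:
            classes = {p.strip().lower() for p in pattern.split(",")}
            if not classes <= class_names:
                raise ConfigError(f"unknown variant class in pattern {pattern!r}")
            rules.append((gene, "class", classes))
    status: dict[str, bool] = {s: False for s in (roster or [])}
    for rec in muts:
        status.setdefault(rec.sample_id, False)
        for gene, kind, spec in rules:
            if rec.hugo_symbol != gene:
                continue
            if kind == "protein":
                if rec.protein_change and fnmatch.fnmatch(rec.protein_change, spec):
                    status[rec.sample_id] = True
            else:
                if rec.variant_classification.value in spec:
                    status[rec.sample_id] = True
    out = pd.Series(status, dtype=bool).sort_index()
    out.index.name = "sample_id"
    out.name = "oncogene_positive"
    return out


def repair_status_frame(statuses: Sequence[RepairStatus]) -> pd.DataFrame:
    df = pd.DataFrame([s.__dict__ for s in statuses]).set_index("sample_id")
    return df
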