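"""Synthetic cohort generation with planted ground truth.

Emits exactly the formats the readers consume (MAF, expression TSV,
protein FASTA, panel GMT + T-subtype TSV, HLA TSV, clinical TSV) with a
known statistical structure: repair-mutant samples draw elevated Poisson
mutation counts, truly infiltrated samples get a log-expression shift on
their cell type's metagene set, designated immune-response genes couple
linearly to the sample's true neoantigen load, and survival hazard drops
for the top-quartile neoantigen group.  Everything is reproducible from
the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .io_formats import (AMINO_ACIDS, ClinicalRecord, ExpressionMatrix,
                         GeneSet, HlaGenotype, MutationRecord, VariantClass,
                         parse_protein_change, write_clinical,
                         write_expression, write_fasta, write_gmt, write_hla,
                         write_maf)
from .phenotype import MetagenePanel
from .repair import (HR_GENES, MMR_GENES, POLE_GENES, SUBSTITUTION_CLASSES,
                     quartile_split)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Output file names shared with the pipeline.
COHORT_FILES = {
    "maf": "mutations.maf.tsv",
    "expression": "expression.tsv",
    "fasta": "proteins.fasta",
    "panel": "panel.gmt",
    "tcell": "tcell_subtypes.tsv",
    "hla": "hla.tsv",
    "clinical": "clinical.tsv",
}


# ---------------------------------------------------------------------------
# Toy binding predictor
# ---------------------------------------------------------------------------

class ToyBindingPredictor:
    """Deterministic position-weight-matrix stand-in for an MHC predictor.

    IC50(peptide, allele) = exp(intercept + sum_i W_allele[i, aa_i]);
    the per-allele weight tables ship with the package, together with one
    guaranteed strong (< 500 nM) and one weak (> 500 nM) fixture peptide
    per allele.
    """

    def __init__(self, table_path=None):
        if table_path is None:
            text = resources.files("immunoscope").joinpath(
                "data/toy_predictor.json").read_text(encoding="utf-8")
        else:
            text = Path(table_path).read_text(encoding="utf-8")
        doc = json.loads(text)
        self.alphabet: str = doc["alphabet"]
        self.k: int = int(doc["peptide_length"])
        self.intercept: float = float(doc["log_ic50_intercept"])
        self._aa_index = {aa: i for i, aa in enumerate(self.alphabet)}
        self.weights: dict[str, np.ndarray] = {
            a: np.asarray(t["weights"], dtype=float)
            for a, t in doc["alleles"].items()}
        self.fixture_peptides: dict[str, tuple[str, str]] = {
            a: (t["strong_peptide"], t["weak_peptide"])
            for a, t in doc["alleles"].items()}

    @property
    def alleles(self) -> list[str]:
        return list(self.weights)

    def _encode(self, peptide: str) -> np.ndarray:
        if len(peptide) != self.k:
            raise DataError(f"peptide must have length {self.k}, "
                            f"got {len(peptide)} ({peptide!r})")
        try:
            return np.array([self._aa_index[aa] for aa in peptide])
        except KeyError as exc:
            raise DataError(f"illegal residue {exc.args[0]!r} in {peptide!r}") from exc

    def score(self, peptide: str, allele: str) -> float:
        if allele not in self.weights:
            raise DataError(f"unknown allele {allele!r}")
        idx = self._encode(peptide)
        return float(self.weights[allele][np.arange(self.k), idx].sum())

    def predict(self, peptide: str, allele: str) -> float:
        """IC50 in nM; strictly positive, identical input -> identical output."""
        return float(np.exp(self.intercept + self.score(peptide, allele)))

    def predict_many(self, peptides: Sequence[str], alleles: Sequence[str]
                     ) -> np.ndarray:
        """(len(peptides), len(alleles)) array of IC50 values."""
        enc = np.stack([self._encode(p) for p in peptides]) if peptides else \
            np.empty((0, self.k), dtype=int)
        out = np.empty((len(peptides), len(alleles)))
        pos = np.arange(self.k)
        for j, allele in enumerate(alleles):
            if allele not in self.weights:
                raise DataError(f"unknown allele {allele!r}")
            w = self.weights[allele]
            out[:, j] = np.exp(self.intercept + w[pos, enc].sum(axis=1))
        return out


_DEFAULT_PREDICTOR: ToyBindingPredictor | None = None


def default_predictor() -> ToyBindingPredictor:
    global _DEFAULT_PREDICTOR
    if _DEFAULT_PREDICTOR is None:
        _DEFAULT_PREDICTOR = ToyBindingPredictor()
    return _DEFAULT_PREDICTOR


def toy_binding_predictor(peptide: str, allele: str) -> float:
    """IC50 in nM from the packaged toy position-weight tables."""
    return default_predictor().predict(peptide, allele)


# ---------------------------------------------------------------------------
# Panel and config
# ---------------------------------------------------------------------------

def synthetic_panel(n_cell_types: int = 10, genes_per_set: int = 20,
                    n_tcell: int = 4) -> MetagenePanel:
    """A stand-in metagene panel with disjoint per-cell-type gene sets."""
    if not (0 <= n_tcell <= n_cell_types):
        raise ConfigError("n_tcell must be between 0 and n_cell_types")
    sets = []
    tcells = []
    for i in range(n_cell_types):
        if i < n_tcell:
            name = f"Tcell_{i + 1:02d}"
            tcells.append(name)
        else:
            name = f"Innate_{i - n_tcell + 1:02d}"
        genes = frozenset(f"{name}_g{j + 1:03d}" for j in range(genes_per_set))
        sets.append(GeneSet(name, genes))
    return MetagenePanel.from_gene_sets(sets, tcell_subtypes=tcells)


#: Immune-response genes coupled positively to true neoantigen load.
DEFAULT_IMMUNE_GENES = (
    "IFNG", "GZMB", "FASLG", "PDCD1", "CD274", "LAG3", "TAP2", "CCR1",
    "LTBR", "TNFRSF25", "IL12RB2", "IL17RA", "IL21", "NOS2", "IL23A",
)

#: Genes coupled negatively to load (immunosuppressive markers).
DEFAULT_SUPPRESSED_GENES = (
    "SOCS2", "CHIA", "CHI3L1", "CHI3L2", "KLF4", "TSLP", "IL33", "IL7", "EDA2R",
)

DEFAULT_HLA_POOL = (
    "HLA-A*01:01", "HLA-A*02:01", "HLA-B*07:02",
    "HLA-B*08:01", "HLA-C*07:01", "HLA-C*07:02",
)


@dataclass
class CohortConfig:
    n_samples: int = 60
    frac_hr_mut: float = 0.15
    frac_mmr_mut: float = 0.10
    frac_pole_mut: float = 0.05
    lambda0: float = 5.0          # baseline mean nonsynonymous count
    rho: float = 3.0              # repair-mutant burden multiplier
    n_proteins: int = 60
    protein_len_range: tuple[int, int] = (60, 120)
    panel: MetagenePanel = field(default_factory=synthetic_panel)
    frac_infiltrated: float = 0.30
    coinfiltrated_pairs: tuple[tuple[str, str], ...] = ()
    delta: float = 2.0            # infiltration log-expression shift
    sigma: float = 1.0            # log-expression noise SD
    alpha: float = 5.0            # immune-gene expression intercept
    beta: float = 1.0             # immune-gene slope on neoantigen load
    immune_noise_sd: float = 1.0
    gamma: float = 0.7            # log-hazard decrement for neoantigen-high
    baseline_hazard: float = 0.02
    followup_months: float = 120.0
    lambda_silent: float = 0.5
    frac_oncogene: float = 0.25
    spectrum_probs: tuple[float, ...] = (1 / 6,) * 6
    class_probs: Mapping[str, float] = field(default_factory=lambda: {
        "missense": 0.85, "nonsense": 0.05, "frameshift": 0.05, "splice": 0.05})
    immune_genes: tuple[str, ...] = DEFAULT_IMMUNE_GENES
    suppressed_genes: tuple[str, ...] = DEFAULT_SUPPRESSED_GENES
    n_background_genes: int = 40
    hla_pool: tuple[str, ...] = DEFAULT_HLA_POOL
    seed: int = 0

    def validate(self) -> None:
        fracs = {"frac_hr_mut": self.frac_hr_mut, "frac_mmr_mut": self.frac_mmr_mut,
                 "frac_pole_mut": self.frac_pole_mut,
                 "frac_infiltrated": self.frac_infiltrated,
                 "frac_oncogene": self.frac_oncogene}
        for name, value in fracs.items():
            if not (0 <= value <= 1):
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.lambda0 <= 0:
            raise ConfigError("lambda0 must be > 0")
        if self.rho < 1:
            raise ConfigError("rho must be >= 1")
        if self.sigma <= 0:
            raise ConfigError("sigma must be > 0")
        lo, hi = self.protein_len_range
        if not (20 <= lo <= hi):
            raise ConfigError("protein_len_range must satisfy 20 <= lo <= hi")
        if abs(sum(self.spectrum_probs) - 1) > 1e-9 or len(self.spectrum_probs) != 6:
            raise ConfigError("spectrum_probs must be 6 probabilities summing to 1")
        if abs(sum(self.class_probs.values()) - 1) > 1e-9:
            raise ConfigError("class_probs must sum to 1")


# ---------------------------------------------------------------------------
# Cohort containers
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    sample_ids: list[str]
    mutations: list[MutationRecord]
    expression: ExpressionMatrix
    proteins: dict[str, str]
    gene_to_transcript: dict[str, str]
    hla: list[HlaGenotype]
    clinical: list[ClinicalRecord]
    panel: MetagenePanel

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {k: outdir / v for k, v in COHORT_FILES.items()}
        write_maf(self.mutations, paths["maf"])
        write_expression(self.expression, paths["expression"])
        write_fasta(self.proteins, paths["fasta"])
        write_gmt([self.panel.sets[ct] for ct in self.panel.cell_types],
                  paths["panel"])
        pd.DataFrame({
            "cell_type": list(self.panel.cell_types),
            "is_tcell_subtype": [int(ct in self.panel.tcell_subtypes)
                                 for ct in self.panel.cell_types],
        }).to_csv(paths["tcell"], sep="\t", index=False)
        write_hla(self.hla, paths["hla"])
        write_clinical(self.clinical, paths["clinical"])
        return paths


@dataclass
class GroundTruth:
    repair: pd.DataFrame            # sample x {hr_mut, mmr_mut, pole_mut}
    infiltration: pd.DataFrame      # sample x cell type booleans
    neoantigen_keys: dict[str, list[tuple]]  # sample -> true neoantigen variants
    neoantigen_load: pd.Series
    survival_group: pd.Series       # top_quartile / rest
    oncogene: pd.Series

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.repair.astype(int).to_csv(outdir / "truth_repair.tsv", sep="\t")
        self.infiltration.astype(int).to_csv(
            outdir / "truth_infiltration.tsv", sep="\t")
        pd.DataFrame({
            "neoantigen_load": self.neoantigen_load,
            "survival_group": self.survival_group,
            "oncogene_positive": self.oncogene.astype(int),
        }).to_csv(outdir / "truth_samples.tsv", sep="\t", index_label="sample_id")
        with open(outdir / "truth_neoantigens.json", "w", encoding="utf-8") as fh:
            json.dump({s: [list(k) for k in keys]
                       for s, keys in self.neoantigen_keys.items()}, fh, indent=1)

    def validate(self, cohort: Cohort) -> None:
        """Internal consistency: flags match the emitted mutation table."""
        pathway_genes = {"hr_mut": HR_GENES, "mmr_mut": MMR_GENES,
                         "pole_mut": POLE_GENES}
        mutated: dict[str, set[str]] = {s: set() for s in cohort.sample_ids}
        for rec in cohort.mutations:
            if rec.variant_classification is not VariantClass.SILENT:
                mutated[rec.sample_id].add(rec.hugo_symbol)
        for flag, genes in pathway_genes.items():
            for sample in cohort.sample_ids:
                has = bool(mutated[sample] & genes)
                if has != bool(self.repair.at[sample, flag]):
                    raise DataError(
                        f"ground truth {flag} inconsistent for {sample}")
        if not self.neoantigen_load.index.equals(self.survival_group.index):
            raise DataError("load and survival group indexes differ")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _draw_snv_alleles(rng: np.random.Generator,
                      spectrum_probs: Sequence[float]) -> tuple[str, str]:
    cls = SUBSTITUTION_CLASSES[rng.choice(6, p=list(spectrum_probs))]
    ref, alt = cls.split(">")
    if rng.random() < 0.5:  # place on the purine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt


def _true_neoantigen(variant_peptides: list[tuple[str, str]],
                     alleles: Sequence[str],
                     predictor: ToyBindingPredictor) -> bool:
    """Independent inline check: any window x allele with mut < 500 < wt.

    (Gene expression is guaranteed positive for every protein gene, so the
    expression filter is always satisfied here.)
    """
    for mut_pep, wt_pep in variant_peptides:
        for allele in alleles:
            if (predictor.predict(mut_pep, allele) < 500.0
                    and predictor.predict(wt_pep, allele) > 500.0):
                return True
    return False


def generate_cohort(config: CohortConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a full synthetic cohort plus its planted ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    predictor = default_predictor()
    n = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]

    # --- repair / oncogene assignment -------------------------------------
    def pick(frac: float) -> set[str]:
        k = int(round(frac * n))
        return set(rng.choice(samples, size=k, replace=False)) if k else set()

    hr_samples = pick(config.frac_hr_mut)
    mmr_samples = pick(config.frac_mmr_mut)
    pole_samples = pick(config.frac_pole_mut)
    onco_samples = pick(config.frac_oncogene)
    repair = pd.DataFrame({
        "hr_mut": [s in hr_samples for s in samples],
        "mmr_mut": [s in mmr_samples for s in samples],
        "pole_mut": [s in pole_samples for s in samples],
    }, index=pd.Index(samples, name="sample_id"))

    # --- proteins ----------------------------------------------------------
    special = sorted(HR_GENES) + sorted(MMR_GENES) + sorted(POLE_GENES) + ["KRAS"]
    n_extra = max(config.n_proteins - len(special), 1)
    genes = special + [f"GENE{i + 1:04d}" for i in range(n_extra)]
    lo, hi = config.protein_len_range
    proteins: dict[str, str] = {}
    gene_to_transcript: dict[str, str] = {}
    for gene in genes:
        length = int(rng.integers(lo, hi + 1))
        seq = _random_protein(rng, length)
        if gene == "KRAS":  # oncogene hotspot residue
            seq = seq[:11] + "G" + seq[12:]
        tid = f"T_{gene}"
        proteins[tid] = seq
        gene_to_transcript[gene] = tid
    random_pool = [g for g in genes if g not in set(special)]

    # --- HLA ---------------------------------------------------------------
    pool_by_locus = {loc: [a for a in config.hla_pool if a.startswith(f"HLA-{loc}")]
                     for loc in "ABC"}
    for loc, alleles in pool_by_locus.items():
        if not alleles:
            raise ConfigError(f"hla_pool has no HLA-{loc} allele")
    hla_list = []
    hla_map: dict[str, HlaGenotype] = {}
    for s in samples:
        alleles = []
        for loc in "ABC":
            alleles.extend(rng.choice(pool_by_locus[loc], size=2, replace=True))
        g = HlaGenotype(s, tuple(alleles))
        hla_list.append(g)
        hla_map[s] = g

    # --- mutations ---------------------------------------------------------
    class_names = list(config.class_probs)
    class_p = [config.class_probs[c] for c in class_names]
    class_enum = {"missense": VariantClass.MISSENSE,
                  "nonsense": VariantClass.NONSENSE,
                  "frameshift": VariantClass.FRAMESHIFT,
                  "splice": VariantClass.SPLICE}
    mutations: list[MutationRecord] = []
    neo_keys: dict[str, list[tuple]] = {s: [] for s in samples}

    def make_mutation(sample: str, gene: str, vclass: VariantClass,
                      fixed_pos: int | None = None,
                      fixed_alt: str | None = None) -> MutationRecord:
        tid = gene_to_transcript[gene]
        seq = proteins[tid]
        if fixed_pos is None:
            pos = int(rng.integers(2, len(seq)))  # interior: 2 .. L-1
        else:
            pos = fixed_pos
        ref_aa = seq[pos - 1]
        if vclass is VariantClass.MISSENSE:
            if fixed_alt is not None:
                alt_aa = fixed_alt
            else:
                choices = [aa for aa in AMINO_ACIDS if aa != ref_aa]
                alt_aa = str(rng.choice(choices))
            pchange = f"p.{ref_aa}{pos}{alt_aa}"
        elif vclass is VariantClass.SILENT:
            pchange = f"p.{ref_aa}{pos}{ref_aa}"
        else:
            pchange = ""
        ref_nt, alt_nt = _draw_snv_alleles(rng, config.spectrum_probs)
        if vclass is VariantClass.FRAMESHIFT:  # 1-bp deletion, not an SNV
            ref_nt, alt_nt = ref_nt + alt_nt, ref_nt
        return MutationRecord(
            sample_id=sample, hugo_symbol=gene,
            chrom=str(int(rng.integers(1, 23))),
            pos=int(rng.integers(1, 100_000_000)),
            ref_allele=ref_nt, alt_allele=alt_nt,
            variant_classification=vclass,
            protein_change=pchange, transcript_id=tid)

    for s in samples:
        is_repair_mut = s in hr_samples or s in mmr_samples or s in pole_samples
        lam = config.rho * config.lambda0 if is_repair_mut else config.lambda0
        forced: list[tuple[str, int | None, str | None]] = []
        if s in hr_samples:
            forced.append((str(rng.choice(sorted(HR_GENES))), None, None))
        if s in mmr_samples:
            forced.append((str(rng.choice(sorted(MMR_GENES))), None, None))
        if s in pole_samples:
            forced.append(("POLE", None, None))
        if s in onco_samples:
            forced.append(("KRAS", 12, str(rng.choice(["C", "D", "V"]))))
        n_nonsyn = max(int(rng.poisson(lam)), len(forced))
        for j in range(n_nonsyn):
            if j < len(forced):
                gene, fpos, falt = forced[j]
                mutations.append(make_mutation(s, gene, VariantClass.MISSENSE,
                                               fixed_pos=fpos, fixed_alt=falt))
            else:
                gene = str(rng.choice(random_pool))
                vclass = class_enum[class_names[rng.choice(len(class_names),
                                                           p=class_p)]]
                mutations.append(make_mutation(s, gene, vclass))
        for _ in range(int(rng.poisson(config.lambda_silent))):
            gene = str(rng.choice(random_pool))
            mutations.append(make_mutation(s, gene, VariantClass.SILENT))

    # --- true neoantigens (inline enumeration, independent of the caller) --
    k = predictor.k
    for rec in mutations:
        if rec.variant_classification is not VariantClass.MISSENSE:
            continue
        seq = proteins[rec.transcript_id]
        _, pos, alt_aa = parse_protein_change(rec.protein_change)
        mut_seq = seq[: pos - 1] + alt_aa + seq[pos:]
        if len(seq) < k:
            continue
        windows = [(mut_seq[st - 1: st - 1 + k], seq[st - 1: st - 1 + k])
                   for st in range(max(1, pos - k + 1),
                                   min(pos, len(seq) - k + 1) + 1)]
        alleles = hla_map[rec.sample_id].distinct_alleles
        if _true_neoantigen(windows, alleles, predictor):
            key = (rec.sample_id, rec.hugo_symbol, rec.transcript_id,
                   pos, seq[pos - 1], alt_aa)
            if key not in neo_keys[rec.sample_id]:
                neo_keys[rec.sample_id].append(key)
    load = pd.Series({s: len(v) for s, v in neo_keys.items()}, dtype=int)
    load.index.name = "sample_id"
    load.name = "neoantigen_load"

    # --- infiltration truth ------------------------------------------------
    panel = config.panel
    infil = pd.DataFrame(False, index=pd.Index(samples, name="sample_id"),
                         columns=list(panel.cell_types))
    for ct in panel.cell_types:
        k_inf = int(round(config.frac_infiltrated * n))
        if k_inf:
            chosen = rng.choice(samples, size=k_inf, replace=False)
            infil.loc[chosen, ct] = True
    for ct_a, ct_b in config.coinfiltrated_pairs:  # plant shared sample sets
        if ct_a not in infil.columns or ct_b not in infil.columns:
            raise ConfigError(f"coinfiltrated pair ({ct_a}, {ct_b}) not in panel")
        infil[ct_b] = infil[ct_a]

    # --- expression --------------------------------------------------------
    panel_genes = sorted(panel.all_genes)
    protein_genes = list(genes)
    background = [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]
    immune = list(dict.fromkeys(config.immune_genes))
    suppressed = list(dict.fromkeys(config.suppressed_genes))
    lognormal_genes = panel_genes + protein_genes + background
    all_genes = lognormal_genes + immune + suppressed
    if len(set(all_genes)) != len(all_genes):
        raise ConfigError("expression gene groups overlap; rename immune genes")

    base_mu = rng.normal(2.3, 0.5, size=len(lognormal_genes))
    log_expr = (base_mu[:, None]
                + rng.normal(0.0, config.sigma,
                             size=(len(lognormal_genes), n)))
    gene_row = {g: i for i, g in enumerate(lognormal_genes)}
    for ct in panel.cell_types:
        mask = infil[ct].to_numpy()
        for g in panel.sets[ct].genes:
            if g in gene_row:
                log_expr[gene_row[g], mask] += config.delta
    values = np.exp(log_expr)

    load_arr = load.reindex(samples).to_numpy(dtype=float)
    imm = (config.alpha + config.beta * load_arr[None, :]
           + rng.normal(0.0, config.immune_noise_sd, size=(len(immune), n)))
    sup = (config.alpha + 10.0 - config.beta * load_arr[None, :]
           + rng.normal(0.0, config.immune_noise_sd,
                        size=(len(suppressed), n)))
    expr_df = pd.DataFrame(
        np.vstack([values, np.clip(imm, 0.0, None), np.clip(sup, 0.0, None)]),
        index=pd.Index(all_genes, name="gene"), columns=samples)
    expression = ExpressionMatrix(expr_df)

    # --- survival + clinical -----------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        surv_group = quartile_split(load.reindex(samples))
    hazard = config.baseline_hazard * np.exp(
        -config.gamma * (surv_group == "top_quartile").to_numpy(dtype=float))
    t_event = rng.exponential(1.0 / hazard)
    os_months = np.minimum(t_event, config.followup_months)
    os_event = t_event <= config.followup_months

    burden_count = pd.Series(0, index=pd.Index(samples), dtype=int)
    for rec in mutations:
        if rec.variant_classification is not VariantClass.SILENT:
            burden_count[rec.sample_id] += 1
    med = burden_count.median()
    clinical = []
    for i, s in enumerate(samples):
        high = burden_count[s] > med
        cluster_p = ([0.35, 0.35, 0.10, 0.20] if high
                     else [0.20, 0.20, 0.35, 0.25])
        hist_p = [0.20, 0.45, 0.35] if high else [0.55, 0.20, 0.25]
        clinical.append(ClinicalRecord(
            sample_id=s,
            os_months=float(round(os_months[i], 4)),
            os_event=bool(os_event[i]),
            smoking_pack_years=float(round(max(
                0.0, 5 + 1.5 * burden_count[s] + rng.normal(0, 10)), 2)),
            cluster_label=str(rng.choice(
                ["cluster2", "cluster3", "cluster4", "other"], p=cluster_p)),
            histology_label=str(rng.choice(["TRU", "PI", "PP"], p=hist_p)),
            oncogene_status="positive" if s in onco_samples else "negative",
        ))

    cohort = Cohort(
        sample_ids=samples, mutations=mutations, expression=expression,
        proteins=proteins, gene_to_transcript=gene_to_transcript,
        hla=hla_list, clinical=clinical, panel=panel)
    onco = pd.Series({s: s in onco_samples for s in samples}, dtype=bool)
    onco.index.name = "sample_id"
    truth = GroundTruth(
        repair=repair, infiltration=infil, neoantigen_keys=neo_keys,
        neoantigen_load=load, survival_group=surv_group.reindex(samples),
        oncogene=onco)
    truth.validate(cohort)
    return cohort, truth
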