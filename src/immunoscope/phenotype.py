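"""Per-sample immune-cell infiltration calling from metagene enrichment.

Each sample's genes are ranked by cohort z-score (descending, ties broken
lexicographically) and every cell type's metagene set is scored with the
weighted Kolmogorov-Smirnov running-sum statistic.  Significance comes
from a gene-label permutation null; q-values are Benjamini-Hochberg
adjusted across the cell types within each sample, and a cell type is
called positively infiltrating when q <= q_threshold with a positive
enrichment score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError, UndefinedScoreError
from .io_formats import ExpressionMatrix, GeneSet
from .stats import bh_fdr


@dataclass(frozen=True)
class MetagenePanel:
    """An ordered collection of cell-type metagene sets.

    ``tcell_subtypes`` marks the subset of cell types aggregated by the
    "any T cell" prevalence summary.
    """

    cell_types: tuple[str, ...]
    sets: Mapping[str, GeneSet]
    tcell_subtypes: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.cell_types:
            raise ConfigError("panel must contain at least one cell type")
        for ct in self.cell_types:
            if ct not in self.sets:
                raise ConfigError(f"cell type {ct!r} has no gene set")
        unknown = self.tcell_subtypes - set(self.cell_types)
        if unknown:
            raise ConfigError(f"tcell_subtypes not in panel: {sorted(unknown)}")

    @classmethod
    def from_gene_sets(cls, sets: Sequence[GeneSet],
                       tcell_subtypes: Iterable[str] = ()) -> "MetagenePanel":
        return cls(
            cell_types=tuple(gs.name for gs in sets),
            sets={gs.name: gs for gs in sets},
            tcell_subtypes=frozenset(tcell_subtypes),
        )

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.sets.values():
            out |= gs.genes
        return frozenset(out)


@dataclass(frozen=True)
class CallingConfig:
    n_permutations: int = 999
    q_threshold: float = 0.10
    weight_exponent: float = 1.0
    require_positive_es: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_permutations < 100:
            raise ConfigError("n_permutations must be >= 100")
        if not (0 <= self.q_threshold < 1):
            raise ConfigError("q_threshold must be in [0, 1)")


@dataclass(frozen=True)
class EnrichmentResult:
    sample_id: str
    cell_type: str
    es: float
    p: float
    q: float
    call: bool


class InfiltrationMatrix:
    """Boolean samples-by-cell-types call matrix plus the score table."""

    def __init__(self, calls: pd.DataFrame, results: pd.DataFrame):
        self.calls = calls.astype(bool)
        self.results = results

    @property
    def sample_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def cell_types(self) -> pd.Index:
        return self.calls.columns


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def _signed_extreme(running: np.ndarray, axis: int = -1) -> np.ndarray:
    """Signed maximal deviation of a running sum.

    The positive peak wins when the two extremes tie in magnitude within
    1e-12 (keeps the decision stable under float summation order).
    """
    hi = running.max(axis=axis)
    lo = running.min(axis=axis)
    return np.where(np.abs(hi) >= np.abs(lo) - 1e-12, hi, lo)


def enrichment_score(ranked_genes: Sequence[str], weights: Sequence[float],
                     gene_set: GeneSet | Iterable[str],
                     weight_exponent: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score of ``gene_set``.

    ``ranked_genes`` must be unique and ordered best-to-worst with their
    rank weights.  Hits advance the running sum by ``|w|^exponent``
    (normalised over hits), misses retreat it by ``1/(N - n_hits)``; the
    score is the signed maximum deviation and lies in [-1, 1].
    """
    genes = np.asarray(ranked_genes, dtype=object)
    w = np.asarray(weights, dtype=float)
    if genes.shape != w.shape:
        raise ValueError("ranked_genes and weights must have equal length")
    members = set(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    n, m = len(genes), int(hit.sum())
    if m == 0:
        raise UndefinedScoreError("gene set disjoint from ranked list")
    if m == n:
        raise UndefinedScoreError("gene set covers the entire ranked list")
    return float(_score_from_hits(np.abs(w) ** weight_exponent, hit))


def _score_from_hits(w_pow: np.ndarray, hit: np.ndarray) -> float:
    n = hit.size
    m = int(hit.sum())
    norm = w_pow[hit].sum()
    inc = np.full(n, -1.0 / (n - m))
    if norm > 0:
        inc[hit] = w_pow[hit] / norm
    else:  # all hit weights zero: fall back to unweighted increments
        inc[hit] = 1.0 / m
    return float(_signed_extreme(np.cumsum(inc)))


def _permutation_scores(w_pow: np.ndarray, m: int, n_permutations: int,
                        rng: np.random.Generator) -> np.ndarray:
    """ES values for ``n_permutations`` random gene sets of size ``m``."""
    n = w_pow.size
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    hit_idx = order[:, :m]
    inc = np.full((n_permutations, n), -1.0 / (n - m))
    rows = np.arange(n_permutations)[:, None]
    w_hit = w_pow[hit_idx]
    norm = w_hit.sum(axis=1, keepdims=True)
    safe = norm.ravel() > 0
    inc[rows, hit_idx] = np.where(norm > 0, w_hit / np.where(norm > 0, norm, 1.0),
                                  1.0 / m)
    running = np.cumsum(inc, axis=1)
    return _signed_extreme(running, axis=1)


def permutation_p(es: float, ranked_genes: Sequence[str],
                  weights: Sequence[float], gene_set: GeneSet | Iterable[str],
                  n_permutations: int = 999, seed: int = 0,
                  weight_exponent: float = 1.0) -> float:
    """Gene-label permutation p-value: ``(1 + #{|es_perm| >= |es|}) / (n_perm + 1)``."""
    genes = np.asarray(ranked_genes, dtype=object)
    w_pow = np.abs(np.asarray(weights, dtype=float)) ** weight_exponent
    members = set(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    m = int(hit.sum())
    if m == 0 or m == len(genes):
        raise UndefinedScoreError("gene set has no proper overlap with ranked list")
    rng = np.random.default_rng(seed)
    null = _permutation_scores(w_pow, m, n_permutations, rng)
    exceed = int(np.sum(np.abs(null) >= abs(es)))
    return (1 + exceed) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Cohort-level calling
# ---------------------------------------------------------------------------

def rank_sample_genes(expr: ExpressionMatrix, sample_id: str
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Genes and z-score weights ordered by z descending, ties lexicographic."""
    z = expr.zscores[sample_id].to_numpy()
    names = np.asarray(expr.gene_ids, dtype=object)
    order = np.lexsort((names, -z))
    return names[order], z[order]


def call_infiltration(expr: ExpressionMatrix, panel: MetagenePanel,
                      cfg: CallingConfig | None = None) -> InfiltrationMatrix:
    """Call infiltration for every (sample, cell type) pair.

    The permutation null is shared across cell types with equal set size
    within a sample (the gene-label null depends only on the ranked
    weights and the number of hits), keyed off ``cfg.seed`` and the
    sample index so results are order-independent and reproducible.
    """
    cfg = cfg or CallingConfig()
    present = frozenset(expr.gene_ids)
    coverage = {}
    usable_sets: dict[str, frozenset[str]] = {}
    for ct in panel.cell_types:
        genes = panel.sets[ct].genes
        inter = genes & present
        coverage[ct] = len(inter) / len(genes)
        if not inter:
            warnings.warn(f"cell type {ct!r} has no genes in the expression "
                          "matrix; excluded from calling")
            continue
        if len(inter) == len(present):
            warnings.warn(f"cell type {ct!r} covers every measured gene; excluded")
            continue
        usable_sets[ct] = inter

    if not usable_sets:
        raise DataError("no cell type has usable gene overlap with the matrix")

    rows: list[EnrichmentResult] = []
    for si, sample in enumerate(expr.sample_ids):
        genes, z = rank_sample_genes(expr, sample)
        w_pow = np.abs(z) ** cfg.weight_exponent
        gene_pos = {g: i for i, g in enumerate(genes)}
        nulls: dict[int, np.ndarray] = {}
        es_by_ct: dict[str, float] = {}
        p_by_ct: dict[str, float] = {}
        for ct, members in usable_sets.items():
            hit = np.zeros(len(genes), dtype=bool)
            hit[[gene_pos[g] for g in members]] = True
            m = int(hit.sum())
            es = _score_from_hits(w_pow, hit)
            if m not in nulls:
                rng = np.random.default_rng([cfg.seed, si, m])
                nulls[m] = _permutation_scores(w_pow, m, cfg.n_permutations, rng)
            exceed = int(np.sum(np.abs(nulls[m]) >= abs(es)))
            es_by_ct[ct] = es
            p_by_ct[ct] = (1 + exceed) / (cfg.n_permutations + 1)
        cts = [ct for ct in panel.cell_types if ct in usable_sets]
        qvals = bh_fdr(np.array([p_by_ct[ct] for ct in cts]))
        for ct, q in zip(cts, qvals):
            es = es_by_ct[ct]
            call = q <= cfg.q_threshold and (es > 0 or not cfg.require_positive_es)
            rows.append(EnrichmentResult(sample, ct, es, p_by_ct[ct], float(q), call))

    results = pd.DataFrame([r.__dict__ for r in rows])
    calls = results.pivot(index="sample_id", columns="cell_type", values="call")
    calls = calls.reindex(index=list(expr.sample_ids),
                          columns=[ct for ct in panel.cell_types if ct in usable_sets])
    calls = calls.fillna(False).astype(bool)
    mat = InfiltrationMatrix(calls, results)
    mat.coverage = coverage
    return mat


# ---------------------------------------------------------------------------
# Prevalence and co-occurrence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrevalenceResult:
    per_cell_type: pd.Series  # percent of samples positive, in [0, 100]
    any_tcell: float
    any_immune: float


def infiltration_prevalence(m: InfiltrationMatrix,
                            panel: MetagenePanel) -> PrevalenceResult:
    """Percent of samples positive per cell type, plus T-cell/immune aggregates."""
    calls = m.calls
    if calls.empty:
        raise DataError("empty infiltration matrix")
    per_ct = 100.0 * calls.mean(axis=0)
    tcols = [c for c in calls.columns if c in panel.tcell_subtypes]
    any_t = 100.0 * calls[tcols].any(axis=1).mean() if tcols else 0.0
    any_imm = 100.0 * calls.any(axis=1).mean()
    return PrevalenceResult(per_ct, float(any_t), float(any_imm))


def cooccurrence(m: InfiltrationMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Fisher's exact co-occurrence of infiltration calls.

    One row per unordered cell-type pair with the 2x2 counts, odds ratio,
    two-sided p, and label in {co-occur, mutually_exclusive, ns}.  Pairs
    with a degenerate margin (a cell type called in all or no samples)
    are reported ns with a warning.
    """
    calls = m.calls
    active = [c for c in calls.columns if calls[c].any()]
    if len(active) < 2:
        raise DataError("need >= 2 cell types with at least one positive call")
    rows = []
    for a, b in combinations(calls.columns, 2):
        va, vb = calls[a].to_numpy(), calls[b].to_numpy()
        table = np.array([
            [np.sum(va & vb), np.sum(va & ~vb)],
            [np.sum(~va & vb), np.sum(~va & ~vb)],
        ])
        degenerate = va.all() or (~va).all() or vb.all() or (~vb).all()
        if degenerate:
            warnings.warn(f"degenerate margin for pair ({a}, {b}); reported ns")
            odds, p, label = np.nan, 1.0, "ns"
        else:
            odds, p = sps.fisher_exact(table, alternative="two-sided")
            if p < alpha and odds > 1:
                label = "co-occur"
            elif p < alpha and odds < 1:
                label = "mutually_exclusive"
            else:
                label = "ns"
        rows.append({"cell_type_a": a, "cell_type_b": b,
                     "n_both": int(table[0, 0]), "n_a_only": int(table[0, 1]),
                     "n_b_only": int(table[1, 0]), "n_neither": int(table[1, 1]),
                     "odds_ratio": odds, "p": float(p), "label": label})
    return pd.DataFrame(rows)
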