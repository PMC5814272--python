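import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from immunoscope.errors import ConfigError, DataError, UndefinedScoreError
from immunoscope.io_formats import ExpressionMatrix, GeneSet
from immunoscope.phenotype import (CallingConfig, InfiltrationMatrix,
                                   MetagenePanel, call_infiltration,
                                   cooccurrence, enrichment_score,
                                   infiltration_prevalence, permutation_p,
                                   rank_sample_genes)
from immunoscope.synthetic import synthetic_panel


def brute_force_es(genes, weights, members, exponent):
    """Independent oracle: literal running-sum walk over the ranked list."""
    members = set(members)
    hits = [g in members for g in genes]
    n, m = len(genes), sum(hits)
    assert 0 < m < n
    norm = sum(abs(w) ** exponent for g, w, h in zip(genes, weights, hits) if h)
    run, hi, lo = 0.0, -math.inf, math.inf
    for g, w, h in zip(genes, weights, hits):
        if h:
            run += (abs(w) ** exponent) / norm if norm > 0 else 1.0 / m
        else:
            run -= 1.0 / (n - m)
        hi, lo = max(hi, run), min(lo, run)
    return hi if abs(hi) >= abs(lo) - 1e-12 else lo


class TestEnrichmentScore:
    def test_set_at_top_exponent_zero_is_one(self):
        genes = list("ABCDEFGHIJ")
        weights = list(range(10, 0, -1))
        assert enrichment_score(genes, weights, {"A", "B", "C"},
                                weight_exponent=0) == pytest.approx(1.0, abs=1e-12)

    def test_set_at_bottom_exponent_zero_is_minus_one(self):
        genes = list("ABCDEFGHIJ")
        weights = list(range(10, 0, -1))
        members = {"H", "I", "J"}
        es = enrichment_score(genes, weights, members, weight_exponent=0)
        assert es == pytest.approx(-1.0, abs=1e-12)
        assert es == pytest.approx(
            brute_force_es(genes, weights, members, 0), abs=1e-12)

    def test_disjoint_set_is_error(self):
        with pytest.raises(UndefinedScoreError):
            enrichment_score(list("ABC"), [3, 2, 1], {"Z"})

    def test_full_cover_is_error(self):
        with pytest.raises(UndefinedScoreError):
            enrichment_score(list("ABC"), [3, 2, 1], {"A", "B", "C"})

    def test_bounded(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        for _ in range(20):
            w = rng.normal(size=50)
            members = set(rng.choice(genes, size=8, replace=False))
            es = enrichment_score(genes, w, members)
            assert -1.0 <= es <= 1.0

    @pytest.mark.parametrize("exponent", [0.0, 1.0])
    def test_agrees_with_oracle_exhaustive_small(self, exponent):
        # every proper nonempty subset of an 8-gene ranked list
        rng = np.random.default_rng(42)
        genes = list("ABCDEFGH")
        weights = np.sort(rng.normal(size=8))[::-1]
        for r in range(1, 8):
            for combo in itertools.combinations(genes, r):
                es = enrichment_score(genes, weights, set(combo), exponent)
                oracle = brute_force_es(genes, weights, set(combo), exponent)
                assert es == pytest.approx(oracle, abs=1e-12), combo


class TestPermutationP:
    def _graded(self, n=50):
        genes = [f"g{i:02d}" for i in range(n)]
        weights = np.linspace(3.0, -3.0, n)
        return genes, weights

    def test_top_set_gets_minimal_p(self):
        genes, weights = self._graded()
        members = set(genes[:5])
        es = enrichment_score(genes, weights, members)
        p = permutation_p(es, genes, weights, members,
                          n_permutations=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_zero_es_near_one(self):
        genes, weights = self._graded()
        p = permutation_p(0.0, genes, weights, set(genes[::7]),
                          n_permutations=199, seed=0)
        assert p > 0.9

    def test_deterministic_under_seed(self):
        genes, weights = self._graded()
        members = set(genes[10:20])
        es = enrichment_score(genes, weights, members)
        args = (es, genes, weights, members)
        assert permutation_p(*args, n_permutations=199, seed=7) == \
            permutation_p(*args, n_permutations=199, seed=7)

    def test_p_at_least_minimum_achievable(self):
        genes, weights = self._graded(20)
        members = set(genes[:4])
        es = enrichment_score(genes, weights, members)
        p = permutation_p(es, genes, weights, members,
                          n_permutations=199, seed=3)
        assert p >= 1 / 200


class TestRanking:
    def test_ties_broken_lexicographically(self):
        df = pd.DataFrame({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 2.0, 1.0]},
                          index=["B", "A", "C"])
        expr = ExpressionMatrix(df)
        genes, _ = rank_sample_genes(expr, "s1")
        # z-scores: C highest in s1; A and B tie -> lexicographic
        assert list(genes) == ["C", "A", "B"]


class TestCallInfiltration:
    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(10)
        panel = synthetic_panel(n_cell_types=4, genes_per_set=15, n_tcell=1)
        genes = sorted(panel.all_genes) + [f"BG{i}" for i in range(40)]
        samples = [f"S{i:02d}" for i in range(12)]
        log_expr = rng.normal(2.0, 1.0, size=(len(genes), len(samples)))
        target_ct = panel.cell_types[0]
        planted = {"S00", "S03", "S07"}
        rows = [i for i, g in enumerate(genes)
                if g in panel.sets[target_ct].genes]
        cols = [j for j, s in enumerate(samples) if s in planted]
        for i in rows:
            for j in cols:
                log_expr[i, j] += 3.0  # delta = 3 sigma
        expr = ExpressionMatrix(pd.DataFrame(np.exp(log_expr), index=genes,
                                             columns=samples))
        mat = call_infiltration(expr, panel,
                                CallingConfig(n_permutations=199, seed=4))
        for s in planted:
            assert mat.calls.at[s, target_ct]

    def test_null_positive_rate_controlled(self, noise_expression):
        panel = synthetic_panel(n_cell_types=6, genes_per_set=12, n_tcell=2)
        # rename panel genes to genes that exist in the matrix
        sets = []
        pool = list(noise_expression.gene_ids)
        start = 0
        for ct in panel.cell_types:
            sets.append(GeneSet(ct, frozenset(pool[start:start + 12])))
            start += 12
        panel = MetagenePanel.from_gene_sets(sets, panel.tcell_subtypes)
        mat = call_infiltration(noise_expression, panel,
                                CallingConfig(n_permutations=199, seed=0))
        rate = mat.calls.to_numpy().mean()
        n_cells = mat.calls.size
        bound = 0.10 + 3 * math.sqrt(0.1 * 0.9 / n_cells)
        assert rate <= bound

    def test_zero_threshold_no_calls(self, noise_expression, demo_panel):
        sets = []
        pool = list(noise_expression.gene_ids)
        start = 0
        for ct in demo_panel.cell_types:
            sets.append(GeneSet(ct, frozenset(pool[start:start + 10])))
            start += 10
        panel = MetagenePanel.from_gene_sets(sets, demo_panel.tcell_subtypes)
        mat = call_infiltration(noise_expression, panel,
                                CallingConfig(n_permutations=199,
                                              q_threshold=0.0, seed=0))
        assert not mat.calls.to_numpy().any()

    def test_uncovered_cell_type_excluded_with_warning(self, noise_expression):
        sets = [GeneSet("covered", frozenset(list(noise_expression.gene_ids)[:8])),
                GeneSet("uncovered", frozenset({"NOT_A_GENE"}))]
        panel = MetagenePanel.from_gene_sets(sets)
        with pytest.warns(UserWarning, match="uncovered"):
            mat = call_infiltration(noise_expression, panel,
                                    CallingConfig(n_permutations=199))
        assert list(mat.calls.columns) == ["covered"]

    def test_deterministic(self, noise_expression):
        sets = [GeneSet("a", frozenset(list(noise_expression.gene_ids)[:10])),
                GeneSet("b", frozenset(list(noise_expression.gene_ids)[10:25]))]
        panel = MetagenePanel.from_gene_sets(sets)
        cfg = CallingConfig(n_permutations=149, seed=5)
        m1 = call_infiltration(noise_expression, panel, cfg)
        m2 = call_infiltration(noise_expression, panel, cfg)
        pd.testing.assert_frame_equal(m1.results, m2.results)


def _matrix_from_calls(calls: pd.DataFrame) -> InfiltrationMatrix:
    return InfiltrationMatrix(calls, pd.DataFrame())


class TestPrevalence:
    def test_simple_percent(self, demo_panel):
        calls = pd.DataFrame(False, index=[f"S{i}" for i in range(4)],
                             columns=list(demo_panel.cell_types))
        calls.iloc[0, 0] = True
        prev = infiltration_prevalence(_matrix_from_calls(calls), demo_panel)
        assert prev.per_cell_type[demo_panel.cell_types[0]] == 25.0

    def test_aggregate_ordering(self, demo_panel):
        rng = np.random.default_rng(3)
        calls = pd.DataFrame(rng.random((30, len(demo_panel.cell_types))) < 0.3,
                             index=[f"S{i}" for i in range(30)],
                             columns=list(demo_panel.cell_types))
        prev = infiltration_prevalence(_matrix_from_calls(calls), demo_panel)
        t_max = max(prev.per_cell_type[ct] for ct in demo_panel.tcell_subtypes)
        assert prev.any_immune >= prev.any_tcell >= t_max

    def test_all_false(self, demo_panel):
        calls = pd.DataFrame(False, index=["S1", "S2"],
                             columns=list(demo_panel.cell_types))
        prev = infiltration_prevalence(_matrix_from_calls(calls), demo_panel)
        assert (prev.per_cell_type == 0).all()
        assert prev.any_tcell == 0.0 and prev.any_immune == 0.0


class TestCooccurrence:
    def _calls(self, a, b):
        return pd.DataFrame({"A": a, "B": b},
                            index=[f"S{i}" for i in range(len(a))])

    def test_perfect_agreement(self):
        calls = self._calls([True] * 10 + [False] * 10,
                            [True] * 10 + [False] * 10)
        out = cooccurrence(_matrix_from_calls(calls))
        row = out.iloc[0]
        # exact hypergeometric: two-sided p = 2 / C(20, 10)
        assert row["p"] == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert row["label"] == "co-occur"

    def test_independence(self):
        calls = self._calls([True] * 5 + [False] * 5 + [True] * 5 + [False] * 5,
                            [True] * 10 + [False] * 10)
        out = cooccurrence(_matrix_from_calls(calls))
        row = out.iloc[0]
        assert row["p"] == pytest.approx(1.0)
        assert row["label"] == "ns"

    def test_perfect_disagreement(self):
        calls = self._calls([True] * 10 + [False] * 10,
                            [False] * 10 + [True] * 10)
        out = cooccurrence(_matrix_from_calls(calls))
        assert out.iloc[0]["label"] == "mutually_exclusive"

    def test_degenerate_margin_is_ns(self):
        calls = self._calls([True] * 20, [True] * 10 + [False] * 10)
        with pytest.warns(UserWarning, match="degenerate"):
            out = cooccurrence(_matrix_from_calls(calls))
        assert out.iloc[0]["label"] == "ns"

    def test_too_few_active_is_error(self):
        calls = self._calls([False] * 10, [False] * 10)
        with pytest.raises(DataError):
            cooccurrence(_matrix_from_calls(calls))


class TestPanelValidation:
    def test_tcell_subtype_must_exist(self):
        sets = [GeneSet("a", frozenset({"X"}))]
        with pytest.raises(ConfigError):
            MetagenePanel.from_gene_sets(sets, tcell_subtypes=["missing"])
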