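import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoscope.errors import FormatError, RecordError, VariantRejectedError
from immunoscope.io_formats import HlaGenotype
from immunoscope.neoantigen import (NeoantigenThresholds, PeptidePair,
                                    ProteinVariant, VariantPrediction,
                                    apply_variant, attach_predictions,
                                    call_neoantigens, enumerate_peptides,
                                    parse_predictor_output, predict_cohort,
                                    predict_pairs, variants_from_mutations)
from immunoscope.io_formats import ExpressionMatrix
from immunoscope.synthetic import default_predictor


def brute_force_windows(L, p, k):
    """Oracle: every k-substring of a length-L sequence that covers p."""
    return [s for s in range(1, L - k + 2) if s <= p <= s + k - 1]


def variant(sample="S1", gene="G1", tid="T1", pos=3, ref="D", alt="N"):
    return ProteinVariant(sample_id=sample, gene=gene, transcript_id=tid,
                          position=pos, ref_aa=ref, alt_aa=alt)


GENOTYPE = HlaGenotype("S1", ("HLA-A*01:01", "HLA-A*02:01", "HLA-B*07:02",
                              "HLA-B*08:01", "HLA-C*07:01", "HLA-C*07:02"))
HOMOZYGOUS = HlaGenotype("S1", ("HLA-A*01:01", "HLA-A*01:01", "HLA-B*07:02",
                                "HLA-B*08:01", "HLA-C*07:01", "HLA-C*07:02"))


class TestApplyVariant:
    def test_substitution(self):
        assert apply_variant("ACDEF", variant(pos=3, ref="D", alt="N")) == "ACNEF"

    def test_reference_mismatch_rejected(self):
        with pytest.raises(VariantRejectedError, match="reference"):
            apply_variant("ACDEF", variant(pos=3, ref="E", alt="N"))

    def test_apply_then_revert_is_identity(self):
        seq = "ACDEFGHIK"
        mutated = apply_variant(seq, variant(pos=5, ref="F", alt="W"))
        back = apply_variant(mutated, variant(pos=5, ref="W", alt="F"))
        assert back == seq

    def test_position_beyond_length_rejected(self):
        with pytest.raises(VariantRejectedError):
            apply_variant("ACD", variant(pos=9, ref="D", alt="N"))


class TestEnumeratePeptides:
    def _seqs(self, L, p):
        wt = ("ACDEFGHIKLMNPQRSTVWY" * 10)[:L]
        alt = "W" if wt[p - 1] != "W" else "Y"
        return wt, wt[: p - 1] + alt + wt[p:]

    def test_interior_site_nine_windows(self):
        wt, mt = self._seqs(20, 10)
        pairs = enumerate_peptides(wt, mt, 10, 9)
        assert [p.window_start for p in pairs] == list(range(2, 11))
        assert len(pairs) == 9

    def test_terminal_residue_one_window(self):
        wt, mt = self._seqs(20, 1)
        pairs = enumerate_peptides(wt, mt, 1, 9)
        assert len(pairs) == 1 and pairs[0].window_start == 1

    def test_whole_protein_window(self):
        wt, mt = self._seqs(9, 5)
        pairs = enumerate_peptides(wt, mt, 5, 9)
        assert len(pairs) == 1
        assert pairs[0].mutant_peptide == mt

    def test_short_protein_warns_empty(self):
        wt, mt = self._seqs(6, 3)
        with pytest.warns(UserWarning, match="no windows"):
            assert enumerate_peptides(wt, mt, 3, 9) == []

    def test_pairs_differ_exactly_at_offset(self):
        wt, mt = self._seqs(25, 12)
        for pair in enumerate_peptides(wt, mt, 12, 9):
            diffs = [i for i, (a, b) in enumerate(
                zip(pair.mutant_peptide, pair.wildtype_peptide), 1) if a != b]
            assert diffs == [pair.offset]
            assert pair.mutant_peptide[pair.offset - 1] == mt[11]
            assert pair.wildtype_peptide[pair.offset - 1] == wt[11]

    @given(st.integers(9, 30), st.data(), st.sampled_from([8, 9, 10]))
    @settings(max_examples=60, deadline=None)
    def test_matches_window_oracle(self, L, data, k):
        p = data.draw(st.integers(1, L))
        wt, mt = self._seqs(L, p)
        if L < k:
            return
        pairs = enumerate_peptides(wt, mt, p, k)
        assert [q.window_start for q in pairs] == brute_force_windows(L, p, k)


class TestPredictPairs:
    def _pairs(self):
        wt, mt = "ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKWMNPQRSTVWY"
        return enumerate_peptides(wt, mt, 10, 9)

    def test_cartesian_count(self):
        table = predict_pairs(self._pairs(), GENOTYPE, default_predictor())
        assert len(table) == 9 * 6

    def test_homozygous_collapses(self):
        table = predict_pairs(self._pairs(), HOMOZYGOUS, default_predictor())
        assert len(table) == 9 * 5

    def test_missing_allele_skipped_with_warning(self):
        class Partial:
            def __init__(self, inner):
                self.inner = inner
                self.alleles = inner.alleles[:-1]

            def predict(self, pep, allele):
                if allele == "HLA-C*07:02":
                    raise KeyError(allele)
                return self.inner.predict(pep, allele)

        with pytest.warns(UserWarning, match="skipped"):
            table = predict_pairs(self._pairs(), GENOTYPE,
                                  Partial(default_predictor()))
        assert len(table) == 9 * 5

    def test_peptides_with_x_dropped(self):
        pair = PeptidePair("ACDEFGHIX", "ACDEFGHIX".replace("I", "W"), 8, 1)
        with pytest.warns(UserWarning, match="dropped"):
            table = predict_pairs([pair], GENOTYPE, default_predictor())
        assert table.empty


def _expr(genes_values, samples):
    return ExpressionMatrix(pd.DataFrame(genes_values, index=samples).T)


class TestCallNeoantigens:
    def _prediction(self, mutant, wt, sample="S1", gene="G1"):
        pair = PeptidePair("ACDEFGHIK", "ACDEFGHIN", 9, 1)
        table = pd.DataFrame([{"pair": pair, "allele": "HLA-A*01:01",
                               "mutant_ic50": mutant, "wildtype_ic50": wt}])
        return VariantPrediction(variant(sample=sample, gene=gene,
                                         ref="N", alt="K", pos=9), table)

    def test_truth_table_all_combinations(self):
        # the three strict filters: mut < 500, wt > 500, expr > 0
        cases = [(100.0, 800.0, 5.2, True),
                 (100.0, 300.0, 5.2, False),
                 (100.0, 800.0, 0.0, False),
                 (700.0, 800.0, 5.2, False),
                 (700.0, 300.0, 5.2, False),
                 (700.0, 800.0, 0.0, False),
                 (100.0, 300.0, 0.0, False),
                 (700.0, 300.0, 0.0, False)]
        for mut_ic50, wt_ic50, expression, expected in cases:
            expr = _expr({"G1": [expression]}, ["S1"])
            calls, load = call_neoantigens([self._prediction(mut_ic50, wt_ic50)],
                                           expr)
            assert calls[0].is_neoantigen is expected, (mut_ic50, wt_ic50,
                                                        expression)
            assert load["S1"] == int(expected)

    def test_boundary_values_fail_strict_inequalities(self):
        expr = _expr({"G1": [1.0]}, ["S1"])
        calls, _ = call_neoantigens([self._prediction(500.0, 800.0)], expr)
        assert not calls[0].is_neoantigen
        calls, _ = call_neoantigens([self._prediction(100.0, 500.0)], expr)
        assert not calls[0].is_neoantigen

    def test_variant_counted_once_with_mixed_rows(self):
        pair = PeptidePair("ACDEFGHIK", "ACDEFGHIN", 9, 1)
        table = pd.DataFrame([
            {"pair": pair, "allele": "HLA-A*01:01",
             "mutant_ic50": 700.0, "wildtype_ic50": 800.0},   # fails
            {"pair": pair, "allele": "HLA-A*02:01",
             "mutant_ic50": 100.0, "wildtype_ic50": 800.0},   # passes
        ])
        vp = VariantPrediction(variant(ref="N", alt="K", pos=9), table)
        expr = _expr({"G1": [2.0]}, ["S1"])
        calls, load = call_neoantigens([vp], expr)
        assert calls[0].is_neoantigen and len(calls[0].passing_pairs) == 1
        assert load["S1"] == 1

    def test_missing_gene_treated_as_zero_expression(self):
        expr = _expr({"OTHER": [9.0]}, ["S1"])
        with pytest.warns(UserWarning, match="absent"):
            calls, _ = call_neoantigens([self._prediction(100.0, 800.0)], expr)
        assert not calls[0].is_neoantigen

    def test_monotone_in_thresholds(self, demo_cohort):
        cohort, _ = demo_cohort
        hla_map = {g.sample_id: g for g in cohort.hla}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = predict_cohort(cohort.mutations, cohort.proteins, hla_map,
                                  default_predictor(), cohort.expression,
                                  NeoantigenThresholds(),
                                  roster=cohort.sample_ids)[1]
            looser = predict_cohort(cohort.mutations, cohort.proteins, hla_map,
                                    default_predictor(), cohort.expression,
                                    NeoantigenThresholds(mutant_ic50_max=1000.0,
                                                         wt_ic50_min=250.0),
                                    roster=cohort.sample_ids)[1]
        assert (looser >= base).all()

    def test_load_matches_ground_truth(self, demo_cohort):
        cohort, truth = demo_cohort
        hla_map = {g.sample_id: g for g in cohort.hla}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, load = predict_cohort(cohort.mutations, cohort.proteins, hla_map,
                                     default_predictor(), cohort.expression,
                                     roster=cohort.sample_ids)
        assert load.equals(truth.neoantigen_load.reindex(load.index))

    def test_load_invariant_under_mutation_order(self, demo_cohort):
        cohort, _ = demo_cohort
        hla_map = {g.sample_id: g for g in cohort.hla}
        rng = np.random.default_rng(0)
        shuffled = list(cohort.mutations)
        rng.shuffle(shuffled)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = predict_cohort(cohort.mutations, cohort.proteins, hla_map,
                               default_predictor(), cohort.expression,
                               roster=cohort.sample_ids)[1]
            b = predict_cohort(shuffled, cohort.proteins, hla_map,
                               default_predictor(), cohort.expression,
                               roster=cohort.sample_ids)[1]
        assert a.equals(b)


class TestVariantsFromMutations:
    def test_only_missense_extracted(self, demo_cohort):
        cohort, _ = demo_cohort
        variants = variants_from_mutations(cohort.mutations)
        from immunoscope.io_formats import VariantClass
        n_missense = sum(m.variant_classification is VariantClass.MISSENSE
                         for m in cohort.mutations)
        assert len(variants) == n_missense
        assert all(v.ref_aa != v.alt_aa for v in variants)


class TestPredictorOutputParsing:
    def test_parse_generic(self, tmp_path):
        path = tmp_path / "preds.tsv"
        path.write_text("peptide\tallele\tic50\n"
                        "ACDEFGHIK\tHLA-A*01:01\t123.4\n"
                        "ACDEFGHIN\tHLA-A*01:01\t765.4\n"
                        "WWWWWWWWW\tHLA-A*01:01\t50.0\n")
        table = parse_predictor_output(path)
        assert len(table) == 3
        assert table["ic50"].tolist() == [123.4, 765.4, 50.0]

    def test_unknown_dialect(self, tmp_path):
        path = tmp_path / "preds.tsv"
        path.write_text("peptide\tallele\tic50\n")
        with pytest.raises(FormatError, match="dialect"):
            parse_predictor_output(path, dialect="nope")

    def test_non_numeric_affinity_is_row_error(self, tmp_path):
        path = tmp_path / "preds.tsv"
        path.write_text("peptide\tallele\tic50\nACDEFGHIK\tHLA-A*01:01\tNA\n")
        with pytest.raises(RecordError, match="row 2"):
            parse_predictor_output(path)

    def test_attach_reports_unmatched(self, tmp_path):
        pair = PeptidePair("ACDEFGHIK", "ACDEFGHIN", 9, 1)
        table = pd.DataFrame({
            "peptide": ["ACDEFGHIK", "ACDEFGHIN", "WWWWWWWWW"],
            "allele": ["HLA-A*01:01"] * 3,
            "ic50": [100.0, 800.0, 5.0]})
        with pytest.warns(UserWarning, match="no peptide pair"):
            joined, unmatched = attach_predictions([pair], table)
        assert len(joined) == 1
        assert joined.iloc[0]["mutant_ic50"] == 100.0
        assert unmatched["peptide"].tolist() == ["WWWWWWWWW"]


class TestThresholds:
    def test_k_minimum(self):
        with pytest.raises(ValueError):
            NeoantigenThresholds(k=7)

    def test_positive_thresholds(self):
        with pytest.raises(ValueError):
            NeoantigenThresholds(mutant_ic50_max=0.0)
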