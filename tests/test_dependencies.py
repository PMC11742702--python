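import math

import numpy as np
import pandas as pd
import pytest

from lingcurate.core import FeatureDef, TraitMatrix
from lingcurate.dependencies import (
    CrossTable,
    Expectation,
    ExpectationResult,
    cohens_d_paired,
    conformity_counts,
    cross_table,
    decide,
    overlap_prefilter,
    sample_probabilities,
)
from lingcurate.sampling import DiversitySample

from conftest import binary_features, make_matrix


def make_sample(taxa):
    return DiversitySample(
        pd.DataFrame({"taxon": taxa, "macroarea": "X", "lineage": taxa}),
        seed=0)


def two_feature_matrix(cells):
    """cells: list of (f1 value, f2 value); taxa t0.."""
    rows = {f"t{i:04d}": {"f1": a, "f2": b} for i, (a, b) in enumerate(cells)}
    return make_matrix(rows, binary_features(["f1", "f2"]))


class TestOverlapPrefilter:
    def test_identical_coded_sets(self):
        m = two_feature_matrix([("1", "1")] * 10)
        proceed, ratio = overlap_prefilter(m, "f1", "f2")
        assert proceed and ratio == 1.0

    @pytest.mark.parametrize("overlap, proceed", [(200, False), (400, True)])
    def test_ratio_against_better_coded_feature(self, overlap, proceed):
        cells = [("1", "1")] * overlap + [("?", "1")] * (1000 - overlap)
        m = two_feature_matrix(cells)
        got_proceed, ratio = overlap_prefilter(m, "f1", "f2")
        assert ratio == pytest.approx(overlap / 1000)
        assert got_proceed is proceed

    def test_zero_coded_feature(self):
        m = two_feature_matrix([("?", "1")] * 5)
        assert overlap_prefilter(m, "f1", "f2") == (False, 0.0)


class TestCrossTable:
    def test_single_taxon_both_states(self):
        m = two_feature_matrix([("1", "1")])
        t = cross_table(m, m.taxa, ("f1", "1"), ("f2", "1"))
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 1)

    def test_empty_overlap_all_zero(self):
        m = two_feature_matrix([("1", "?"), ("?", "1")])
        t = cross_table(m, m.taxa, ("f1", "1"), ("f2", "1"))
        assert t.n == 0

    def test_uncoded_taxa_ignored(self):
        m = two_feature_matrix([("1", "1"), ("1", "NA"), ("?", "0")])
        t = cross_table(m, m.taxa, ("f1", "1"), ("f2", "1"))
        assert t.n == 1


class TestApplicability:
    def test_full_coverage(self):
        m = two_feature_matrix([("1", "1")] * 6 + [("0", "0")] * 6)
        s = sample_probabilities(m, make_sample(m.taxa),
                                 Expectation("e", "THEN", ("f1", "1"),
                                             ("f2", "1")))
        assert s.applicability == (1.0,)
        assert s.valid

    def test_three_of_four_antecedents(self):
        cells = ([("1", "1")] * 3 + [("1", "?")]
                 + [("0", "1")] * 8)
        m = two_feature_matrix(cells)
        s = sample_probabilities(m, make_sample(m.taxa),
                                 Expectation("e", "THEN", ("f1", "1"),
                                             ("f2", "1")))
        assert s.applicability == (0.75,)
        assert s.valid

    def test_below_one_third_invalidates(self):
        cells = [("1", "1")] * 3 + [("1", "?")] * 7 + [("0", "1")] * 5
        m = two_feature_matrix(cells)
        s = sample_probabilities(m, make_sample(m.taxa),
                                 Expectation("e", "THEN", ("f1", "1"),
                                             ("f2", "1")))
        assert s.applicability[0] == pytest.approx(0.30)
        assert not s.valid

    def test_zero_denominator_flagged_distinctly(self):
        m = two_feature_matrix([("0", "1")] * 5)
        s = sample_probabilities(m, make_sample(m.taxa),
                                 Expectation("e", "THEN", ("f1", "1"),
                                             ("f2", "1")))
        assert not s.valid
        assert "antecedent" in s.invalid_reason


class TestSampleProbabilities:
    def test_no_exceptions_gives_zero_conditional(self):
        m = two_feature_matrix([("1", "1")] * 5 + [("0", "0")] * 5)
        s = sample_probabilities(m, make_sample(m.taxa),
                                 Expectation("e", "THEN", ("f1", "1"),
                                             ("f2", "1")))
        assert s.conditional == (0.0,)

    def test_constructed_table(self):
        # 10 antecedent taxa (1 exception), 30 both-coded in total with
        # 12 consequent-negative -> conditional 0.1, marginal 0.4
        cells = ([("1", "0")] * 1 + [("1", "1")] * 9
                 + [("0", "0")] * 11 + [("0", "1")] * 9)
        m = two_feature_matrix(cells)
        s = sample_probabilities(m, make_sample(m.taxa),
                                 Expectation("e", "THEN", ("f1", "1"),
                                             ("f2", "1")))
        assert s.n_both_coded == 30
        assert s.conditional == (pytest.approx(0.1),)
        assert s.marginal == (pytest.approx(0.4),)

    def test_independent_features_conditional_matches_marginal(self):
        rng = np.random.default_rng(17)
        n = 10_000
        cells = list(zip(rng.choice(["1", "0"], n, p=[0.4, 0.6]),
                         rng.choice(["1", "0"], n, p=[0.7, 0.3])))
        m = two_feature_matrix(cells)
        s = sample_probabilities(m, make_sample(m.taxa),
                                 Expectation("e", "THEN", ("f1", "1"),
                                             ("f2", "1")))
        assert s.conditional[0] == pytest.approx(s.marginal[0], abs=0.03)

    def test_bidirectional_types_report_two_directions(self):
        cells = [("1", "0")] * 10 + [("0", "1")] * 10 + [("0", "0")] * 5
        m = two_feature_matrix(cells)
        s = sample_probabilities(m, make_sample(m.taxa),
                                 Expectation("e", "OR", ("f1", "1"),
                                             ("f2", "1")))
        assert len(s.applicability) == len(s.conditional) == 2
        assert s.conditional == (0.0, 0.0)  # perfectly exclusionary


class TestConformity:
    def test_then_counts_only_antecedent_violations(self):
        t = CrossTable(a=5, b=6, c=2, d=20)
        assert conformity_counts(t, "THEN") == (31, 2)

    def test_or_counts_cooccurrence(self):
        t = CrossTable(a=5, b=6, c=7, d=2)
        assert conformity_counts(t, "OR") == (13, 2)


class TestCohensD:
    def test_identical_vectors(self):
        assert cohens_d_paired([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == (0.0, True)

    def test_constant_nonzero_difference_is_infinite(self):
        d, degenerate = cohens_d_paired([0.1, 0.2], [0.3, 0.4])
        assert math.isinf(d) and degenerate

    def test_requires_pairs(self):
        with pytest.raises(ValueError):
            cohens_d_paired([0.1], [0.2])


def result_with(aggs, n_valid=100):
    e = Expectation("e", "THEN" if len(aggs) == 1 else "OR",
                    ("f1", "1"), ("f2", "1"))
    return ExpectationResult(e, "none", n_valid_samples=n_valid,
                             aggregates=aggs)


def agg(d, mu_cond, sd_cond=0.01, mu_marg=0.5):
    return {"mu_cond": mu_cond, "sd_cond": sd_cond, "mu_marg": mu_marg,
            "sd_marg": 0.05, "cohens_d": d}


class TestDecide:
    def test_few_exceptions_strong_effect_acts(self):
        assert decide(result_with([agg(5.0, 0.05)])) == "act"

    def test_many_exceptions_strong_effect_logged(self):
        assert decide(result_with([agg(5.0, 0.35, sd_cond=0.1)])) == "log_remaining"

    def test_few_exceptions_weak_effect_none(self):
        assert decide(result_with([agg(0.3, 0.05)])) == "none"

    def test_too_few_samples_untestable(self):
        assert decide(result_with([agg(5.0, 0.05)], n_valid=19)) == \
            "untestable_samples"

    def test_bidirectional_needs_both_directions(self):
        both = result_with([agg(5.0, 0.05), agg(5.0, 0.05)])
        assert decide(both) == "act"
        one = result_with([agg(5.0, 0.05), agg(0.5, 0.05)])
        assert decide(one) == "log_remaining"

    def test_anti_directional_effect_never_acts(self):
        backwards = result_with([agg(5.0, 0.05, mu_marg=0.01)])
        assert decide(backwards) != "act"
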