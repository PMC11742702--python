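import numpy as np
import pandas as pd
import pytest

from lingcurate.core import NOT_APPLICABLE, UNKNOWN, TraitMatrixError
from lingcurate.recode import (
    Modification,
    PlanError,
    RecodePlan,
    apply_plan,
    condition_feature,
    derive_meta_feature,
    merge_combined,
    min_coding_filter,
    min_variability_filter,
    name_feature,
    state_adapt,
)

from conftest import binary_features, make_matrix


def col(values, index=None, name="x"):
    index = index or [f"t{i}" for i in range(len(values))]
    return pd.Series(values, index=index, dtype=object, name=name)


class TestAutomaticFilters:
    @pytest.mark.parametrize("n_coded, passes", [(100, True), (99, False)])
    def test_min_coding_boundary(self, n_coded, passes):
        rows = {f"t{i}": {"f": "1" if i < n_coded else "?", "g": "0"}
                for i in range(150)}
        m = make_matrix(rows, binary_features(["f", "g"]))
        assert ("f" not in min_coding_filter(m, 100)) == passes

    def test_all_unknown_fails(self):
        m = make_matrix({f"t{i}": {"f": "?"} for i in range(5)},
                        binary_features(["f"]))
        assert min_coding_filter(m, 3) == ["f"]

    @pytest.mark.parametrize(
        "counts, passes",
        [((10, 3), True), ((10, 2), False), ((10, 0), False)],
        ids=["second=3", "second=2", "single-state"],
    )
    def test_min_variability(self, counts, passes):
        values = ["A"] * counts[0] + ["B"] * counts[1]
        rows = {f"t{i}": {"f": v} for i, v in enumerate(values)}
        from lingcurate.core import FeatureDef
        m = make_matrix(rows, {"f": FeatureDef(id="f", states=("A", "B"))})
        assert ("f" not in min_variability_filter(m, 3)) == passes


class TestStateAdapt:
    STATES = ("NoVelarNasal", "InitialVelarNasal", "NoInitialVelarNasal")

    def test_incoherent_state_becomes_unknown(self):
        c = col(["mixed", "A"])
        out, states = state_adapt(c, {"mixed": UNKNOWN},
                                  ("mixed", "A", "B"))
        assert list(out) == [UNKNOWN, "A"]
        assert states == ("A", "B")

    def test_identity_mapping(self):
        c = col(["1", "0", "?"])
        out, states = state_adapt(c, {}, ("1", "0"))
        assert list(out) == ["1", "0", "?"]
        assert states == ("1", "0")

    def test_presence_dimension_of_compositional_split(self):
        # merging the two positional states recovers plain presence
        c = col(["InitialVelarNasal", "NoInitialVelarNasal", "NoVelarNasal"])
        mapping = {"InitialVelarNasal": "VelarNasal",
                   "NoInitialVelarNasal": "VelarNasal"}
        out, states = state_adapt(c, mapping, self.STATES)
        assert list(out) == ["VelarNasal", "VelarNasal", "NoVelarNasal"]
        assert set(states) == {"VelarNasal", "NoVelarNasal"}

    def test_collapse_below_two_states_is_error(self):
        with pytest.raises(TraitMatrixError):
            state_adapt(col(["1", "0"]), {"1": "0"}, ("1", "0"))


class TestMetaFeature:
    @pytest.mark.parametrize(
        "inputs, expected",
        [(("1", "?", "0"), "1"), (("0", "0", "0"), "0"), (("0", "?", "0"), "?")],
        ids=["any-present", "all-known-absent", "agnostic"],
    )
    def test_three_rules(self, inputs, expected):
        cols = [col([v], index=["t"]) for v in inputs]
        assert derive_meta_feature(cols).loc["t"] == expected

    def test_order_invariant_and_duplicate_idempotent(self):
        cols = [col(list(v)) for v in
                (["1", "0", "?"], ["0", "0", "0"], ["?", "0", "0"])]
        base = derive_meta_feature(cols)
        assert derive_meta_feature(cols[::-1]).equals(base)
        assert derive_meta_feature(cols + [cols[0]]).equals(base)

    def test_empty_input_error(self):
        with pytest.raises(TraitMatrixError):
            derive_meta_feature([])


class TestConditioning:
    def test_self_conditioning_is_error(self):
        c = col(["1", "0"], name="f")
        with pytest.raises(TraitMatrixError):
            condition_feature(c, c, {"1"})

    def test_never_rewrites_coded_to_other_coded(self):
        rng = np.random.default_rng(5)
        target = col(list(rng.choice(["1", "0", "?", "NA"], size=60)),
                     name="t")
        cond = col(list(rng.choice(["1", "0", "?", "NA"], size=60)), name="c")
        for mode in ("conservative", "liberal"):
            out = condition_feature(target, cond, {"1"}, mode)
            coded_both = (~target.isin(["?", "NA"])) & (~out.isin(["?", "NA"]))
            assert (out[coded_both] == target[coded_both]).all()

    def test_liberal_preserves_through_unknown_condition(self):
        out = condition_feature(col(["0"]), col(["?"]), {"1"}, "liberal")
        assert out.iloc[0] == "0"


class TestMergeCombined:
    @pytest.mark.parametrize(
        "a, b, priority, expected",
        [
            ("X", "?", "a", "X"),     # b uncoded -> a
            ("X", "Y", "a", "X"),     # conflict -> priority side
            ("X", "Y", "b", "Y"),
            ("?", "Y", "a", "Y"),     # single-source fallback
            ("X", "X", "b", "X"),     # agreement
            ("?", "?", "a", "?"),
            ("NA", "NA", "a", "NA"),  # NA only when both NA
            ("NA", "?", "a", "?"),
        ],
    )
    def test_rule_table(self, a, b, priority, expected):
        out = merge_combined(col([a], index=["t"]), col([b], index=["t"]),
                             priority)
        assert out.loc["t"] == expected


class TestApplyPlan:
    def test_empty_plan_is_identity(self):
        m = make_matrix({"a": {"f": "1"}, "b": {"f": "0"}},
                        binary_features(["f"]))
        out, audit = apply_plan(m, RecodePlan([]), enforce_filters=False)
        assert out == m
        assert audit.empty

    def test_single_exclude(self):
        m = make_matrix({"a": {"f": "1", "g": "0"}, "b": {"f": "0", "g": "1"}},
                        binary_features(["f", "g"]))
        plan = RecodePlan([Modification("x1", "design", "exclude", ["f"], [])])
        out, _ = apply_plan(m, plan, enforce_filters=False)
        assert out.feature_ids == ["g"]

    def test_gender_fixture_meta_and_conditioning(self, gender_fixture):
        """Manual truth table for the six-taxon gender block."""
        m, plan = gender_fixture
        out, audit = apply_plan(m, plan, enforce_filters=False)
        assert set(out.feature_ids) == {"gender_m", "g1c", "g2c", "g3c"}
        meta = out.column("gender_m")
        assert list(meta) == ["1", "0", "?", "1", "?", "?"]
        # all-absent taxon gets NA on every conditioned column
        for g in ("g1c", "g2c", "g3c"):
            assert out.data.at["t2", g] == NOT_APPLICABLE
        # taxa with unknown meta are forced agnostic (conservative mode)
        for t in ("t3", "t5", "t6"):
            assert set(out.data.loc[t, ["g1c", "g2c", "g3c"]]) == {UNKNOWN}
        # present taxa keep their manifestation values
        assert list(out.data.loc["t4", ["g1c", "g2c", "g3c"]]) == ["1", "1", "0"]
        assert len(audit) == len(plan.modifications)

    def test_dangling_reference_names_modification(self):
        m = make_matrix({"a": {"f": "1"}, "b": {"f": "0"}},
                        binary_features(["f"]))
        plan = RecodePlan([Modification("bad-mod", "design", "exclude",
                                        ["ghost"], [])])
        with pytest.raises(PlanError, match="bad-mod"):
            apply_plan(m, plan)

    def test_postfilter_drops_invariable_feature(self):
        rows = {f"t{i}": {"f": "1" if i else "0", "g": "1"} for i in range(10)}
        m = make_matrix(rows, binary_features(["f", "g"]))
        out, audit = apply_plan(m, RecodePlan([]), min_coding=1,
                                min_variability=3)
        assert "g" not in out.feature_ids  # single attested state
        assert "f" not in out.feature_ids  # second state count 1 < 3


class TestNaming:
    @pytest.mark.parametrize(
        "bases, trail, scheme, kwargs, expected",
        [
            (["GB046"], [], "GBI", {}, "GB046"),
            (["GB553"], ["drm", "c"], "GBI", {}, "GB553drmc"),
            (["GB058"], ["C"], "GBI", {}, "GB058C"),
            (["WALS_1A"], [], "TLI", {}, "o_WALS_1A"),
            (["WALS_93A"], ["e"], "TLI", {}, "rec_e_WALS_93A"),
            (["WALS_110A"], ["d", "a"], "TLI", {"decompose_index": 1},
             "rec_da_WALS_110A_1"),
            (["WALS_10A", "PHOIBLE_BAF_nasalizedVowels_presence"], ["m"],
             "TLI", {},
             "rec_m+WALS_10A+PHOIBLE_BAF_nasalizedVowels_presence"),
            (["lexibank_TreeInBark", "lexibank_BarkAndSkin"], ["EON"], "TLI",
             {}, "rec_EON+lexibank_TreeInBark+lexibank_BarkAndSkin"),
        ],
    )
    def test_conventions(self, bases, trail, scheme, kwargs, expected):
        assert name_feature(bases, trail, scheme, **kwargs) == expected
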