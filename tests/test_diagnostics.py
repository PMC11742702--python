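import math

import numpy as np
import pandas as pd
import pytest

from lingcurate.core import FeatureDef, Taxon, taxonomy_frame
from lingcurate.diagnostics import (
    assign_to_grid,
    entropy_diff,
    entropy_map,
    family_proportions,
    fibonacci_grid,
    nipals_pca,
    normalized_entropy,
    ordination_compare,
)
from lingcurate.recode import apply_plan

from conftest import binary_features, make_matrix


class TestNormalizedEntropy:
    def test_single_state_is_zero(self):
        assert normalized_entropy({"A": 5}, 2) == 0.0

    def test_uniform_two_state_is_one(self):
        assert normalized_entropy({"A": 2, "B": 2}, 2) == pytest.approx(1.0)

    def test_three_one_split(self):
        assert normalized_entropy({"A": 3, "B": 1}, 2) == pytest.approx(
            0.8113, abs=1e-4)

    def test_no_coded_taxa_undefined(self):
        assert normalized_entropy({}, 2) is None

    def test_degenerate_state_space_rejected(self):
        with pytest.raises(ValueError):
            normalized_entropy({"A": 1}, 1)

    def test_relabeling_invariant(self):
        a = normalized_entropy({"A": 3, "B": 7, "C": 2}, 3)
        b = normalized_entropy({"x": 7, "y": 2, "z": 3}, 3)
        assert a == pytest.approx(b)


def grid_assignment(taxa, gid="g0"):
    return pd.Series(gid, index=taxa)


class TestEntropyMap:
    def test_identical_taxa_give_zero(self):
        m = make_matrix({t: {"f": "1", "g": "0"} for t in "abc"},
                        binary_features(["f", "g"]))
        emap = entropy_map(m, grid_assignment(list("abc")))
        assert emap.loc["g0", "mean_entropy"] == 0.0

    def test_sparse_feature_skipped(self):
        m = make_matrix(
            {"a": {"f": "1", "g": "1"}, "b": {"f": "?", "g": "0"},
             "c": {"f": "?", "g": "1"}},
            binary_features(["f", "g"]))
        emap = entropy_map(m, grid_assignment(list("abc")))
        # f coded 1/3 <= 0.5 -> only g contributes
        assert emap.loc["g0", "n_features"] == 1

    def test_mean_of_zero_and_one(self):
        m = make_matrix(
            {"a": {"f": "1", "g": "1"}, "b": {"f": "1", "g": "0"}},
            binary_features(["f", "g"]))
        emap = entropy_map(m, grid_assignment(list("ab")))
        assert emap.loc["g0", "mean_entropy"] == pytest.approx(0.5)

    def test_min_taxa_rule(self):
        m = make_matrix({"a": {"f": "1"}}, binary_features(["f"]))
        emap = entropy_map(m, grid_assignment(["a"]))
        assert emap.empty

    def test_taxon_order_invariant(self):
        rows = {f"t{i}": {"f": "1" if i % 2 else "0"} for i in range(6)}
        m1 = make_matrix(rows, binary_features(["f"]))
        m2 = m1.subset(taxa=list(reversed(m1.taxa)))
        a = entropy_map(m1, grid_assignment(m1.taxa))
        b = entropy_map(m2, grid_assignment(m2.taxa))
        assert a.equals(b)


class TestEntropyDiff:
    def test_self_difference_is_zero(self):
        m = make_matrix({t: {"f": "1" if i % 2 else "0"}
                         for i, t in enumerate("abcd")},
                        binary_features(["f"]))
        emap = entropy_map(m, grid_assignment(list("abcd")))
        assert (entropy_diff(emap, emap) == 0).all()

    def test_disjoint_grids_error(self):
        df1 = pd.DataFrame({"mean_entropy": [0.5]}, index=["g0"])
        df2 = pd.DataFrame({"mean_entropy": [0.5]}, index=["g1"])
        with pytest.raises(ValueError):
            entropy_diff(df1, df2)

    def test_meta_recoding_raises_local_entropy(self, gender_fixture):
        """A locally invariant all-absent block no longer drags the mean
        entropy down once it is recoded to one meta-feature + NA cells."""
        m, plan = gender_fixture
        varied = pd.Series(["1", "0", "1", "0", "1", "0"], index=m.taxa,
                           dtype=object)
        m = m.with_column(FeatureDef(id="v", states=("1", "0")), varied)
        # restrict to taxa where the block is uniformly absent
        absent = ["t2", "t3", "t6"]
        before = entropy_map(m.subset(taxa=absent),
                             grid_assignment(absent))
        curated, _ = apply_plan(m, plan, enforce_filters=False)
        after = entropy_map(curated.subset(taxa=absent),
                            grid_assignment(absent))
        diff = entropy_diff(after, before)
        assert (diff > 0).all()


class TestFamilyProportions:
    def test_worked_example(self):
        # one family, binary feature 3x"1" vs 1x"0"; "1" dropped as most
        # frequent -> single column for state 0 with value 1/4
        m = make_matrix({t: {"f": "1"} for t in "abc"} | {"d": {"f": "0"}},
                        binary_features(["f"]))
        tax = taxonomy_frame([Taxon(t, "fam", "Africa") for t in "abcd"])
        table = family_proportions(m, tax)
        assert list(table.columns) == ["f=0"]
        assert table.loc["fam", "f=0"] == pytest.approx(0.25)

    def test_uncoded_family_missing_cell(self):
        m = make_matrix(
            {"a": {"f": "1"}, "b": {"f": "0"}, "c": {"f": "?"}},
            binary_features(["f"]))
        tax = taxonomy_frame([Taxon("a", "famA", "Africa"),
                              Taxon("b", "famA", "Africa"),
                              Taxon("c", "famB", "Africa")])
        table = family_proportions(m, tax)
        assert math.isnan(table.loc["famB"].iloc[0])

    def test_column_count_is_states_minus_one_per_feature(self):
        m = make_matrix(
            {"a": {"f": "1", "g": "x"}, "b": {"f": "0", "g": "y"},
             "c": {"f": "1", "g": "z"}},
            {"f": FeatureDef(id="f", states=("1", "0")),
             "g": FeatureDef(id="g", states=("x", "y", "z"))})
        tax = taxonomy_frame([Taxon(t, f"fam{t}", "Africa") for t in "abc"])
        table = family_proportions(m, tax)
        assert table.shape[1] == (2 - 1) + (3 - 1)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(9)
        rows = {f"t{i}": {"f": rng.choice(["1", "0", "?"]),
                          "g": rng.choice(["1", "0"])} for i in range(30)}
        m = make_matrix(rows, binary_features(["f", "g"]))
        tax = taxonomy_frame([Taxon(t, f"fam{i % 5}", "Africa")
                              for i, t in enumerate(m.taxa)])
        table = family_proportions(m, tax)
        vals = table.to_numpy(float)
        vals = vals[~np.isnan(vals)]
        assert ((vals >= 0) & (vals <= 1)).all()


def random_proportion_table(n_families=50, n_cols=12, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.random((n_families, 3)) @ rng.random((3, n_cols))
    base += 0.05 * rng.random((n_families, n_cols))
    return pd.DataFrame(base, index=[f"fam{i:02d}" for i in range(n_families)],
                        columns=[f"c{j}" for j in range(n_cols)])


class TestOrdination:
    def test_table_against_itself(self):
        t = random_proportion_table()
        corr = ordination_compare(t, t)
        assert np.allclose(corr, 1.0, atol=1e-6)

    def test_masked_cells_preserve_components(self):
        t = random_proportion_table(seed=1)
        rng = np.random.default_rng(2)
        masked = t.copy()
        mask = rng.random(t.shape) < 0.10
        masked = masked.mask(mask)
        corr = ordination_compare(t, masked)
        assert (corr > 0.9).all()

    def test_row_order_invariance(self):
        t = random_proportion_table(seed=3)
        shuffled = t.sample(frac=1.0, random_state=0)
        a = ordination_compare(t, t)
        b = ordination_compare(t, shuffled)
        assert np.allclose(a, b, atol=1e-6)

    def test_too_few_shared_families(self):
        t = random_proportion_table(n_families=4)
        with pytest.raises(ValueError):
            ordination_compare(t, t)

    def test_nipals_matches_svd_on_complete_data(self):
        t = random_proportion_table(seed=5).to_numpy()
        T, P = nipals_pca(t, 2)
        centered = t - t.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        svd_scores = centered @ vt[:2].T
        for i in range(2):
            r = abs(np.corrcoef(T[:, i], svd_scores[:, i])[0, 1])
            assert r > 0.999


def test_grid_assignment_unique_and_total():
    grid = fibonacci_grid(100)
    tax = taxonomy_frame([
        Taxon("a", "f1", "Africa", lat=10.0, lon=20.0),
        Taxon("b", "f2", "Africa", lat=-30.0, lon=150.0),
        Taxon("c", "f3", "Africa", lat=None, lon=None),
    ])
    assigned = assign_to_grid(tax, grid)
    assert set(assigned.index) == {"a", "b"}  # no coordinates -> unassigned
    assert assigned.isin(grid.index).all()
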