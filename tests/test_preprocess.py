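"""Filtering rules, split sizes, transform semantics, leakage audit."""

import numpy as np
import pandas as pd
import pytest

from aggnet import preprocess as pre
from aggnet.preprocess import (
    FeatureTable,
    ItemMeta,
    PreprocessPlan,
    apply_transform,
    filter_items,
    filter_participants,
    fit_transform,
    make_splits,
)


def _table(values: dict, types: dict | None = None) -> FeatureTable:
    df = pd.DataFrame(values)
    types = types or {}
    dictionary = {
        c: ItemMeta("s1", types.get(c, "numeric"), "feature") for c in df.columns
    }
    return FeatureTable(df, dictionary)


class TestFilterItems:
    def test_item_strictly_above_threshold_removed(self):
        n = 100
        vals = {"a": np.arange(n, dtype=float), "b": np.arange(n, dtype=float)}
        vals["a"][:26] = np.nan  # 26% missing
        table = _table(vals)
        out, log = filter_items(table, PreprocessPlan())
        assert out.items == ["b"]
        assert log["removed_high_missing"] == ["a"]

    def test_item_exactly_at_threshold_retained(self):
        n = 100
        vals = {"a": np.arange(n, dtype=float)}
        vals["a"][:25] = np.nan  # exactly 25%
        out, _ = filter_items(_table(vals), PreprocessPlan())
        assert out.items == ["a"]

    def test_string_items_removed(self):
        table = _table(
            {"a": [1.0, 2.0], "txt": ["x", "y"]}, types={"txt": "string"}
        )
        out, log = filter_items(table, PreprocessPlan())
        assert out.items == ["a"]
        assert log["removed_string"] == ["txt"]

    def test_complete_table_unchanged(self):
        table = _table({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out, log = filter_items(table, PreprocessPlan())
        assert out.items == ["a", "b"]
        assert log["n_kept"] == 2


class TestFilterParticipants:
    def _cohort(self, n=100):
        rng = np.random.default_rng(0)
        feats = {f"f{i}": rng.standard_normal(n) for i in range(40)}
        feats["age"] = rng.uniform(15, 24, n)
        feats["sex"] = np.array(["male", "female"] * (n // 2), dtype=object)
        table = _table(feats, types={"sex": "nominal"})
        outcomes = pd.DataFrame({"y1": rng.standard_normal(n), "y2": rng.standard_normal(n)})
        return table, outcomes

    def test_missing_outcome_item_excludes_participant(self):
        table, outcomes = self._cohort()
        outcomes.loc[3, "y2"] = np.nan
        out, o2, log = filter_participants(table, outcomes, PreprocessPlan(min_participants=5))
        assert 3 not in out.values.index
        assert log["n_missing_outcome"] == 1

    def test_modest_feature_missingness_retained(self):
        table, outcomes = self._cohort()
        # 1 of 40 features missing = 2.5% < 5%
        table.values.loc[7, "f0"] = np.nan
        out, _, _ = filter_participants(table, outcomes, PreprocessPlan(min_participants=5))
        assert 7 in out.values.index

    def test_sparse_participant_excluded(self):
        table, outcomes = self._cohort()
        table.values.loc[9, [f"f{i}" for i in range(10)]] = np.nan  # 25%
        out, _, log = filter_participants(table, outcomes, PreprocessPlan(min_participants=5))
        assert 9 not in out.values.index
        assert log["n_sparse"] == 1

    def test_complete_cohort_has_no_exclusions(self):
        table, outcomes = self._cohort()
        out, _, log = filter_participants(table, outcomes, PreprocessPlan(min_participants=5))
        assert log["n_excluded"] == 0
        assert len(out.values) == len(table.values)

    def test_missing_age_or_sex_excludes(self):
        table, outcomes = self._cohort()
        table.values.loc[2, "age"] = np.nan
        out, _, log = filter_participants(table, outcomes, PreprocessPlan(min_participants=5))
        assert 2 not in out.values.index
        assert log["n_missing_critical"] == 1


class TestMakeSplits:
    def test_study_scale_split_sizes(self):
        plan = make_splits(2184, seed=0, n_repeats=2)
        assert len(plan.discovery_idx) == 1638
        assert len(plan.holdout_idx) == 546

    def test_small_n_floor_rule(self):
        plan = make_splits(8, seed=0, n_repeats=1)
        assert len(plan.discovery_idx) == 6
        assert len(plan.holdout_idx) == 2

    def test_same_seed_gives_identical_plan(self):
        a = make_splits(200, seed=5, n_repeats=4)
        b = make_splits(200, seed=5, n_repeats=4)
        np.testing.assert_array_equal(a.discovery_idx, b.discovery_idx)
        for (t1, e1), (t2, e2) in zip(a.repeat_splits, b.repeat_splits):
            np.testing.assert_array_equal(t1, t2)
            np.testing.assert_array_equal(e1, e2)

    def test_partitions_are_disjoint_and_exhaustive(self):
        plan = make_splits(101, seed=2, n_repeats=5)
        all_idx = np.sort(np.concatenate([plan.discovery_idx, plan.holdout_idx]))
        np.testing.assert_array_equal(all_idx, np.arange(101))
        n_disc = len(plan.discovery_idx)
        for tr, te in plan.repeat_splits:
            assert np.intersect1d(tr, te).size == 0
            assert len(tr) + len(te) == n_disc

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_splits(100, discovery_frac=1.5)

    def test_roundtrip_json(self, tmp_path):
        plan = make_splits(50, seed=1, n_repeats=2)
        path = tmp_path / "splits.json"
        plan.to_json(path)
        back = pre.SplitPlan.from_json(path)
        np.testing.assert_array_equal(back.holdout_idx, plan.holdout_idx)


class TestTransform:
    def test_dummy_coding_full_indicator_set(self):
        table = _table({"cat": ["A", "B", "A", "B"]}, types={"cat": "nominal"})
        X, dmap = pre.encode(table)
        assert list(X.columns) == ["cat=A", "cat=B"]
        np.testing.assert_array_equal(X["cat=A"], [1, 0, 1, 0])
        np.testing.assert_array_equal(X["cat=B"], [0, 1, 0, 1])

    def test_unseen_category_maps_to_all_zero(self):
        train = _table({"cat": ["A", "B", "A", "B"] * 5, "x": list(np.arange(20.0))},
                       types={"cat": "nominal"})
        ft, _ = fit_transform(train, PreprocessPlan())
        new = _table({"cat": ["C", "A"], "x": [1.0, 2.0]}, types={"cat": "nominal"})
        Z = apply_transform(ft, new)
        # unseen category C: both indicator columns at the (standardized) zero level
        raw_zero_a = (0.0 - ft.center[ft.kept_items.index("cat=A")]) / ft.scale[
            ft.kept_items.index("cat=A")
        ]
        assert Z.iloc[0]["cat=A"] == pytest.approx(raw_zero_a)

    def test_constant_column_dropped(self):
        train = _table({"c": np.ones(30), "x": np.arange(30.0)})
        ft, X = fit_transform(train, PreprocessPlan())
        assert "c" not in X.columns
        assert "c" in ft.dropped_items

    def test_training_columns_standardized(self):
        rng = np.random.default_rng(3)
        train = _table({f"f{i}": rng.standard_normal(60) * (i + 1) for i in range(4)})
        _, X = fit_transform(train, PreprocessPlan())
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(X.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_apply_on_train_reproduces_fitted_design(self):
        rng = np.random.default_rng(4)
        vals = {f"f{i}": rng.standard_normal(50) for i in range(5)}
        vals["f0"][::9] = np.nan
        train = _table(vals)
        ft, X_fit = fit_transform(train, PreprocessPlan(knn_k=5))
        X_again = apply_transform(ft, train)
        np.testing.assert_allclose(X_fit.to_numpy(), X_again.to_numpy(), atol=1e-12)

    def test_knn_imputes_mean_of_identical_neighbors(self):
        # one column all 7s except a missing cell: every neighbor holds 7, so
        # the imputed standardized value must equal the neighbors' value
        rng = np.random.default_rng(5)
        n = 30
        vals = {"a": rng.standard_normal(n), "b": rng.standard_normal(n)}
        vals["m"] = np.concatenate([[np.nan], np.full(n - 1, 7.0) + rng.standard_normal(n - 1) * 0.0])
        # give column m some variance so it is kept: add distinct values far away
        vals["m"][-3:] = [6.0, 8.0, 7.5]
        train = _table(vals)
        ft, X = fit_transform(train, PreprocessPlan(knn_k=5))
        col = X["m"].to_numpy()
        seven_std = (7.0 - ft.center[ft.kept_items.index("m")]) / ft.scale[
            ft.kept_items.index("m")
        ]
        assert col[0] == pytest.approx(seven_std, abs=1e-9)

    def test_leakage_perturbing_heldout_rows_leaves_fit_unchanged(self):
        rng = np.random.default_rng(6)
        vals = {f"f{i}": rng.standard_normal(80) for i in range(6)}
        vals["f1"][::7] = np.nan
        full = _table(vals)
        train = full.subset_rows(full.values.index[:60])
        ft1, _ = fit_transform(train, PreprocessPlan(knn_k=5))
        # perturb the held-out rows and refit on the same training rows
        corrupted = {k: v.copy() for k, v in vals.items()}
        for k in corrupted:
            corrupted[k][60:] = 999.0
        full2 = _table(corrupted)
        ft2, _ = fit_transform(full2.subset_rows(full2.values.index[:60]), PreprocessPlan(knn_k=5))
        np.testing.assert_array_equal(ft1.center, ft2.center)
        np.testing.assert_array_equal(ft1.scale, ft2.scale)
        assert ft1.kept_items == ft2.kept_items
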