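"""Categorical expansion, imputation, normalization and splitting."""

import numpy as np
import pandas as pd
import pytest

from survarea import Preprocessor, SurvivalDataset, split_stratified
from survarea.preprocess import binarize_categoricals, impute_mean, normalize


class TestBinarize:
    def test_two_level_column(self):
        df = pd.DataFrame({"g": ["A", "B", "A"], "x": [1.0, 2.0, 3.0]})
        out, levels = binarize_categoricals(df, ["g"])
        assert list(out.columns) == ["g=A", "g=B", "x"]
        assert levels == {"g": ["A", "B"]}
        np.testing.assert_array_equal(out[["g=A", "g=B"]].sum(axis=1), [1, 1, 1])

    def test_missing_rows_get_all_zero_indicators(self):
        df = pd.DataFrame({"g": ["A", None, "B"]})
        out, _ = binarize_categoricals(df, ["g"])
        assert out.iloc[1].sum() == 0.0

    def test_three_levels_row_sums_one(self):
        df = pd.DataFrame({"g": list("ABCAB")})
        out, _ = binarize_categoricals(df, ["g"])
        assert out.shape[1] == 3
        np.testing.assert_array_equal(out.sum(axis=1), np.ones(5))

    def test_stored_levels_reused_on_new_data(self):
        df = pd.DataFrame({"g": ["A", "B"]})
        _, levels = binarize_categoricals(df, ["g"])
        new, _ = binarize_categoricals(pd.DataFrame({"g": ["B", "C"]}),
                                       ["g"], levels=levels)
        assert list(new.columns) == ["g=A", "g=B"]
        assert new.iloc[1].sum() == 0.0  # unseen level maps to all zeros

    def test_unknown_column_rejected(self):
        with pytest.raises(ValueError):
            binarize_categoricals(pd.DataFrame({"x": [1]}), ["nope"])


class TestImpute:
    def test_mean_of_observed(self):
        df = pd.DataFrame({"x": [1.0, np.nan, 3.0]})
        out, values = impute_mean(df)
        np.testing.assert_array_equal(out["x"], [1.0, 2.0, 3.0])
        assert values == {"x": 2.0}

    def test_no_missing_unchanged(self):
        df = pd.DataFrame({"x": [1.0, 2.0]})
        out, _ = impute_mean(df)
        pd.testing.assert_frame_equal(out, df)

    def test_stored_mean_applied(self):
        out, _ = impute_mean(pd.DataFrame({"x": [np.nan]}), {"x": 2.0})
        assert out["x"].iloc[0] == 2.0

    def test_all_missing_column_rejected(self):
        with pytest.raises(ValueError):
            impute_mean(pd.DataFrame({"x": [np.nan, np.nan]}))


class TestNormalize:
    def test_sample_sd_convention(self):
        out, _ = normalize(pd.DataFrame({"x": [0.0, 2.0]}))
        np.testing.assert_allclose(out["x"], [-0.7071067811865475, 0.7071067811865475])

    def test_fitted_columns_standardized(self, rng):
        df = pd.DataFrame({"x": rng.normal(5, 3, 100), "y": rng.uniform(size=100)})
        out, _ = normalize(df)
        for col in out:
            assert abs(out[col].mean()) < 1e-10
            assert abs(out[col].std(ddof=1) - 1) < 1e-10

    def test_constant_column_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out, (_, _, dropped) = normalize(
                pd.DataFrame({"c": [1.0, 1.0], "x": [0.0, 1.0]})
            )
        assert dropped == ["c"] and list(out.columns) == ["x"]

    def test_stored_params_replayed(self):
        train = pd.DataFrame({"x": [0.0, 2.0, 4.0]})
        _, params = normalize(train)
        out, _ = normalize(pd.DataFrame({"x": [2.0]}), params)
        assert out["x"].iloc[0] == 0.0


class TestPipeline:
    def test_composed_pipeline_is_numeric_and_complete(self):
        df = pd.DataFrame(
            {
                "g": ["A", "B", None, "A", "B", "A"],
                "x": [1.0, np.nan, 3.0, 4.0, 2.0, np.nan],
                "const": [7.0] * 6,
            }
        )
        pre = Preprocessor(categorical_columns=["g"])
        with pytest.warns(UserWarning):
            out = pre.fit_transform(df)
        assert not out.isna().any().any()
        assert out.select_dtypes(include=[np.number]).shape == out.shape
        assert "const" not in out.columns

    def test_no_leakage_train_params_fixed(self, rng):
        train = pd.DataFrame({"x": rng.normal(3, 2, 50)})
        test = pd.DataFrame({"x": rng.normal(100, 5, 20)})
        pre = Preprocessor()
        pre.fit_transform(train)
        before = dict(pre.params.means)
        transformed = pre.transform(test)
        assert pre.params.means == before
        # test-set transform uses train statistics, so test mean is far from 0
        assert abs(transformed["x"].mean()) > 5


class TestSplit:
    def make(self, n_censored, n_events):
        times = np.arange(1.0, n_censored + n_events + 1)
        events = np.array([0] * n_censored + [1] * n_events)
        return SurvivalDataset(times, events)

    def test_proportional_allocation(self):
        data = self.make(4, 4)
        train, test = split_stratified(data, 0.25, np.random.default_rng(0))
        assert len(test) == 2
        assert (test.events == 0).sum() == 1

    def test_fraction_zero_gives_no_test_set(self):
        train, test = split_stratified(self.make(3, 3), 0.0,
                                       np.random.default_rng(0))
        assert test is None and len(train) == 6

    def test_seeded_reproducibility(self):
        data = self.make(20, 30)
        a = split_stratified(data, 0.25, np.random.default_rng(4))[1]
        b = split_stratified(data, 0.25, np.random.default_rng(4))[1]
        np.testing.assert_array_equal(a.times, b.times)

    def test_partition_disjoint_and_exhaustive(self):
        data = self.make(30, 50)
        train, test = split_stratified(data, 0.25, np.random.default_rng(1))
        combined = np.sort(np.concatenate([train.times, test.times]))
        np.testing.assert_array_equal(combined, data.times)

    def test_censored_fraction_matches_within_one_subject(self):
        data = self.make(37, 63)
        train, test = split_stratified(data, 0.25, np.random.default_rng(2))
        overall = 0.37
        assert abs((test.events == 0).sum() - overall * len(test)) <= 1.0

    def test_tiny_stratum_warns(self):
        data = self.make(1, 9)
        with pytest.warns(UserWarning, match="best-effort"):
            split_stratified(data, 0.25, np.random.default_rng(3))
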