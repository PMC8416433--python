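"""Tabular preprocessing filters and class-imbalance resamplers."""

import numpy as np
import pandas as pd
import pytest

from dilipred.prep import (
    FeatureMatrix,
    ResampleConfig,
    correlation_filter,
    derive_reporting_ratios,
    drop_missing_rows,
    drop_zero_variance,
    rose_bandwidth,
    rose_resample,
    smote,
    standardize,
    upsample_minority,
)


def make_fm(x, y=None, name="t"):
    x = pd.DataFrame(x)
    x.index = [f"d{i}" for i in range(len(x))]
    if y is None:
        y = np.zeros(len(x), dtype=int)
        y[: len(x) // 2] = 1
    return FeatureMatrix(X=x, y=pd.Series(y, index=x.index), name=name)


class TestFilters:
    def test_constant_column_removed(self, rng):
        fm = make_fm({"a": rng.normal(size=10), "b": np.ones(10)})
        out = drop_zero_variance(fm)
        assert list(out.X.columns) == ["a"]
        assert out.log

    def test_no_constant_columns_identity(self, rng):
        fm = make_fm({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        assert drop_zero_variance(fm).X.equals(fm.X)

    def test_column_constant_after_missing_removal(self, rng):
        # pipeline order: drop missing rows first, then the column is constant
        x = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        x.loc[3, "b"] = np.nan
        x.loc[3, "a"] = np.nan
        fm = make_fm(x)
        out = drop_zero_variance(drop_missing_rows(fm))
        assert list(out.X.columns) == ["a"]

    def test_missing_rows_paper_scale_counts(self, rng):
        # 57 of 412 rows carry a missing cell -> 355 remain
        x = pd.DataFrame(rng.normal(size=(412, 6)))
        rows = rng.choice(412, size=57, replace=False)
        x.iloc[rows, 2] = np.nan
        out = drop_missing_rows(make_fm(x))
        assert len(out.X) == 355

    def test_single_missing_cell_drops_only_that_row(self, rng):
        x = pd.DataFrame(rng.normal(size=(5, 3)))
        x.iloc[2, 1] = np.nan
        out = drop_missing_rows(make_fm(x))
        assert len(out.X) == 4 and "d2" not in out.X.index

    def test_all_rows_missing_raises(self):
        fm = make_fm(pd.DataFrame({"a": [np.nan, np.nan]}))
        with pytest.raises(ValueError):
            drop_missing_rows(fm)


class TestCorrelationFilter:
    def test_duplicated_column_one_copy_removed(self, rng):
        a = rng.normal(size=50)
        fm = make_fm({"a": a, "b": a.copy(), "c": rng.normal(size=50)})
        out = correlation_filter(fm, cutoff=0.82)
        assert out.X.shape[1] == 2 and "c" in out.X.columns

    def test_uncorrelated_identity(self, rng):
        fm = make_fm(rng.normal(size=(100, 4)))
        out = correlation_filter(fm, cutoff=0.82)
        assert out.X.shape[1] == 4

    def test_three_mutual_duplicates_two_removed(self, rng):
        a = rng.normal(size=60)
        fm = make_fm({"a": a, "b": a + rng.normal(scale=1e-3, size=60),
                      "c": a + rng.normal(scale=1e-3, size=60),
                      "d": rng.normal(size=60)})
        out = correlation_filter(fm, cutoff=0.82)
        assert out.X.shape[1] == 2 and "d" in out.X.columns


class TestStandardize:
    def test_training_set_scaled_to_zero_one(self, rng):
        fm = make_fm(rng.normal(loc=5, scale=3, size=(50, 3)))
        out = standardize(fm, fm)
        np.testing.assert_allclose(out.X.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(out.X.std(ddof=1), 1, atol=1e-12)

    def test_train_statistics_reused_on_test(self, rng):
        train = make_fm(rng.normal(size=(50, 2)))
        shift = 2.5
        test = make_fm(train.X + shift)
        out = standardize(train, test)
        sd = train.X.std(ddof=1)
        expected = standardize(train, train).X + shift / sd
        np.testing.assert_allclose(out.X.to_numpy(), expected.to_numpy(), atol=1e-10)
        assert "training statistics" in out.log[-1]

    def test_zero_sd_column_raises(self, rng):
        fm = make_fm({"a": np.ones(10)})
        with pytest.raises(ValueError):
            standardize(fm, fm)


class TestReportingRatios:
    def _fm(self, dili_m, all_m, dili_f=(1.0,), all_f=(4.0,)):
        n = len(dili_m)
        return make_fm({
            "dili_events_male": dili_m, "all_events_male": all_m,
            "dili_events_female": list(dili_f) * n if len(dili_f) == 1 else dili_f,
            "all_events_female": list(all_f) * n if len(all_f) == 1 else all_f,
        }, y=[1] * (n // 2 + n % 2) + [0] * (n // 2))

    def test_equal_counts_give_ratio_one(self):
        out = derive_reporting_ratios(self._fm([7.0, 3.0], [7.0, 3.0]))
        assert (out.X["male_ratio"] == 1.0).all()

    def test_zero_dili_events_ratio_zero(self):
        out = derive_reporting_ratios(self._fm([0.0, 0.0], [10.0, 5.0]))
        assert (out.X["male_ratio"] == 0.0).all()

    def test_arithmetic_and_zero_over_zero(self):
        out = derive_reporting_ratios(self._fm([5.0, 0.0], [20.0, 0.0]))
        assert out.X["male_ratio"].tolist() == [0.25, 0.0]
        assert "zero-over-zero" in out.log[-1]

    def test_missing_column_names_the_mapping(self, rng):
        fm = make_fm(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError, match="dili_events_male"):
            derive_reporting_ratios(fm)


class TestUpsample:
    def test_paper_scale_counts_balanced(self, rng):
        x = rng.normal(size=(422, 3))
        y = np.array([1] * 96 + [0] * 326)
        out = upsample_minority(make_fm(x, y), ResampleConfig(method="upsample", seed=1))
        assert out.n_pos == 326 and out.n_neg == 326

    def test_already_balanced_identity(self, rng):
        fm = make_fm(rng.normal(size=(10, 2)))
        out = upsample_minority(fm, ResampleConfig(method="upsample", seed=1))
        assert out.X.equals(fm.X)

    def test_added_rows_duplicate_existing_minority_rows(self, rng):
        fm = make_fm(rng.normal(size=(20, 3)), y=[1] * 4 + [0] * 16)
        out = upsample_minority(fm, ResampleConfig(method="upsample", seed=3))
        originals = fm.X[fm.y == 1].to_numpy()
        added = out.X.iloc[len(fm.X):].to_numpy()
        for row in added:
            assert any(np.array_equal(row, o) for o in originals)

    def test_originals_untouched_and_deterministic(self, rng):
        fm = make_fm(rng.normal(size=(20, 3)), y=[1] * 4 + [0] * 16)
        cfg = ResampleConfig(method="upsample", seed=5)
        out1, out2 = upsample_minority(fm, cfg), upsample_minority(fm, cfg)
        assert out1.X.equals(out2.X)
        assert out1.X.iloc[: len(fm.X)].equals(fm.X)


class TestSmote:
    def test_two_minority_points_synthetics_on_segment(self):
        x = np.zeros((12, 2))
        x[0] = [0.0, 0.0]
        x[1] = [1.0, 2.0]
        x[2:] = np.random.default_rng(0).normal(loc=10, size=(10, 2))
        y = [1, 1] + [0] * 10
        out = smote(make_fm(x, y), ResampleConfig(method="smote", k_neighbors=1, seed=2))
        assert out.n_pos == out.n_neg == 10
        synth = out.X.iloc[12:].to_numpy()
        # on the segment: x = t * (1, 2) for t in [0, 1]
        t = synth[:, 0]
        np.testing.assert_allclose(synth[:, 1], 2 * t, atol=1e-12)
        assert ((t >= 0) & (t <= 1)).all()

    def test_synthetics_within_minority_bounding_box(self, rng):
        x = rng.normal(size=(60, 4))
        y = [1] * 12 + [0] * 48
        fm = make_fm(x, y)
        out = smote(fm, ResampleConfig(method="smote", seed=7))
        mins = fm.X[fm.y == 1].min()
        maxs = fm.X[fm.y == 1].max()
        synth = out.X.iloc[60:]
        assert ((synth >= mins - 1e-12) & (synth <= maxs + 1e-12)).all().all()

    def test_minority_of_one_rejected(self, rng):
        fm = make_fm(rng.normal(size=(10, 2)), y=[1] + [0] * 9)
        with pytest.raises(ValueError):
            smote(fm, ResampleConfig(method="smote", seed=1))

    def test_k_reduced_when_minority_small(self, rng):
        fm = make_fm(rng.normal(size=(20, 2)), y=[1] * 3 + [0] * 17)
        out = smote(fm, ResampleConfig(method="smote", k_neighbors=5, seed=1))
        assert out.n_pos == out.n_neg == 17


class TestRose:
    def test_zero_shrink_gives_exact_copies(self, rng):
        fm = make_fm(rng.normal(size=(30, 3)), y=[1] * 10 + [0] * 20)
        out = rose_resample(fm, ResampleConfig(method="rose", seed=4, shrink=0.0))
        originals = fm.X.to_numpy()
        for row in out.X.to_numpy():
            assert any(np.allclose(row, o) for o in originals)

    def test_class_proportion_half_in_expectation(self, rng):
        fm = make_fm(rng.normal(size=(40, 2)), y=[1] * 8 + [0] * 32)
        out = rose_resample(fm, ResampleConfig(method="rose", seed=9), n_out=10000)
        frac = out.y.mean()
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(10000)

    def test_synthetic_variance_matches_convolution(self, rng):
        # Var(synthetic) = sigma^2 (bootstrap) + h^2 (kernel), per feature
        fm = make_fm(rng.normal(scale=2.0, size=(200, 3)), y=[1] * 100 + [0] * 100)
        out = rose_resample(fm, ResampleConfig(method="rose", seed=13), n_out=20000)
        x_pos = fm.X[fm.y == 1].to_numpy()
        h = rose_bandwidth(x_pos)
        sigma = x_pos.std(axis=0, ddof=1)
        expected_sd = np.sqrt(sigma**2 + h**2)
        observed_sd = out.X[out.y == 1].std(ddof=1).to_numpy()
        np.testing.assert_allclose(observed_sd, expected_sd, rtol=0.08)

    def test_single_row_class_rejected(self, rng):
        fm = make_fm(rng.normal(size=(5, 2)), y=[1] + [0] * 4)
        with pytest.raises(ValueError):
            rose_resample(fm, ResampleConfig(method="rose", seed=1))
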