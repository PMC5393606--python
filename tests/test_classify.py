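"""Covariate extraction, tuning, RFE, weighted SVM, LGOCV, map prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ecosite as es
from ecosite.classify import SampleSet, _importance_scores
from tests.conftest import bind_samples


def make_samples(stack, pixels, labels, states=None):
    states = states or [1] * len(pixels)
    rows = []
    for i, ((r, c), lab, s) in enumerate(zip(pixels, labels, states)):
        x, y = stack.transform.xy(r, c)
        rows.append(
            {"id": f"s{i}", "x": float(x), "y": float(y), "row": r, "col": c,
             "es_class": lab, "state_code": s}
        )
    return SampleSet(pd.DataFrame(rows))


def gaussian_clouds(n_per_class, n_features=6, shift=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 1, (n_per_class, n_features)), rng.normal(shift, 1, (n_per_class, n_features))]
    )
    y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    return pd.DataFrame(X), y


class TestExtractCovariates:
    def test_row_equals_pixel_series(self, small_scene):
        _, stack, _ = small_scene
        samples = make_samples(stack, [(0, 0)], ["Clayey"])
        table = es.extract_covariates(stack, samples)
        np.testing.assert_array_equal(table.iloc[0].values, stack.values[:, 0, 0])
        assert list(table.columns) == list(stack.dates.strftime("%Y-%m-%d"))

    def test_shared_pixel_identical_rows(self, small_scene):
        _, stack, _ = small_scene
        samples = make_samples(stack, [(2, 3), (2, 3)], ["Clayey", "Loamy"])
        table = es.extract_covariates(stack, samples)
        np.testing.assert_array_equal(table.iloc[0].values, table.iloc[1].values)

    def test_full_study_dimensions(self, rng):
        """176 samples on a 628-step grid give a 176 x 628 table."""
        grid = es.build_time_grid("1984-05-21", "2011-11-08", 16)
        values = rng.normal(0.3, 0.05, (628, 6, 6))
        stack = es.NDVIStack(values=values, mask=np.zeros_like(values, bool), dates=grid)
        pixels = [(int(r), int(c)) for r, c in rng.integers(0, 6, (176, 2))]
        samples = make_samples(stack, pixels, ["Sandy"] * 176)
        assert es.extract_covariates(stack, samples).shape == (176, 628)

    def test_out_of_bounds_pixel_names_sample(self, small_scene):
        _, stack, _ = small_scene
        samples = make_samples(stack, [(0, 0)], ["Clayey"])
        samples.frame.loc[0, "row"] = 99
        with pytest.raises(ValueError, match="s0"):
            es.extract_covariates(stack, samples)


def test_inverse_frequency_weights():
    w = es.inverse_frequency_weights(["a"] * 9 + ["b"])
    assert w["b"] / w["a"] == pytest.approx(9.0)
    assert np.mean(list(w.values())) == pytest.approx(1.0)


class TestTuneSvm:
    def test_single_point_grid(self):
        X, y = gaussian_clouds(20)
        C, gamma, table = es.tune_svm(X, y, C_grid=[2.0], gamma_grid=[0.5], cv_folds=3, seed=0)
        assert (C, gamma) == (2.0, 0.5)
        assert len(table) == 1

    def test_separable_clouds_reach_high_pcc(self):
        X, y = gaussian_clouds(100)
        _, _, table = es.tune_svm(
            X, y, C_grid=[1.0, 10.0], gamma_grid=[0.01, 0.1], cv_folds=5, seed=0
        )
        assert table["cv_pcc"].max() >= 95.0

    def test_tie_breaks_toward_smallest(self):
        X, y = gaussian_clouds(50, shift=8.0)  # trivially separable: all tie
        C, gamma, _ = es.tune_svm(
            X, y, C_grid=[8.0, 1.0, 2.0], gamma_grid=[0.2, 0.05], cv_folds=3, seed=0
        )
        assert (C, gamma) == (1.0, 0.05)

    def test_single_class_rejected(self):
        X, _ = gaussian_clouds(10)
        with pytest.raises(ValueError):
            es.tune_svm(X, ["a"] * len(X), cv_folds=2)


class TestRfe:
    def test_iteration_size_schedule(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (40, 60)))
        y = np.array(["a", "b"] * 20)
        result = es.rfe(X, y, step=10, cv_folds=2, seed=0)
        assert result.sizes == [60, 50, 40, 30, 20, 10]

    def test_ranking_is_permutation(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (40, 25)))
        y = np.array(["a", "b"] * 20)
        result = es.rfe(X, y, step=5, cv_folds=2, seed=0)
        assert sorted(result.ranking.values) == list(range(1, 26))

    def test_planted_informative_covariates_recovered(self):
        rng = np.random.default_rng(3)
        n = 60
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        X = rng.normal(0, 1, (n, 60))
        informative = [5, 20, 40]
        for j in informative:
            X[y == "b", j] += 3.0  # 3 SD class shift
        result = es.rfe(pd.DataFrame(X), y, step=10, cv_folds=3, seed=0)
        assert set(informative) <= set(result.selected)

    def test_constant_covariates_rank_worse_than_informative(self):
        rng = np.random.default_rng(0)
        y = np.array(["a"] * 20 + ["b"] * 20)
        X = rng.normal(0, 1, (40, 10))
        X[:, 3] = 0.7  # zero variance
        X[y == "b", 7] += 4.0  # informative
        scores = _importance_scores(X, y)
        assert scores[3] == 0.0
        assert scores[7] > scores[3]
        result = es.rfe(pd.DataFrame(X), y, step=2, cv_folds=2, seed=0)
        assert result.ranking[3] > result.ranking[7]

    def test_oversized_step_rejected(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (20, 5)))
        with pytest.raises(ValueError):
            es.rfe(X, ["a", "b"] * 10, step=6)


class TestFitSvm:
    def test_separable_training_is_perfect(self):
        X, y = gaussian_clouds(30)
        model = es.fit_svm(X, y, C=4.0, gamma="scale")
        assert (model.predict(X) == y).all()

    def test_determinism(self):
        X, y = gaussian_clouds(30, shift=1.5)
        a = es.fit_svm(X, y, C=2.0, gamma="scale").predict(X)
        b = es.fit_svm(X, y, C=2.0, gamma="scale").predict(X)
        np.testing.assert_array_equal(a, b)

    def test_nan_rejected(self):
        X, y = gaussian_clouds(10)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            es.fit_svm(X, y)

    def test_weights_lift_minority_producers_accuracy(self):
        """Inverse-frequency weighting beats no weighting for the rare class."""
        better = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_major, n_minor = 90, 10
            X = np.vstack(
                [rng.normal(0, 1.2, (n_major, 2)), rng.normal(1.6, 1.2, (n_minor, 2))]
            )
            y = np.array(["maj"] * n_major + ["min"] * n_minor)
            test_X = np.vstack(
                [rng.normal(0, 1.2, (60, 2)), rng.normal(1.6, 1.2, (60, 2))]
            )
            test_y = np.array(["maj"] * 60 + ["min"] * 60)
            weights = es.inverse_frequency_weights(y)
            pa = {}
            for w in (None, weights):
                model = es.fit_svm(pd.DataFrame(X), y, C=1.0, gamma="scale", class_weights=w)
                pred = model.predict(test_X)
                pa[w is None] = np.mean(pred[test_y == "min"] == "min")
            if pa[False] > pa[True]:
                better += 1
        assert better >= 14  # majority of paired runs


class TestLgocv:
    def test_single_rep_matrix_total(self):
        X, y = gaussian_clouds(20)
        matrix, per_rep = es.lgocv(X, y, reps=1, test_frac=0.3, seed=0)
        assert matrix.total == round(0.3 * len(y))
        assert len(per_rep) == 1

    def test_pooled_total_at_study_scale(self):
        """176 samples, 100 repeats of a 30% hold-out pool 5,300 values."""
        rng = np.random.default_rng(0)
        n = 176
        y = np.array(["a"] * 86 + ["b"] * 16 + ["c"] * 32 + ["d"] * 37 + ["e"] * 5)
        X = rng.normal(0, 1, (n, 4)) + (pd.factorize(y)[0][:, None] * 3.0)
        matrix, _ = es.lgocv(pd.DataFrame(X), y, reps=100, test_frac=0.30, seed=1)
        assert matrix.total == 100 * round(0.30 * 176)  # 5,300

    def test_reference_marginals_match_class_frequencies(self):
        """Pooled reference marginal is consistent with class shares."""
        rng = np.random.default_rng(5)
        y = np.array(["a"] * 60 + ["b"] * 30 + ["c"] * 10)
        X = rng.normal(0, 1, (100, 3)) + (pd.factorize(y)[0][:, None] * 4.0)
        matrix, _ = es.lgocv(pd.DataFrame(X), y, reps=100, test_frac=0.3, seed=2)
        observed = matrix.counts.sum(axis=0).values
        expected = matrix.total * np.array([0.6, 0.3, 0.1])
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=2) * 3  # generous: reps correlate

    def test_tiny_class_rejected(self):
        X, y = gaussian_clouds(10)
        y = y.copy()
        y[0] = "c"  # singleton class
        with pytest.raises(ValueError, match="fewer than 2"):
            es.lgocv(X, y, reps=2)

    def test_seeded_determinism(self):
        X, y = gaussian_clouds(25, shift=1.0)
        m1, p1 = es.lgocv(X, y, reps=5, seed=11)
        m2, p2 = es.lgocv(X, y, reps=5, seed=11)
        assert m1.counts.equals(m2.counts) and p1 == p2


class TestPredictMap:
    def test_uniform_stack_single_class(self, small_scene, decade_grid):
        _, stack, _ = small_scene
        samples = make_samples(stack, [(0, 0), (0, 1), (9, 9), (9, 8)],
                               ["Clayey", "Clayey", "Deep sand", "Deep sand"])
        table = es.extract_covariates(stack, samples)
        model = es.fit_svm(table, samples.labels, C=4.0, gamma="scale")
        uniform = es.NDVIStack(
            values=np.broadcast_to(stack.values[:, :1, :1], stack.shape).copy(),
            mask=np.zeros(stack.shape, bool),
            dates=stack.dates,
        )
        raster = es.predict_map(model, uniform)
        assert len(np.unique(raster)) == 1

    def test_pixel_order_invariance(self, small_scene):
        config, stack, truth = small_scene
        frame = es.draw_samples(truth, 8, seed=2)
        samples = bind_samples(frame, config.transform)
        table = es.extract_covariates(stack, samples)
        model = es.fit_svm(table, samples.labels, C=4.0, gamma="scale")
        raster = es.predict_map(model, stack)
        # shuffle columns of the scene and predict again
        order = np.random.default_rng(0).permutation(stack.n_cols)
        shuffled = es.NDVIStack(
            values=stack.values[:, :, order], mask=stack.mask[:, :, order], dates=stack.dates
        )
        np.testing.assert_array_equal(es.predict_map(model, shuffled), raster[:, order])

    def test_date_grid_mismatch_rejected(self, small_scene):
        _, stack, _ = small_scene
        samples = make_samples(stack, [(0, 0), (5, 5)], ["Clayey", "Sandy"])
        table = es.extract_covariates(stack, samples)
        model = es.fit_svm(table, samples.labels)
        short = es.NDVIStack(
            values=stack.values[:-5], mask=stack.mask[:-5], dates=stack.dates[:-5]
        )
        with pytest.raises(ValueError, match="covariate dates"):
            es.predict_map(model, short)
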