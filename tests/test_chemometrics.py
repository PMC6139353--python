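"""Kennard-Stone splitting, grid-searched calibration and the metrics."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ramanlre import simulate as sim
from ramanlre.chemometrics import (
    BenchmarkConfig,
    ModelSpec,
    fit_predict,
    grid_search_cv,
    kennard_stone_split,
    quantitation_limit,
    regression_metrics,
    run_benchmark,
)


def kennard_stone_oracle(X, n_train):
    """Independent brute-force restatement of the greedy maximin rule."""
    d = cdist(X, X)
    n = len(X)
    best, pair = -1.0, None
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > best:
                best, pair = d[i, j], (i, j)
    chosen = list(pair)
    while len(chosen) < n_train:
        cand_best, cand = -1.0, None
        for i in range(n):
            if i in chosen:
                continue
            score = min(d[i, j] for j in chosen)
            if score > cand_best:
                cand_best, cand = score, i
        chosen.append(cand)
    return chosen


def linear_dataset(rng, n=40, channels=60, components=3, noise=0.0):
    P = rng.uniform(0.5, 2.0, (components, channels))
    C = rng.dirichlet(np.ones(components), size=n)
    X = C @ P + noise * rng.standard_normal((n, channels))
    return X, C


class TestKennardStone:
    def test_all_samples_in_train(self):
        X = np.arange(10.0).reshape(5, 2)
        split = kennard_stone_split(X, 5)
        assert sorted(split.train_indices) == [0, 1, 2, 3, 4]
        assert split.test_indices == ()

    def test_collinear_extremes_selected_first(self):
        X = np.array([[0.0], [1.0], [10.0]])
        split = kennard_stone_split(X, 2)
        assert set(split.train_indices) == {0, 2}
        assert split.test_indices == (1,)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            X = rng.standard_normal((8, 2))
            split = kennard_stone_split(X, 4)
            assert list(split.train_indices) == kennard_stone_oracle(X, 4)

    def test_disjoint_and_covering(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 5))
        split = kennard_stone_split(X, 20)
        assert set(split.train_indices) | set(split.test_indices) == set(range(30))
        assert not set(split.train_indices) & set(split.test_indices)


class TestGridSearch:
    def test_single_point_grid(self):
        rng = np.random.default_rng(1)
        X, C = linear_dataset(rng)
        spec = ModelSpec(pls_components_grid=(4,), cv_folds=3)
        assert grid_search_cv(X, C, spec)["n_components"] == 4

    def test_noise_free_linear_data_picks_low_rank(self):
        """CV-RMSE flattens at the true mixing rank, so the tie rule keeps
        the model small."""
        rng = np.random.default_rng(7)
        X, C = linear_dataset(rng, noise=0.0)
        spec = ModelSpec(pls_components_grid=tuple(range(1, 11)), cv_folds=5)
        assert grid_search_cv(X, C, spec)["n_components"] <= 4

    def test_grid_order_invariance(self):
        rng = np.random.default_rng(3)
        X, C = linear_dataset(rng, noise=0.05)
        g = (5, 1, 3, 2, 4)
        a = grid_search_cv(X, C, ModelSpec(pls_components_grid=g))
        b = grid_search_cv(X, C, ModelSpec(pls_components_grid=tuple(sorted(g))))
        assert a == b

    def test_folds_exceeding_samples_rejected(self):
        rng = np.random.default_rng(4)
        X, C = linear_dataset(rng, n=4)
        with pytest.raises(ValueError):
            grid_search_cv(X, C, ModelSpec(cv_folds=10))

    def test_svm_grid_search_smoke(self):
        rng = np.random.default_rng(8)
        X, C = linear_dataset(rng, n=25, channels=15)
        spec = ModelSpec(
            model="svm",
            svm_c_grid=(1.0, 10.0),
            svm_gamma_grid=(0.01, 0.1),
            svm_epsilon_grid=(0.01,),
            cv_folds=3,
        )
        params = grid_search_cv(X, C, spec)
        assert params["C"] in (1.0, 10.0)
        assert params["gamma"] in (0.01, 0.1)


class TestFitPredict:
    def test_pls_interpolates_noise_free_linear_system(self):
        rng = np.random.default_rng(11)
        X, C = linear_dataset(rng)
        pred = fit_predict(ModelSpec(), {"n_components": 4}, X, C, X)
        for j in range(C.shape[1]):
            r2, _ = regression_metrics(C[:, j], pred[:, j])
            assert r2 >= 0.999

    def test_constant_component_yields_nan_r2(self):
        rng = np.random.default_rng(12)
        X, _ = linear_dataset(rng, n=20)
        y_const = np.full(20, 0.3)
        pred = fit_predict(ModelSpec(), {"n_components": 2}, X, y_const, X)
        with pytest.warns(UserWarning):
            r2, rmse = regression_metrics(y_const, pred)
        assert math.isnan(r2)
        assert rmse >= 0.0

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_predict(
                ModelSpec(), {"n_components": 1},
                np.zeros((5, 4)), np.zeros((5, 1)), np.zeros((3, 6)),
            )

    def test_svm_recovers_linear_trend(self):
        rng = np.random.default_rng(13)
        X, C = linear_dataset(rng, n=30, channels=10)
        pred = fit_predict(
            ModelSpec(model="svm"), {"C": 10.0, "gamma": 0.1, "epsilon": 0.01},
            X, C, X,
        )
        r2, _ = regression_metrics(C[:, 0], pred[:, 0])
        assert r2 > 0.9


class TestMetrics:
    def test_hand_computed_example(self):
        r2, rmse = regression_metrics([0.0, 1.0, 2.0], [0.0, 1.0, 3.0])
        assert r2 == 0.5
        assert rmse == pytest.approx(math.sqrt(1.0 / 3.0), rel=1e-15)

    def test_perfect_prediction(self):
        r2, rmse = regression_metrics([1.0, 2.0, 4.0], [1.0, 2.0, 4.0])
        assert (r2, rmse) == (1.0, 0.0)

    def test_mean_prediction_scores_zero(self):
        a = np.array([0.0, 1.0, 2.0])
        r2, _ = regression_metrics(a, np.full(3, a.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_joint_translation_invariance(self):
        rng = np.random.default_rng(14)
        a, p = rng.standard_normal((2, 25))
        r2a, rmsea = regression_metrics(a, p)
        r2b, rmseb = regression_metrics(a + 5.0, p + 5.0)
        assert rmsea == pytest.approx(rmseb, rel=1e-12)
        assert r2a == pytest.approx(r2b, rel=1e-10)

    def test_r2_invariant_to_affine_unit_change(self):
        rng = np.random.default_rng(15)
        a, p = rng.standard_normal((2, 25))
        r2a, _ = regression_metrics(a, p)
        r2b, _ = regression_metrics(100.0 * a + 3.0, 100.0 * p + 3.0)
        assert r2a == pytest.approx(r2b, rel=1e-10)


class TestQuantitationLimit:
    def test_identical_predictions_give_zero(self):
        assert quantitation_limit(np.full((12, 3), 0.5)).tolist() == [0, 0, 0]

    def test_ten_sigma_formula(self):
        rng = np.random.default_rng(16)
        preds = rng.standard_normal(500) * 0.02
        ql = quantitation_limit(preds.reshape(-1, 1))[0]
        assert ql == pytest.approx(10 * np.std(preds, ddof=1), rel=1e-12)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            quantitation_limit(np.zeros((5, 2)))


class TestRunBenchmark:
    def test_split_sizes_and_cell_bookkeeping(self):
        noisy, _ = sim.tablet_dataset(seed=1, n_samples=100)
        cfg = BenchmarkConfig(
            preprocessings=("raw",),
            models=("pls",),
            model_spec=ModelSpec(pls_components_grid=(2, 3), cv_folds=3),
        )
        report = run_benchmark(noisy, cfg)
        assert report.metadata["n_train"] == 85
        assert report.metadata["n_test"] == 15
        assert set(report.cells) == {
            ("raw", "pls", c) for c in ("compA", "compB", "compC")
        }
        for cell in report.cells.values():
            assert cell.error is None
            assert cell.rmse >= 0.0
            assert cell.r2 <= 1.0

    def test_report_roundtrips_through_dict(self):
        noisy, _ = sim.tablet_dataset(seed=2, n_samples=40)
        cfg = BenchmarkConfig(
            n_train=30,
            preprocessings=("raw",),
            models=("pls",),
            model_spec=ModelSpec(pls_components_grid=(2,), cv_folds=3),
        )
        report = run_benchmark(noisy, cfg)
        from ramanlre.chemometrics import RegressionReport

        back = RegressionReport.from_dict(report.to_dict())
        assert back.cells.keys() == report.cells.keys()
        assert back.metadata["n_train"] == 30

    def test_requires_concentrations(self):
        import dataclasses as dc

        blanks = sim.blank_dataset(seed=0, n_blanks=12)
        unlabeled = dc.replace(blanks, concentrations=None, component_names=())
        with pytest.raises(ValueError):
            run_benchmark(unlabeled, BenchmarkConfig())
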