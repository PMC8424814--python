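"""Exemplar-network mechanics: splits, kernel predictions, bandwidth
selection and the leave-one-out criterion, each against independent
oracles where one exists."""

import numpy as np
import pytest

from cpinet import (
    GRNNModel,
    SplitSpec,
    StopConditions,
    evaluate,
    fit,
    load_model,
    loo_criterion,
    predict,
    predict_posterior,
    save_model,
    split,
)


def kernel_oracle(X, y, q, sigma):
    """Independent double-loop kernel-regression sum (normalized weights)."""
    d2 = [sum((qk - xk) ** 2 for qk, xk in zip(q, x)) for x in X]
    m = min(d2)
    w = [np.exp(-(d - m) / (2 * sigma**2)) for d in d2]
    return sum(wi * yi for wi, yi in zip(w, y)) / sum(w)


def make_model(X, y, sigma=1.0, **kw):
    return GRNNModel(task="continuous", exemplars=np.asarray(X, dtype=float),
                     targets=np.asarray(y, dtype=float), bandwidth=sigma,
                     column_names=tuple(f"x{i}" for i in range(np.shape(X)[1])),
                     scaling={}, **kw)


class TestSplit:
    def test_study_scale_sizes(self):
        train, test, holdout = split(list(range(684)), SplitSpec(seed=1))
        assert (len(train), len(test), len(holdout)) == (544, 136, 4)

    def test_small_split_without_holdout(self):
        train, test, holdout = split(list(range(10)), SplitSpec(n_holdout=0, seed=0))
        assert (len(train), len(test), len(holdout)) == (8, 2, 0)

    def test_partition_is_disjoint_and_exhaustive(self):
        records = list(range(101))
        train, test, holdout = split(records, SplitSpec(seed=3))
        assert sorted(train + test + holdout) == records

    def test_deterministic_given_seed(self):
        a = split(list(range(50)), SplitSpec(seed=9))
        b = split(list(range(50)), SplitSpec(seed=9))
        assert a == b

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            split([1, 2, 3], SplitSpec(n_holdout=4))


class TestPredict:
    def test_single_exemplar_returns_its_target(self):
        model = make_model([[0.3, -1.2]], [7.5], sigma=0.01)
        for sigma in (0.01, 1.0, 100.0):
            model.bandwidth = sigma
            assert predict(model, [0.3, -1.2]) == pytest.approx(7.5)

    def test_midpoint_symmetry(self):
        model = make_model([[0.0], [1.0]], [0.0, 1.0])
        assert predict(model, [0.5]) == pytest.approx(0.5)

    def test_large_bandwidth_limit_is_training_mean(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(20, 3)), rng.normal(size=20)
        model = make_model(X, y, sigma=1e6)
        assert predict(model, rng.normal(size=3)) == pytest.approx(y.mean(), abs=1e-6)

    def test_small_bandwidth_recovers_training_targets(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(15, 4)), rng.normal(size=15)
        model = make_model(X, y, sigma=1e-4)
        got = predict(model, X)
        assert np.allclose(got, y)

    def test_matches_bruteforce_oracle_to_1e12(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 21))
            d = int(rng.integers(1, 6))
            X = rng.normal(size=(n, d))
            y = rng.normal(size=n)
            sigma = float(rng.uniform(0.2, 3.0))
            q = rng.normal(size=d)
            model = make_model(X, y, sigma=sigma)
            assert predict(model, q) == pytest.approx(
                kernel_oracle(X, y, q, sigma), abs=1e-12)

    def test_prediction_is_convex_combination_of_targets(self):
        rng = np.random.default_rng(7)
        X, y = rng.normal(size=(30, 5)), rng.normal(size=30)
        for sigma in (0.05, 0.5, 5.0):
            model = make_model(X, y, sigma=sigma)
            preds = predict(model, rng.normal(size=(1000, 5)) * 3)
            assert np.all(preds >= y.min() - 1e-12)
            assert np.all(preds <= y.max() + 1e-12)

    def test_exemplar_order_invariance(self):
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(12, 3)), rng.normal(size=12)
        q = rng.normal(size=(5, 3))
        perm = rng.permutation(12)
        a = predict(make_model(X, y, 0.8), q)
        b = predict(make_model(X[perm], y[perm], 0.8), q)
        assert np.allclose(a, b, atol=1e-12)

    def test_schema_mismatch_raises(self):
        model = make_model([[0.0, 1.0]], [1.0])
        with pytest.raises(ValueError, match="features"):
            predict(model, [0.0])

    def test_group_exclusion_hides_own_exemplars(self):
        X = np.array([[0.0], [0.0], [5.0]])
        y = np.array([1.0, 1.0, 9.0])
        model = make_model(X, y, sigma=0.5, exemplar_groups=("a", "a", "b"))
        plain = predict(model, np.array([[0.0]]))
        excluded = predict(model, np.array([[0.0]]), exclude_groups=["a"])
        assert plain == pytest.approx(1.0, abs=1e-6)
        assert excluded == pytest.approx(9.0)


class TestLooCriterion:
    def test_matches_refit_without_row_oracle(self):
        rng = np.random.default_rng(11)
        X, y = rng.normal(size=(8, 2)), rng.normal(size=8)
        sigma = 0.9
        errs = []
        for i in range(8):
            keep = [j for j in range(8) if j != i]
            pred = kernel_oracle(X[keep], y[keep], X[i], sigma)
            errs.append((pred - y[i]) ** 2)
        assert loo_criterion(X, y, sigma) == pytest.approx(np.mean(errs), abs=1e-12)

    def test_duplicated_exemplars_give_near_zero_criterion(self):
        X = np.repeat(np.random.default_rng(0).normal(size=(4, 2)), 2, axis=0)
        y = np.repeat([1.0, 2.0, 3.0, 4.0], 2)
        assert loo_criterion(X, y, 0.01) == pytest.approx(0.0, abs=1e-9)

    def test_pure_noise_at_large_bandwidth_equals_mean_predictor_error(self):
        rng = np.random.default_rng(5)
        X, y = rng.normal(size=(200, 3)), rng.normal(size=200)
        crit = loo_criterion(X, y, 1e5)
        mean_pred_mse = np.mean([(y[i] - np.delete(y, i).mean()) ** 2
                                 for i in range(len(y))])
        assert crit == pytest.approx(mean_pred_mse, rel=1e-3)

    def test_grouped_exclusion_ignores_twin_rows(self):
        # two rows per group share features and target; plain LOO is
        # trivially zero, grouped LOO is not
        rng = np.random.default_rng(8)
        base = rng.normal(size=(10, 2))
        X = np.repeat(base, 2, axis=0)
        y = np.repeat(rng.normal(size=10), 2)
        groups = np.repeat(np.arange(10), 2)
        assert loo_criterion(X, y, 0.05) == pytest.approx(0.0, abs=1e-6)
        assert loo_criterion(X, y, 0.05, groups=groups) > 0.01

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            loo_criterion(np.zeros((3, 1)), np.zeros(3), -1.0)


class TestFit:
    def test_noiseless_linear_target_fits_tightly(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, size=(200, 2))
        y = 2.0 * X[:, 0] - X[:, 1]
        model = fit(X, y)
        Xq = rng.uniform(-1, 1, size=(40, 2))
        metrics = evaluate(model, Xq, 2.0 * Xq[:, 0] - Xq[:, 1])
        assert metrics.r2 >= 0.99

    def test_time_budget_returns_best_so_far(self):
        rng = np.random.default_rng(4)
        X, y = rng.normal(size=(60, 3)), rng.normal(size=60)
        model = fit(X, y, stop=StopConditions(max_seconds=1e-4))
        assert model.metadata["stop_reason"] == "time"
        assert np.asarray(model.bandwidth) > 0

    def test_cycle_budget_stop(self):
        rng = np.random.default_rng(4)
        X, y = rng.normal(size=(40, 2)), rng.normal(size=40)
        model = fit(X, y, stop=StopConditions(max_cycles=5))
        assert model.metadata["stop_reason"] == "cycles"
        assert model.metadata["cycles"] <= 5

    def test_fitted_criterion_no_worse_than_grid_endpoints(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=80)
        model = fit(X, y)
        best = model.metadata["criterion"]
        assert best <= loo_criterion(X, y, 1e-3) + 1e-12
        assert best <= loo_criterion(X, y, 1e3) + 1e-12

    def test_degenerate_features_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit(np.ones((10, 3)), np.arange(10.0))

    def test_per_feature_mode_downweights_noise_feature(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(120, 3))
        y = np.sin(2 * X[:, 0]) + 0.05 * rng.normal(size=120)
        model = fit(X, y, bandwidth_mode="per_feature")
        rel = model._relevance()
        assert rel[0] > 5 * max(rel[1], rel[2])

    def test_pruning_zeroes_irrelevant_features(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(150, 4))
        y = X[:, 0] + 0.05 * rng.normal(size=150)
        Xv = rng.normal(size=(60, 4))
        yv = Xv[:, 0] + 0.05 * rng.normal(size=60)
        model = fit(X, y, bandwidth_mode="per_feature",
                    val_features=Xv, val_targets=yv)
        rel = model._relevance()
        assert rel[0] > 0
        assert model.metadata["prune_level"] is not None

    def test_deterministic(self):
        rng = np.random.default_rng(14)
        X, y = rng.normal(size=(40, 2)), rng.normal(size=40)
        a = fit(X, y)
        b = fit(X, y)
        assert np.array_equal(np.asarray(a.bandwidth), np.asarray(b.bandwidth))


class TestCategorical:
    def test_separable_classes_classified_correctly(self):
        rng = np.random.default_rng(21)
        X = np.vstack([rng.normal(-2, 0.3, size=(25, 2)), rng.normal(2, 0.3, size=(25, 2))])
        y = np.array(["no"] * 25 + ["yes"] * 25)
        model = fit(X, y, task="categorical")
        labels, probs = predict_posterior(model, X)
        assert (labels == y).all()
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_posterior_requires_categorical(self):
        model = make_model([[0.0]], [1.0])
        with pytest.raises(ValueError):
            predict_posterior(model, [[0.0]])

    def test_evaluate_all_correct(self):
        rng = np.random.default_rng(22)
        X = np.vstack([rng.normal(-3, 0.2, size=(10, 1)), rng.normal(3, 0.2, size=(10, 1))])
        y = np.array([0] * 10 + [1] * 10)
        model = fit(X, y, task="categorical")
        m = evaluate(model, X, y)
        assert m.accuracy == 1.0
        assert sum(m.confusion.values()) == 20
        assert all(a == b for (a, b) in m.confusion)


class TestEvaluate:
    def test_perfect_predictions(self):
        X = np.array([[0.0], [1.0], [2.0]])
        model = make_model(X, [1.0, 2.0, 3.0], sigma=1e-5)
        m = evaluate(model, X, [1.0, 2.0, 3.0])
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0, abs=1e-9)

    def test_constant_prediction_scores_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        model = make_model([[100.0]], [y.mean()], sigma=1.0)
        m = evaluate(model, np.zeros((4, 1)), y)
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_empty_rows_error(self):
        model = make_model([[0.0]], [1.0])
        with pytest.raises(ValueError):
            evaluate(model, np.empty((0, 1)), [])


def test_model_json_round_trip(tmp_path):
    rng = np.random.default_rng(30)
    X, y = rng.normal(size=(25, 3)), rng.normal(size=25)
    model = fit(X, y, bandwidth_mode="per_feature")
    model.scaling = {"x0": (0.5, 2.0)}
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    assert back.task == model.task
    assert np.allclose(back.exemplars, model.exemplars)
    assert np.allclose(np.asarray(back.bandwidth), np.asarray(model.bandwidth))
    assert back.scaling == model.scaling
    q = rng.normal(size=(6, 3))
    assert np.allclose(predict(back, q), predict(model, q), atol=1e-12)
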