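import numpy as np
import pytest

from silentnet import (
    PerceptronConnectivity,
    PopulationSpec,
    TrainingConfig,
    build_feedforward_weights,
    generate_raster,
    optimize_learning_rate,
    perceptron_update,
    threshold_unit_forward,
    train,
    weight_rmse,
)
from silentnet.raster import SpikeRaster


class TestPerceptronUpdate:
    def test_agreement_leaves_weights_unchanged(self):
        w = np.array([1.0, -2.0])
        out = perceptron_update(w, np.array([1.0, 1.0]), 1, 1, lr=0.5)
        np.testing.assert_array_equal(out, w)

    def test_missed_spike_potentiates_active_inputs(self):
        out = perceptron_update(np.zeros(2), np.array([1.0, 0.0]), 1, 0, lr=0.01)
        np.testing.assert_allclose(out, [0.01, 0.0])

    def test_false_alarm_depresses_only_active_inputs(self):
        out = perceptron_update(np.zeros(2), np.array([1.0, 0.0]), 0, 1, lr=0.01)
        np.testing.assert_allclose(out, [-0.01, 0.0])

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError):
            perceptron_update(np.zeros(1), np.ones(1), 2, 0, 0.1)


class TestFit:
    def test_silent_inputs_keep_initial_weights_exactly(self, rng):
        occ = (rng.random((6, 4, 50)) < 0.2).astype(np.uint8)
        occ[[1, 4]] = 0  # two inputs never spike
        raster = SpikeRaster(occ)
        y = (rng.random(200) < 0.3).astype(np.uint8)
        est = PerceptronConnectivity(n_iterations=7).fit(raster, y)
        assert est.weights_[1] == 0.0 and est.weights_[4] == 0.0
        est_u = PerceptronConnectivity(
            n_iterations=7, init_weights="uniform_small", random_state=3
        ).fit(raster, y)
        assert est_u.weights_[1] == est_u._init_weights_[1]
        assert est_u.weights_[4] == est_u._init_weights_[4]

    def test_first_pass_updates_scale_linearly_with_lr(self):
        # y=1 on sparse bins while predictions stay 0 throughout the pass,
        # so each update is +lr per active input and the total is ~ lr
        occ = np.zeros((3, 1, 100), dtype=np.uint8)
        occ[0, 0, ::10] = 1
        occ[2, 0, ::20] = 1
        raster = SpikeRaster(occ)
        y = np.zeros(100, dtype=np.uint8)
        y[::10] = 1
        w1 = PerceptronConnectivity(learning_rate=0.001, n_iterations=1).fit(raster, y).weights_
        w3 = PerceptronConnectivity(learning_rate=0.003, n_iterations=1).fit(raster, y).weights_
        np.testing.assert_allclose(w3, 3.0 * w1)

    def test_linearly_separable_patterns_reach_zero_error(self):
        # all 8 binary patterns of 3 inputs labelled by a hidden separator
        patterns = np.array(
            [[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)],
            dtype=np.uint8,
        )
        hidden = np.array([25.0, 12.0, 12.0])
        y = (patterns @ hidden > 20.0).astype(np.uint8)
        occ = np.tile(patterns.T[:, None, :], (1, 1, 1))  # (3, 1, 8)
        raster = SpikeRaster(occ)
        est = PerceptronConnectivity(learning_rate=1.0, n_iterations=500).fit(
            raster, y
        )
        assert est.errors_[-1] == 0
        pred = threshold_unit_forward(raster, est.weights_)
        np.testing.assert_array_equal(pred, y)

    def test_fit_accepts_bin_major_arrays(self, rng):
        X = (rng.random((80, 5)) < 0.3).astype(np.uint8)
        y = (rng.random(80) < 0.2).astype(np.uint8)
        est = PerceptronConnectivity(n_iterations=3).fit(X, y)
        assert est.weights_.shape == (5,)
        assert est.n_features_in_ == 5

    def test_misaligned_lengths_raise(self, rng):
        X = (rng.random((50, 4)) < 0.3).astype(np.uint8)
        with pytest.raises(ValueError, match="bins"):
            PerceptronConnectivity().fit(X, np.zeros(49))

    def test_lif_model_with_zero_truth_stays_at_zero(self, rng):
        occ = (rng.random((4, 2, 60)) < 0.2).astype(np.uint8)
        raster = SpikeRaster(occ)
        y = np.zeros(120, dtype=np.uint8)  # zero-weight circuit never fires
        est = PerceptronConnectivity(model="lif", n_iterations=5).fit(raster, y)
        np.testing.assert_array_equal(est.weights_, np.zeros(4))
        assert est.errors_.sum() == 0

    def test_sklearn_param_interface(self):
        est = PerceptronConnectivity(learning_rate=0.02)
        assert est.get_params()["learning_rate"] == 0.02
        est.set_params(n_iterations=5)
        assert est.n_iterations == 5


class TestRecovery:
    def test_hyperactive_population_recovers_weights(self):
        # all-active population: derived weights converge onto the truth
        spec = PopulationSpec(n_total=200, silent_fraction=0.0)
        rmses = []
        for seed in range(3):
            actual = build_feedforward_weights(seed=seed)
            raster = generate_raster(spec, n_trials=150, seed=10 + seed)
            post = threshold_unit_forward(raster, actual.weights)
            derived, trace = train(
                raster, post, TrainingConfig(n_iterations=40), true_weights=actual
            )
            rmses.append(weight_rmse(derived, actual))
            # the RMSE trace is computed against ground truth and improves
            assert trace["rmse"].iloc[-1] < trace["rmse"].iloc[0]
        assert np.mean(rmses) < 0.6

    def test_training_is_deterministic(self):
        spec = PopulationSpec(n_total=20, silent_fraction=0.5)
        raster = generate_raster(spec, n_trials=10, seed=3)
        actual = build_feedforward_weights(20, 10, 8, seed=3)
        post = threshold_unit_forward(raster, actual.weights)
        w1, _ = train(raster, post, TrainingConfig(n_iterations=10))
        w2, _ = train(raster, post, TrainingConfig(n_iterations=10))
        np.testing.assert_array_equal(w1.weights, w2.weights)


@pytest.fixture(scope="module")
def toy_problem():
    spec = PopulationSpec(n_total=40, silent_fraction=0.0)
    raster = generate_raster(spec, n_trials=60, seed=5)
    actual = build_feedforward_weights(40, 20, 16, seed=5)
    post = threshold_unit_forward(raster, actual.weights)
    return raster, post, actual


class TestOptimizeLearningRate:

    def test_single_candidate_is_best_by_construction(self, toy_problem):
        raster, post, actual = toy_problem
        best, curve = optimize_learning_rate(
            raster, post, [0.01], n_iterations=5, true_weights=actual
        )
        assert best == 0.01 and len(curve) == 1

    def test_duplicate_candidates_score_identically(self, toy_problem):
        raster, post, actual = toy_problem
        _, curve = optimize_learning_rate(
            raster, post, [0.01, 0.01], n_iterations=5, true_weights=actual
        )
        assert curve["rmse"].iloc[0] == curve["rmse"].iloc[1]

    def test_vanishing_rate_cannot_move_weights(self, toy_problem):
        # with lr=1e-5 and few passes the weights stay near zero, so its
        # RMSE is near the all-zero baseline and far above lr=0.01's
        raster, post, actual = toy_problem
        best, curve = optimize_learning_rate(
            raster, post, [1e-5, 1e-2], n_iterations=20, true_weights=actual
        )
        rmse = dict(zip(curve["learning_rate"], curve["rmse"]))
        assert rmse[1e-5] > rmse[1e-2]
        assert best == 1e-2

    def test_empty_candidates_rejected(self, toy_problem):
        raster, post, _ = toy_problem
        with pytest.raises(ValueError):
            optimize_learning_rate(raster, post, [])
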