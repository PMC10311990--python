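import itertools

import numpy as np
import pytest

from silentnet import (
    ClassificationScheme,
    calibrate_epsilon,
    classification_accuracy,
    classify_weight,
    classify_weights,
    cluster_subpopulations,
    evaluate_run,
    spike_prediction_scores,
    weight_rmse,
)


class TestWeightRmse:
    def test_identity_is_zero(self):
        assert weight_rmse([1.0, -3.0], [1.0, -3.0]) == 0.0

    def test_hand_computation(self):
        assert weight_rmse([1.0, 1.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_subset_restriction(self):
        d = np.array([0.0, 5.0, 0.0])
        a = np.array([0.0, 1.0, 0.0])
        assert weight_rmse(d, a, subset=np.array([1])) == pytest.approx(4.0)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            weight_rmse([1.0], [1.0], subset=np.array([], dtype=int))


class TestSpikeScores:
    def test_perfect_prediction(self):
        s = spike_prediction_scores([0, 1, 0, 1], [0, 1, 0, 1])
        assert s.tpr == 1.0 and s.ppv == 1.0 and s.performance == 1.0

    def test_three_of_four_hit_plus_one_extra(self):
        actual = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        predicted = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        s = spike_prediction_scores(actual, predicted)
        assert s.tpr == pytest.approx(0.75)
        assert s.ppv == pytest.approx(0.75)

    def test_empty_sets_are_undefined_not_one(self):
        with pytest.warns(UserWarning, match="TPR undefined"):
            s = spike_prediction_scores([0, 0], [0, 1])
        assert np.isnan(s.tpr) and s.ppv == 0.0
        with pytest.warns(UserWarning, match="PPV undefined"):
            s = spike_prediction_scores([0, 1], [0, 0])
        assert np.isnan(s.ppv)

    def test_matches_confusion_matrix_on_all_length6_pairs(self):
        # exhaustive brute force: TPR = TP/(TP+FN), PPV = TP/(TP+FP)
        for a_bits in itertools.product((0, 1), repeat=6):
            for p_bits in itertools.product((0, 1), repeat=6):
                a = np.array(a_bits)
                p = np.array(p_bits)
                if a.sum() == 0 or p.sum() == 0:
                    continue
                tp = int(((a == 1) & (p == 1)).sum())
                fn = int(((a == 1) & (p == 0)).sum())
                fp = int(((a == 0) & (p == 1)).sum())
                s = spike_prediction_scores(a, p)
                assert s.tpr == pytest.approx(tp / (tp + fn))
                assert s.ppv == pytest.approx(tp / (tp + fp))


class TestClassification:
    @pytest.mark.parametrize(
        "w,label",
        [
            (5.0, "strong_excitatory"),
            (0.0, "unconnected"),
            (-6.0, "strong_inhibitory"),
            (1.0, "weak_excitatory"),
            (-1.0, "weak_inhibitory"),
            # boundaries are assigned toward zero
            (4.0, "weak_excitatory"),
            (-4.0, "weak_inhibitory"),
            (0.16, "unconnected"),
            (-0.16, "unconnected"),
            (8.0, "strong_excitatory"),
            (-8.0, "strong_inhibitory"),
        ],
    )
    def test_interval_assignment(self, w, label):
        assert classify_weight(w) == label

    def test_partition_totality_by_scan(self):
        # every weight in [-8, 8] gets exactly one label, agreeing with an
        # independent interval-membership oracle at 1e-3 resolution
        scheme = ClassificationScheme()
        grid = np.round(np.arange(-8.0, 8.0 + 1e-9, 1e-3), 6)
        labels = classify_weights(grid, scheme)

        def oracle(w):
            eps, b = scheme.epsilon, scheme.strong_bound
            if w < -b:
                return "strong_inhibitory"
            if w < -eps:
                return "weak_inhibitory"
            if w <= eps:
                return "unconnected"
            if w <= b:
                return "weak_excitatory"
            return "strong_excitatory"

        expected = np.array([oracle(w) for w in grid], dtype=object)
        assert (labels == expected).all()

    def test_out_of_range_raises_unless_clipped(self):
        with pytest.raises(ValueError, match="outside"):
            classify_weight(9.0)
        assert classify_weights([9.0], clip=True)[0] == "strong_excitatory"

    def test_accuracy_matches_direct_counting(self):
        actual = np.array([6.0, 5.0, -6.0, 0.0, 1.0, -1.0])
        derived = np.array([6.2, 1.0, -6.1, 0.05, 5.0, -1.2])  # two misassigned
        acc = classification_accuracy(derived, actual)
        assert acc["strong_excitatory"] == pytest.approx(0.5)
        assert acc["strong_inhibitory"] == 1.0
        assert acc["unconnected"] == 1.0
        assert acc["weak_excitatory"] == 0.0
        assert acc["weak_inhibitory"] == 1.0

    def test_perfect_derivation_gives_unit_accuracy(self):
        actual = np.array([6.0, -6.0, 0.0, 2.0, -2.0])
        acc = classification_accuracy(actual.copy(), actual)
        assert all(v == 1.0 for v in acc.values())

    def test_empty_class_reported_as_nan(self):
        actual = np.zeros(4)
        with pytest.warns(UserWarning, match="no members"):
            acc = classification_accuracy(np.zeros(4), actual)
        assert np.isnan(acc["strong_excitatory"])
        assert acc["unconnected"] == 1.0


class TestCalibrateEpsilon:
    def test_exact_unconnected_recovery_gives_zero(self):
        runs = [(np.array([0.0, 3.0]), np.array([0.0, 3.0]), 0.995)]
        assert calibrate_epsilon(runs) == 0.0

    def test_hand_rmse(self):
        runs = [(np.array([0.1, -0.1, 5.0]), np.array([0.0, 0.0, 5.0]), 1.0)]
        assert calibrate_epsilon(runs) == pytest.approx(0.1)

    def test_pooling_over_runs(self):
        runs = [
            (np.array([0.3]), np.array([0.0]), 1.0),
            (np.array([0.1]), np.array([0.0]), 1.0),
            (np.array([9.9]), np.array([0.0]), 0.5),  # below threshold: excluded
        ]
        assert calibrate_epsilon(runs) == pytest.approx(np.sqrt((0.09 + 0.01) / 2))

    def test_no_qualifying_run_raises(self):
        with pytest.raises(ValueError, match="calibration"):
            calibrate_epsilon([(np.zeros(2), np.zeros(2), 0.5)])


class TestClusterSubpopulations:
    def test_well_separated_pairs_recovered_exactly(self):
        w = np.array([1.0, 1.1, 4.0, 4.1, 7.0, 7.1])
        labels = cluster_subpopulations(w)
        assert list(labels) == [
            "weak_excitatory", "weak_excitatory",
            "mid_excitatory", "mid_excitatory",
            "strong_excitatory", "strong_excitatory",
        ]

    def test_signs_never_share_a_group(self, rng):
        w = np.concatenate([rng.uniform(0.5, 8, 20), rng.uniform(-8, -0.5, 20)])
        labels = cluster_subpopulations(w)
        for lab, val in zip(labels, w):
            assert lab.endswith("excitatory") == (val > 0)

    def test_degenerate_magnitudes_raise(self):
        with pytest.raises(ValueError, match="distinct"):
            cluster_subpopulations(np.full(6, 2.0))

    def test_zero_weights_labelled_unconnected(self):
        w = np.array([0.0, 1.0, 4.0, 7.0])
        labels = cluster_subpopulations(w)
        assert labels[0] == "unconnected"


def test_evaluate_run_report_consistency():
    actual = np.array([6.0, -6.0, 0.0, 2.0, -2.0, 0.0])
    derived = actual + np.array([0.1, -0.1, 0.0, 0.2, 0.1, 0.05])
    report = evaluate_run(derived, actual, [0, 1, 1, 0], [0, 1, 0, 0])
    assert report.rmse_weights == pytest.approx(
        np.sqrt(np.mean((derived - actual) ** 2))
    )
    assert report.performance == pytest.approx((report.tpr + report.ppv) / 2)
    assert 0 <= report.tpr <= 1 and 0 <= report.ppv <= 1
    d = report.to_dict()
    assert "rmse_strong_excitatory" in d and "accuracy_unconnected" in d
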