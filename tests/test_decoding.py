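"""Template and LDA decoders, cross-validation schemes, decoder invariants."""

import numpy as np
import pytest

from popcode import (
    METHODS,
    ValidationError,
    Window,
    classify,
    cross_validated_accuracy,
    cv_accuracy_from_responses,
    fit_decoder,
    fit_lda,
    fit_template,
    random_split_accuracy,
    single_neuron_accuracy,
)
from popcode.decoding import _distances


def gaussian_responses(rng, centers, n_trials, noise=1.0):
    """(S, T, d) responses around per-stimulus centers."""
    centers = np.asarray(centers, dtype=float)
    S, d = centers.shape
    return centers[:, None, :] + noise * rng.standard_normal((S, n_trials, d))


class TestTemplates:
    def test_single_trial_templates_equal_trials(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        m = fit_template(X, np.array([0, 1]))
        np.testing.assert_array_equal(m.templates, X)

    def test_opposite_trials_average_to_zero(self):
        X = np.array([[1.0, -2.0], [-1.0, 2.0]])
        m = fit_template(X, np.array([0, 0]))
        np.testing.assert_allclose(m.templates, [[0.0, 0.0]])

    def test_means_match_brute_force(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.integers(0, 3, size=30)
        m = fit_template(X, y)
        for i, c in enumerate(m.classes):
            np.testing.assert_allclose(m.templates[i], X[y == c].mean(axis=0))


class TestClassify:
    def test_template_exactly_recovered(self, rng):
        X = rng.normal(size=(12, 4))
        y = np.repeat(np.arange(3), 4)
        for method in ("tmpeuc", "tmpcos"):
            m = fit_template(X, y, method=method)
            pred = classify(m, m.templates)
            np.testing.assert_array_equal(pred, m.classes)

    def test_hand_computed_distances(self):
        m = fit_template(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0, 1]))
        d = _distances(m, np.array([[0.9, 0.1]]))
        np.testing.assert_allclose(d[0], [np.sqrt(0.02), np.sqrt(1.62)])
        assert classify(m, [0.9, 0.1])[0] == 0

    def test_angular_distance_scale_invariant(self, rng):
        X = rng.normal(size=(12, 6)) + 3
        y = np.repeat(np.arange(3), 4)
        m = fit_template(X, y, method="tmpcos")
        probe = rng.normal(size=(5, 6)) + 3
        np.testing.assert_array_equal(classify(m, probe), classify(m, 10.0 * probe))
        # test vector equal to 10x a template lands on that template
        assert classify(m, 10.0 * m.templates[1])[0] == m.classes[1]

    def test_tie_breaks_to_lowest_index(self):
        m = fit_template(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0, 1]))
        assert classify(m, np.array([0.5, 0.5]))[0] == 0

    def test_zero_norm_vector_under_tmpcos(self):
        m = fit_template(
            np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0, 1]), method="tmpcos"
        )
        d = _distances(m, np.zeros((1, 2)))
        np.testing.assert_allclose(d[0], [1.0, 1.0])  # neutral distance
        assert classify(m, np.zeros(2))[0] == 0  # resolved by index


class TestLDA:
    def test_well_separated_classes_decode_perfectly(self, rng):
        R = gaussian_responses(rng, 30 * np.eye(4), n_trials=20, noise=1.0)
        res = cv_accuracy_from_responses(R, "lda")
        assert res.accuracy == 1.0

    def test_identical_distributions_decode_at_chance(self, rng):
        R = rng.standard_normal((6, 20, 10))
        res = cv_accuracy_from_responses(R, "lda")
        se = np.sqrt((1 / 6) * (5 / 6) / 120)
        assert abs(res.accuracy - 1 / 6) < 3 * se

    def test_pca_keeps_one_component_for_collinear_data(self, rng):
        t = rng.normal(size=40)
        X = np.outer(t, [1.0, 2.0, -1.0])  # all variance on one line
        y = (t > 0).astype(int)
        m = fit_lda(X, y)
        assert m.pca.n_components_ == 1

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            fit_lda(np.ones((3, 2)), np.array([0, 0, 0]))
        with pytest.raises(ValidationError):
            fit_lda(np.ones((3, 2)), np.array([0, 0, 1]))


class TestCrossValidation:
    def test_separable_population_all_methods(self, rng):
        R = gaussian_responses(rng, 50 * np.eye(6) + 5, n_trials=20, noise=0.5)
        for m in METHODS:
            assert cv_accuracy_from_responses(R, m).accuracy == 1.0

    def test_label_shuffle_gives_chance(self, rng):
        """No leakage between folds: shuffled labels decode at chance."""
        R = gaussian_responses(rng, 50 * np.eye(6), n_trials=20, noise=0.5)
        flat = R.reshape(120, 6)[rng.permutation(120)]
        R_shuf = flat.reshape(6, 20, 6)
        se = np.sqrt((1 / 6) * (5 / 6) / 120)
        for m in METHODS:
            acc = cv_accuracy_from_responses(R_shuf, m).accuracy
            assert abs(acc - 1 / 6) < 4 * se

    def test_confusion_and_fold_bookkeeping(self, rng):
        R = gaussian_responses(rng, 10 * np.eye(3), n_trials=8, noise=1.0)
        res = cv_accuracy_from_responses(R, "tmpeuc")
        assert res.confusion.sum() == 24
        np.testing.assert_array_equal(res.confusion.sum(axis=1), [8, 8, 8])
        assert res.accuracy == pytest.approx(res.fold_accuracies.mean())

    def test_brute_force_nearest_mean_oracle(self, rng):
        """TMPEUC fold predictions match an independent loop implementation."""
        for _ in range(20):
            S, T, d = 4, 8, 3
            R = gaussian_responses(rng, rng.normal(size=(S, d)), T, noise=1.0)
            res = cv_accuracy_from_responses(R, "tmpeuc")
            correct = 0
            block = T // 4
            for k in range(4):
                test_idx = range(k * block, (k + 1) * block)
                train_idx = [t for t in range(T) if t not in test_idx]
                means = [R[s, train_idx].mean(axis=0) for s in range(S)]
                for s in range(S):
                    for t in test_idx:
                        dists = [np.linalg.norm(R[s, t] - mu) for mu in means]
                        if int(np.argmin(dists)) == s:
                            correct += 1
            assert res.accuracy == pytest.approx(correct / (S * T))

    def test_indivisible_trials_rejected(self, rng):
        with pytest.raises(ValidationError):
            cv_accuracy_from_responses(rng.normal(size=(3, 18, 2)), "tmpeuc")

    def test_from_spiketrainset(self, small_pop):
        res = cross_validated_accuracy(small_pop, Window(20, 15), "tmpeuc")
        assert 0.0 <= res.accuracy <= 1.0
        assert res.n_test == 120


class TestRandomSplit:
    def test_separable_data_has_zero_sd(self):
        from conftest import make_spiketrainset

        # deterministic responses: stimulus s drives only neuron s
        spikes = {
            (s, s, tr): np.linspace(1, 14, 10)
            for s in range(2)
            for tr in range(20)
        }
        data = make_spiketrainset(spikes, n_neurons=2, n_stimuli=2, n_trials=20)
        mean, sd, runs = random_split_accuracy(
            data, Window(0, 15), "tmpeuc", n_runs=25, seed=0
        )
        assert mean == 1.0
        assert sd == 0.0

    def test_seeded_reproducibility_and_chance_level(self, small_pop):
        w = Window(-200, 15)  # pre-onset: stimulus-independent
        m1, s1, runs1 = random_split_accuracy(small_pop, w, "tmpeuc", n_runs=30, seed=5)
        m2, s2, runs2 = random_split_accuracy(small_pop, w, "tmpeuc", n_runs=30, seed=5)
        np.testing.assert_array_equal(runs1, runs2)
        binom_sd = np.sqrt((1 / 6) * (5 / 6) / 30)
        assert abs(m1 - 1 / 6) < 4 * binom_sd


class TestSingleNeuron:
    def test_disjoint_count_ranges_decode_perfectly(self):
        from conftest import make_spiketrainset

        spikes = {}
        for s in range(2):
            for tr in range(8):
                # stimulus 0: 1 spike; stimulus 1: 8 spikes in the window
                n_spk = 1 if s == 0 else 8
                spikes[(0, s, tr)] = np.linspace(1, 14, n_spk)
        data = make_spiketrainset(spikes, n_neurons=1, n_stimuli=2, n_trials=8)
        res = single_neuron_accuracy(data, 0, Window(0, 15))
        assert res.accuracy == 1.0

    def test_untuned_neuron_at_chance(self, small_pop):
        res = single_neuron_accuracy(small_pop, 0, Window(-250, 15))
        se = np.sqrt((1 / 6) * (5 / 6) / 120)
        assert abs(res.accuracy - 1 / 6) < 4 * se

    def test_matches_exhaustive_template_oracle(self, small_pop):
        w = Window(20, 15)
        idx = small_pop.neurons.index(3)
        counts = small_pop.count_matrix([w])[idx, :, :, 0]
        rates = counts * (1000.0 / w.length)
        S, T = rates.shape
        correct = 0
        for k in range(4):
            test_idx = list(range(k * 5, k * 5 + 5))
            train_idx = [t for t in range(T) if t not in test_idx]
            means = rates[:, train_idx].mean(axis=1)
            for s in range(S):
                for t in test_idx:
                    if int(np.argmin(np.abs(means - rates[s, t]))) == s:
                        correct += 1
            # oracle uses lowest-index tie-break via argmin, same as decoder
        assert single_neuron_accuracy(small_pop, 3, w).accuracy == pytest.approx(
            correct / (S * T)
        )


class TestInvariants:
    def test_tmpeuc_translation_invariance(self, rng):
        R = gaussian_responses(rng, rng.normal(size=(4, 5)), 8, noise=1.0)
        shift = rng.normal(size=5)
        a = cv_accuracy_from_responses(R, "tmpeuc").accuracy
        b = cv_accuracy_from_responses(R + shift, "tmpeuc").accuracy
        assert a == b

    def test_tmpcos_per_trial_scaling_invariance(self, rng):
        R = np.abs(gaussian_responses(rng, 5 + rng.normal(size=(4, 5)), 8, noise=1.0))
        scales = rng.uniform(0.5, 2.0, size=(4, 8, 1))
        m = fit_template(R.reshape(32, 5), np.repeat(np.arange(4), 8), "tmpcos")
        a = classify(m, R.reshape(32, 5))
        b = classify(m, (R * scales).reshape(32, 5))
        np.testing.assert_array_equal(a, b)
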