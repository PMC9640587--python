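"""Naive Bayes position decoder: parameters, oracle equivalence, continuity,
shuffle control, knock-outs, and neuron down-sampling."""

import numpy as np
import pandas as pd
import pytest

from cppmap import decoding as dc
from cppmap.arena import ArenaSpec
from cppmap.preprocessing import binarize_events
from cppmap.synthetic import ExperimentConfig, PopulationSpec, simulate_experiment


@pytest.fixture(scope="module")
def decoded_setup():
    arena = ArenaSpec()
    exp = simulate_experiment(
        arena, PopulationSpec(n_neurons=60), ExperimentConfig(duration_s=300.0, seed=4)
    )
    fr = 30.0
    ev_b = binarize_events(exp.sessions["baseline"].amplitudes, fr).events
    ev_t = binarize_events(exp.sessions["prebaseline"].amplitudes, fr).events
    train = dc.bin_activity(ev_b, exp.sessions["baseline"].trajectory, arena, fr)
    test = dc.bin_activity(ev_t, exp.sessions["prebaseline"].trajectory, arena, fr)
    dec = dc.NaiveBayesPositionDecoder(arena=arena).fit(train.X, train.y)
    return arena, train, test, dec


class TestBinActivity:
    def test_bin_count_arithmetic(self, arena, short_traj, rng):
        events = rng.random((3, len(short_traj))) < 0.05
        binned = dc.bin_activity(events, short_traj, arena, 30.0, dt=0.8, speed_threshold=0.0)
        assert len(binned.X) == len(short_traj) // 24  # 24 frames per 0.8 s bin

    def test_counts_conserved_minus_remainder(self, arena, short_traj, rng):
        events = rng.random((2, len(short_traj))) < 0.1
        binned = dc.bin_activity(events, short_traj, arena, 30.0, speed_threshold=0.0)
        used = len(binned.X) * 24
        assert binned.X.sum() == events[:, :used].sum()

    def test_stationary_trajectory_single_label(self, arena):
        n = 240
        traj = pd.DataFrame(
            {"t": np.arange(n) / 30, "x": np.full(n, 30.0), "y": np.full(n, 12.0),
             "speed": np.full(n, 5.0)}
        )
        binned = dc.bin_activity(np.zeros((1, n)), traj, arena, 30.0)
        assert len(np.unique(binned.y)) == 1


class TestDecoderModel:
    def test_theta_laplace_zero_spike_neuron(self):
        # location with S total spikes, N neurons: silent neuron gets 1/(S+N)
        X = np.array([[2, 0], [3, 0]])
        y = np.array([7, 7])
        dec = dc.NaiveBayesPositionDecoder(arena=ArenaSpec()).fit(X, y)
        theta = np.exp(dec.log_theta_)
        assert theta[0, 1] == pytest.approx(1 / (5 + 2))
        assert theta[0, 0] == pytest.approx(6 / 7)

    def test_single_neuron_theta_is_one(self, rng):
        X = rng.integers(0, 5, size=(30, 1))
        y = rng.integers(0, 4, size=30)
        dec = dc.NaiveBayesPositionDecoder(arena=ArenaSpec()).fit(X, y)
        assert np.allclose(np.exp(dec.log_theta_), 1.0)

    def test_theta_rows_sum_to_one(self, rng):
        X = rng.integers(0, 6, size=(100, 7))
        y = rng.integers(0, 9, size=100)
        for pw in (False, True):
            dec = dc.NaiveBayesPositionDecoder(arena=ArenaSpec(), prior_weighting=pw).fit(X, y)
            assert np.allclose(np.exp(dec.log_theta_).sum(axis=1), 1.0)

    def test_prior_is_empirical(self, rng):
        y = np.array([0] * 30 + [5] * 10)
        X = rng.integers(0, 3, size=(40, 4))
        dec = dc.NaiveBayesPositionDecoder(arena=ArenaSpec()).fit(X, y)
        assert np.exp(dec.log_prior_) == pytest.approx([0.75, 0.25])


class TestDecode:
    def test_two_location_hand_case(self):
        # neuron 0 fires only at location A in training; a test bin with one
        # event from that neuron decodes to A
        X = np.array([[3, 1], [0, 1], [3, 1], [0, 1]])
        y = np.array([0, 1, 0, 1])
        dec = dc.NaiveBayesPositionDecoder(arena=ArenaSpec()).fit(X, y)
        assert dec.predict(np.array([[1, 0]]))[0] == 0

    def test_all_zero_bin_decodes_prior_weighted(self):
        X = np.array([[1, 1]] * 6 + [[1, 1]] * 2)
        y = np.array([0] * 6 + [1] * 2)
        dec = dc.NaiveBayesPositionDecoder(arena=ArenaSpec()).fit(X, y)
        # identical likelihoods, prior favors location 0
        assert dec.predict(np.zeros((1, 2)))[0] == 0

    def test_matches_bruteforce_posterior_enumeration(self, rng):
        X = rng.integers(0, 4, size=(60, 3))
        y = rng.integers(0, 5, size=60)
        dec = dc.NaiveBayesPositionDecoder(arena=ArenaSpec()).fit(X, y)
        classes, inv = np.unique(y, return_inverse=True)
        counts = np.zeros((len(classes), 3))
        np.add.at(counts, inv, X)
        theta = (counts + 1) / (counts.sum(1, keepdims=True) + 3)
        prior = np.bincount(inv) / len(y)
        Xt = rng.integers(0, 4, size=(40, 3))
        post = prior[None, :] * np.prod(
            theta.T[None, :, :] ** Xt[:, :, None], axis=1
        )
        assert np.array_equal(dec.predict(Xt), classes[np.argmax(post, axis=1)])


class TestTwoStep:
    def test_flat_constraint_limit_equals_one_step(self, decoded_setup):
        arena, train, test, dec = decoded_setup
        wide = dc.NaiveBayesPositionDecoder(arena=arena, continuity_a=1e9).fit(train.X, train.y)
        one = wide.predict(test.X)
        two = wide.predict_2step(test.X, test.speed)
        # first bin is identical by definition; with sigma -> inf all agree
        assert np.array_equal(one, two)

    def test_zero_speed_floored_not_frozen(self, decoded_setup):
        arena, train, test, dec = decoded_setup
        speeds = np.zeros(len(test.X))
        preds = dec.predict_2step(test.X, speeds)
        assert len(np.unique(preds)) > 1  # trajectory does not freeze at y_0

    def test_two_step_reduces_error_on_smooth_trajectory(self, decoded_setup):
        arena, train, test, dec = decoded_setup
        e1 = dc.decoding_error(dec.predict_coords(test.X), test.coords)
        e2 = dc.decoding_error(dec.coords_of(dec.predict_2step(test.X, test.speed)), test.coords)
        assert e2 <= e1 * 1.05  # never substantially worse on smooth data


class TestErrorAndShuffle:
    def test_perfect_prediction_zero_error(self):
        c = np.random.default_rng(0).random((10, 2))
        assert dc.decoding_error(c, c) == 0.0

    def test_one_bin_offset_error(self):
        c = np.zeros((5, 2))
        p = c.copy()
        p[:, 0] += 1.8
        assert dc.decoding_error(p, c) == pytest.approx(1.8)

    def test_random_predictions_match_analytic_expectation(self, rng):
        # mean error of uniform random predictions ~ expected pairwise distance
        pts = rng.uniform(0, 10, size=(4000, 2))
        true = rng.uniform(0, 10, size=(4000, 2))
        emp = dc.decoding_error(pts, true)
        # expected distance between two uniform points in a 10x10 square
        expect = 10 * 0.5214054
        assert abs(emp - expect) / expect < 0.05

    def test_shuffle_preserves_counts_and_beats_truth(self, decoded_setup):
        arena, train, test, dec = decoded_setup
        errors = dc.shuffle_control(dec, test, n_shuffles=30, seed=0)
        true_err = dc.decoding_error(dec.predict_coords(test.X), test.coords)
        assert true_err < np.percentile(errors, 5)
        # joint circular shift preserves every neuron's total count
        Xs = np.roll(test.X, 17, axis=0)
        assert np.array_equal(Xs.sum(0), test.X.sum(0))


class TestKnockout:
    def test_empty_ko_is_identity(self, decoded_setup):
        arena, train, test, dec = decoded_setup
        full = dc.knockout_decode(dec, test, None)
        empty = dc.knockout_decode(dec, test, np.array([], int))
        assert np.array_equal(full.pred_labels, empty.pred_labels)

    def test_compartment_fractions_sum_to_one(self, decoded_setup):
        arena, train, test, dec = decoded_setup
        res = dc.knockout_decode(dec, test, np.arange(5))
        assert sum(res.compartment_time.values()) == pytest.approx(1.0)

    def test_ko_all_neurons_warns(self, decoded_setup):
        arena, train, test, dec = decoded_setup
        with pytest.warns(UserWarning):
            dc.knockout_decode(dec, test, np.arange(test.X.shape[1]))

    def test_ko_does_not_modify_inputs(self, decoded_setup):
        arena, train, test, dec = decoded_setup
        before = test.X.copy()
        dc.knockout_decode(dec, test, np.arange(10))
        assert np.array_equal(before, test.X)


class TestDownsample:
    def test_full_population_single_iteration_matches_plain(self, decoded_setup):
        arena, train, test, dec = decoded_setup
        err = dc.downsample_neurons(train, test, n=train.X.shape[1], arena=arena)
        plain = dc.decoding_error(dec.predict_coords(test.X), test.coords)
        assert err == pytest.approx(plain)

    def test_reproducible_under_seed(self, decoded_setup):
        arena, train, test, dec = decoded_setup
        a = dc.downsample_neurons(train, test, n=30, n_iterations=5, seed=3, arena=arena)
        b = dc.downsample_neurons(train, test, n=30, n_iterations=5, seed=3, arena=arena)
        assert a == b

    def test_more_neurons_do_not_hurt(self, decoded_setup):
        arena, train, test, dec = decoded_setup
        e_small = dc.downsample_neurons(train, test, n=10, n_iterations=8, seed=0, arena=arena)
        e_large = dc.downsample_neurons(train, test, n=55, n_iterations=8, seed=0, arena=arena)
        assert e_large <= e_small

    def test_oversampling_rejected(self, decoded_setup):
        arena, train, test, dec = decoded_setup
        with pytest.raises(ValueError):
            dc.downsample_neurons(train, test, n=10_000)
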