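"""Arena geometry and synthetic-experiment generator contracts."""

import numpy as np
import pandas as pd
import pytest

from cppmap.arena import ArenaSpec
from cppmap.preprocessing import spatial_coverage
from cppmap.synthetic import (
    ExperimentConfig,
    PopulationSpec,
    SimConfig,
    calcium_traces,
    make_population,
    read_experiment,
    resolve_effect_compartments,
    simulate_events,
    simulate_experiment,
    simulate_trajectory,
    write_experiment,
)


class TestArena:
    def test_compartment_split_at_midline(self, arena):
        x = np.array([0.0, 24.9, 25.0, 49.9])
        assert list(arena.compartment_of(x)) == ["left", "left", "right", "right"]

    def test_door_window(self, arena):
        assert arena.in_door(12.5)
        assert not arena.in_door(12.5 + arena.door_width)
        assert arena.door_hi - arena.door_lo == pytest.approx(6.5)

    def test_door_wider_than_compartment_rejected(self):
        with pytest.raises(ValueError):
            ArenaSpec(door_width=30.0)

    def test_bin_index_covers_grid(self, arena):
        nx, ny = arena.n_bins(1.8)
        rng = np.random.default_rng(0)
        x = rng.uniform(0, arena.width, 1000)
        y = rng.uniform(0, arena.height, 1000)
        idx = arena.bin_index(x, y, 1.8)
        assert idx.min() >= 0 and idx.max() < nx * ny
        centers = arena.bin_centers(1.8)
        assert centers.shape == (nx * ny, 2)


class TestTrajectory:
    def test_zero_duration_gives_empty_trajectory(self, arena):
        traj = simulate_trajectory(arena, SimConfig(duration_s=0.0, seed=0))
        assert len(traj) == 0

    def test_positions_inside_arena(self, arena, short_traj):
        assert short_traj["x"].between(0, arena.width).all()
        assert short_traj["y"].between(0, arena.height).all()

    def test_max_step_bounded_by_max_speed(self, arena):
        cfg = SimConfig(duration_s=120.0, seed=3)
        traj = simulate_trajectory(arena, cfg)
        steps = np.hypot(np.diff(traj["x"]), np.diff(traj["y"]))
        assert steps.max() <= cfg.max_speed / cfg.frame_rate + 1e-9

    def test_non_positive_frame_rate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(frame_rate=0.0)

    def test_deterministic_under_seed(self, arena):
        a = simulate_trajectory(arena, SimConfig(duration_s=30.0, seed=5))
        b = simulate_trajectory(arena, SimConfig(duration_s=30.0, seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_unbiased_occupancy_near_half(self, arena):
        # Monte-Carlo over seeds: mean left-time fraction approximately 1/2
        fr = [
            (simulate_trajectory(arena, SimConfig(duration_s=240.0, seed=s)).compartment == "left").mean()
            for s in range(20)
        ]
        assert abs(np.mean(fr) - 0.5) < 0.06

    def test_bias_shifts_occupancy(self, arena):
        fr = [
            (
                simulate_trajectory(
                    arena,
                    SimConfig(duration_s=240.0, occupancy_bias=0.6, bias_compartment="right", seed=s),
                ).compartment
                == "right"
            ).mean()
            for s in range(6)
        ]
        assert np.mean(fr) > 0.55

    def test_coverage_above_90pct_at_15_minutes(self, arena):
        traj = simulate_trajectory(arena, SimConfig(duration_s=900.0, seed=2))
        assert spatial_coverage(traj, arena, 1.8) > 0.9

    def test_midline_crossings_only_through_door(self, arena, short_traj):
        x = short_traj["x"].to_numpy()
        y = short_traj["y"].to_numpy()
        cross = np.flatnonzero(np.sign(x[:-1] - 25.0) * np.sign(x[1:] - 25.0) < 0)
        y_cross = y[cross] + (25.0 - x[cross]) / (x[cross + 1] - x[cross]) * (y[cross + 1] - y[cross])
        assert len(cross) > 3  # the animal does traverse
        assert ((y_cross >= arena.door_lo - 1e-6) & (y_cross <= arena.door_hi + 1e-6)).all()


class TestEvents:
    def test_zero_peak_neuron_is_silent_up_to_noise(self, arena, short_traj, rng):
        spec = PopulationSpec(n_neurons=4, n_untuned=4, baseline_event_p=0.0, cluster_coactivity=0.0)
        truth = resolve_effect_compartments(make_population(arena, spec, rng), "left")
        amps = simulate_events(truth, short_traj, "baseline", rng)
        assert np.all(amps == 0.0)

    def test_amplitudes_nonnegative_and_aligned(self, small_experiment):
        for sess in small_experiment.sessions.values():
            assert np.all(sess.amplitudes >= 0)
            assert sess.amplitudes.shape[1] == len(sess.trajectory)

    def test_unknown_session_label_rejected(self, arena, short_traj, rng):
        truth = resolve_effect_compartments(
            make_population(arena, PopulationSpec(n_neurons=3), rng), "left"
        )
        with pytest.raises(ValueError, match="session"):
            simulate_events(truth, short_traj, "conditioning7", rng)

    def test_in_field_rate_recovers_planted_peak(self, arena, rng):
        # dense sampling at the field centre: empirical rate ~= planted peak
        spec = PopulationSpec(
            n_neurons=5, field_prob=1.0, peak_p=0.2, peak_p_sd=0.0,
            baseline_event_p=0.0, cluster_coactivity=0.0,
        )
        truth = resolve_effect_compartments(make_population(arena, spec, rng), "left")
        n_frames = 4000
        i = 0
        cx, cy = truth.centers[i, 0]
        traj = pd.DataFrame(
            {
                "t": np.arange(n_frames) / 30.0,
                "x": np.full(n_frames, cx),
                "y": np.full(n_frames, cy),
                "speed": np.full(n_frames, 10.0),
                "heading": np.zeros(n_frames),
                "compartment": ["left"] * n_frames,
            }
        )
        amps = simulate_events(truth, traj, "baseline", rng)
        emp = (amps[i] > 0).mean()
        assert abs(emp - 0.2) / 0.2 < 0.15

    def test_disappear_label_silences_compartment_in_tests_only(self, arena, rng):
        spec = PopulationSpec(
            n_neurons=6, n_disappear_pref=6, field_prob=1.0,
            baseline_event_p=0.0, cluster_coactivity=0.0, n_clusters=1,
        )
        truth = resolve_effect_compartments(make_population(arena, spec, rng), "left")
        n = 3000
        traj_left = pd.DataFrame(
            {
                "t": np.arange(n) / 30.0,
                "x": truth.centers[:, 0, 0].mean() * np.ones(n),
                "y": truth.centers[:, 0, 1].mean() * np.ones(n),
                "speed": np.full(n, 10.0),
                "heading": np.zeros(n),
                "compartment": ["left"] * n,
            }
        )
        base = simulate_events(truth, traj_left, "baseline", np.random.default_rng(0))
        test = simulate_events(truth, traj_left, "test1", np.random.default_rng(0))
        assert base.sum() > 0
        assert test.sum() == 0  # planted tuning removed, no spontaneous noise here


class TestExperiment:
    def test_effect_counts_exceeding_population_rejected(self, arena):
        with pytest.raises(ValueError):
            make_population(
                arena, PopulationSpec(n_neurons=5, n_disappear_pref=6), np.random.default_rng(0)
            )

    def test_same_seed_bit_identical(self, arena):
        spec = PopulationSpec(n_neurons=10)
        cfg = ExperimentConfig(duration_s=30.0, seed=9)
        a = simulate_experiment(arena, spec, cfg)
        b = simulate_experiment(arena, spec, cfg)
        for name in a.sessions:
            assert np.array_equal(a.sessions[name].amplitudes, b.sessions[name].amplitudes)
            pd.testing.assert_frame_equal(a.sessions[name].trajectory, b.sessions[name].trajectory)

    def test_neuron_count_constant_across_sessions(self, small_experiment):
        counts = {s.amplitudes.shape[0] for s in small_experiment.sessions.values()}
        assert counts == {40}

    def test_session_order_fixed(self, small_experiment):
        assert small_experiment.session_names == ("prebaseline", "baseline", "test1", "test2")

    def test_hdf5_roundtrip(self, small_experiment, tmp_path):
        path = str(tmp_path / "exp.h5")
        write_experiment(small_experiment, path)
        back = read_experiment(path)
        assert set(back.sessions) == set(small_experiment.sessions)
        np.testing.assert_allclose(
            back.sessions["baseline"].amplitudes, small_experiment.sessions["baseline"].amplitudes
        )
        np.testing.assert_array_equal(back.truth.cluster, small_experiment.truth.cluster)


def test_calcium_traces_shapes_and_decay(rng):
    amps = np.zeros((2, 100))
    amps[0, 10] = 1.0
    den, raw = calcium_traces(amps, frame_rate=30.0, tau=0.5, noise_sd=0.0)
    assert den.shape == raw.shape == (2, 100)
    assert den[0, 10] == pytest.approx(1.0)
    assert 0 < den[0, 20] < den[0, 11]  # exponential decay after the event
    assert np.all(den[1] == 0)
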