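"""Binarization, maps, occupancy matching, and coverage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cppmap.arena import ArenaSpec
from cppmap.preprocessing import (
    EmptySelectionError,
    binarize_events,
    compute_maps,
    match_occupancy,
    occupancy_map,
    rate_map,
    read_trajectory_csv,
    spatial_coverage,
    speed_filter,
)


class TestBinarize:
    def test_all_zero_trace_has_no_events(self):
        em = binarize_events(np.zeros((1, 100)))
        assert em.events.sum() == 0
        assert not em.excluded[0]

    def test_single_spike_hand_computed_sd(self):
        # 999 zeros + one amplitude of 10: population SD ~ 0.3161,
        # threshold ~ 0.948, exactly one event survives
        tr = np.zeros(1000)
        tr[500] = 10.0
        em = binarize_events(tr)
        assert em.thresholds[0] == pytest.approx(3 * 0.31606961, rel=1e-6)
        assert em.events.sum() == 1
        assert em.events[0, 500]

    @given(scale=st.floats(min_value=0.01, max_value=1e4))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        amps = rng.exponential(1.0, size=(3, 400)) * (rng.random((3, 400)) < 0.05)
        a = binarize_events(amps)
        b = binarize_events(amps * scale)
        assert np.array_equal(a.events, b.events)

    def test_constant_nonzero_trace_flagged_degenerate(self):
        em = binarize_events(np.full((1, 50), 2.0))
        assert em.excluded[0]
        assert em.events.sum() == 0

    def test_negative_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            binarize_events(np.array([[-1.0, 0.0]]))


class TestSpeedFilter:
    def _traj(self, speeds):
        n = len(speeds)
        return pd.DataFrame(
            {"t": np.arange(n) / 30, "x": np.ones(n), "y": np.ones(n), "speed": speeds}
        )

    def test_fast_frames_all_kept(self):
        assert speed_filter(self._traj(np.full(10, 5.0))).all()

    def test_all_slow_raises(self):
        with pytest.raises(EmptySelectionError):
            speed_filter(self._traj(np.full(10, 1.0)))

    def test_mixed_count_matches_threshold(self):
        speeds = np.array([0.0, 1.9, 2.0, 3.0, 10.0])
        assert speed_filter(self._traj(speeds)).sum() == 3


class TestMaps:
    def test_rate_is_events_per_occupancy_second(self, arena):
        # one event in a bin occupied 2 s -> 0.5 events/s
        n = 60  # 2 s at 30 Hz
        traj = pd.DataFrame(
            {"t": np.arange(n) / 30, "x": np.full(n, 5.0), "y": np.full(n, 5.0),
             "speed": np.full(n, 5.0)}
        )
        events = np.zeros(n, bool)
        events[10] = True
        occ, rm = compute_maps(traj, events, arena)
        b = arena.bin_index(np.array([5.0]), np.array([5.0]))[0]
        assert rm.rate[b] == pytest.approx(0.5)

    def test_uniform_events_give_flat_rate(self, arena, short_traj):
        events = np.ones(len(short_traj), bool)
        occ, rm = compute_maps(short_traj, events, arena)
        vis = occ.included
        assert np.allclose(rm.rate[vis], 30.0)

    def test_occupancy_probability_sums_to_one(self, arena, short_traj):
        idx = arena.bin_index(short_traj["x"].to_numpy(), short_traj["y"].to_numpy())
        occ = occupancy_map(idx, arena, 30.0)
        assert occ.p.sum() == pytest.approx(1.0)
        assert (occ.p >= 0).all()

    def test_mean_rate_identity(self, arena, short_traj, rng):
        # session mean rate equals sum P_i * rate_i over included bins
        events = rng.random(len(short_traj)) < 0.02
        occ, rm = compute_maps(short_traj, events, arena)
        assert rm.mean_rate == pytest.approx(
            float(np.sum(occ.p[occ.included] * rm.rate[occ.included]))
        )

    def test_smoothing_matches_direct_convolution_oracle(self, arena, short_traj, rng):
        events = rng.random(len(short_traj)) < 0.05
        occ, rm = compute_maps(short_traj, events, arena, smooth_sd_bins=2.0)
        # direct renormalized-kernel convolution
        nx, ny = occ.grid_shape
        r = np.where(occ.included, rm.rate, 0.0).reshape(nx, ny)
        m = occ.included.reshape(nx, ny).astype(float)
        rad = 8  # 4 sd
        ax = np.arange(-rad, rad + 1)
        k = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * 2.0**2))
        expect = np.zeros_like(r)
        for i in range(nx):
            for j in range(ny):
                if not m[i, j]:
                    continue
                num = den = 0.0
                for di in range(-rad, rad + 1):
                    for dj in range(-rad, rad + 1):
                        a, b = i + di, j + dj
                        if 0 <= a < nx and 0 <= b < ny and m[a, b]:
                            w = k[di + rad, dj + rad]
                            num += w * r[a, b]
                            den += w
                expect[i, j] = num / den
        np.testing.assert_allclose(
            rm.smoothed.reshape(nx, ny), expect, rtol=1e-6, atol=1e-9
        )

    def test_no_events_gives_zero_map(self, arena, short_traj):
        occ, rm = compute_maps(short_traj, np.zeros(len(short_traj), bool), arena)
        assert rm.rate.sum() == 0
        assert rm.mean_rate == 0


class TestMatchOccupancy:
    def test_identical_occupancy_keeps_everything(self):
        bins = np.array([0, 0, 1, 1, 2])
        ms = match_occupancy(bins, bins.copy(), 3, n_iterations=2, seed=0)
        assert all(len(k) == 5 for k in ms.keep_a + ms.keep_b)

    def test_min_rule_per_bin(self):
        a = np.zeros(10, int)
        b = np.zeros(4, int)
        ms = match_occupancy(a, b, 1, n_iterations=3, seed=1)
        for ka, kb in zip(ms.keep_a, ms.keep_b):
            assert len(ka) == len(kb) == 4

    def test_retained_counts_equal_across_conditions(self, rng):
        a = rng.integers(0, 8, 300)
        b = rng.integers(0, 8, 260)
        ms = match_occupancy(a, b, 8, n_iterations=5, seed=2)
        for ka, kb in zip(ms.keep_a, ms.keep_b):
            ca = np.bincount(a[ka], minlength=8)
            cb = np.bincount(b[kb], minlength=8)
            assert np.array_equal(ca, cb)
            assert np.array_equal(ca, np.minimum(np.bincount(a, minlength=8), np.bincount(b, minlength=8)))

    def test_averaging_over_iterations_reduces_variance(self, arena, short_traj, rng):
        # SD of the 50-iteration average across replicates < SD of single draws
        events = rng.random(len(short_traj)) < 0.03
        x = short_traj["x"].to_numpy()
        idx = arena.bin_index(x, short_traj["y"].to_numpy())
        left = np.flatnonzero(x < 25)
        right = np.flatnonzero(x >= 25)
        singles, means = [], []
        for rep in range(6):
            ms = match_occupancy(idx[left], idx[right], int(idx.max()) + 1, 20, seed=rep)
            vals = [events[left[k]].mean() for k in ms.keep_a]
            singles.append(vals[0])
            means.append(np.mean(vals))
        assert np.std(means) < np.std(singles) + 1e-12


class TestTrajectoryCSV:
    def test_roundtrip_and_derived_columns(self, tmp_path, short_traj):
        path = tmp_path / "traj.csv"
        short_traj[["t", "x", "y"]].to_csv(path, index=False)
        back = read_trajectory_csv(path)
        assert {"speed", "heading", "compartment"} <= set(back.columns)
        np.testing.assert_allclose(back["x"], short_traj["x"])
        # derived speed matches the generator's displacement speed (first
        # frame is a boundary case in both)
        np.testing.assert_allclose(
            back["speed"].to_numpy()[1:], short_traj["speed"].to_numpy()[1:], rtol=1e-6
        )

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"t": [0.0], "x": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing"):
            read_trajectory_csv(path)

    def test_nonmonotonic_time_rejected(self, tmp_path):
        path = tmp_path / "bad2.csv"
        pd.DataFrame({"t": [0.0, 0.0], "x": [1.0, 2.0], "y": [1.0, 2.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="increasing"):
            read_trajectory_csv(path)


class TestCoverage:
    def test_single_point_touches_one_bin(self, arena):
        traj = pd.DataFrame({"t": [0.0], "x": [5.0], "y": [5.0], "speed": [3.0]})
        nx, ny = arena.n_bins(1.8)
        assert spatial_coverage(traj, arena) == pytest.approx(1 / (nx * ny))

    def test_full_grid_coverage_is_one(self, arena):
        centers = arena.bin_centers(1.8)
        traj = pd.DataFrame(
            {"t": np.arange(len(centers)) / 30, "x": centers[:, 0], "y": centers[:, 1],
             "speed": np.full(len(centers), 5.0)}
        )
        assert spatial_coverage(traj, arena) == 1.0

    def test_empty_trajectory_rejected(self, arena):
        with pytest.raises(ValueError):
            spatial_coverage(pd.DataFrame({"t": [], "x": [], "y": [], "speed": []}), arena)
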