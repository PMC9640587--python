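"""Event binarization, occupancy/rate maps, and occupancy matching.

Deconvolved amplitude traces are binarized per neuron at a multiple of the
trace's standard deviation; trajectories are speed-filtered, binned on a
1.8 cm grid, and rate maps built as events per second of occupancy
(unsmoothed maps feed the spatial-information score, smoothed maps the
field-size and map-correlation measures). Occupancy matching equalizes the
per-bin sample counts of two conditions by random down-sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .arena import DEFAULT_BIN_CM, ArenaSpec

MIN_BIN_OCCUPANCY_S = 0.1


@dataclass
class EventMatrix:
    """Binarized calcium events alongside the source amplitudes.

    ``events[i, j]`` is True only where ``amplitudes[i, j]`` exceeds the
    neuron's threshold; ``excluded`` flags neurons with a degenerate
    (constant nonzero) amplitude trace.
    """

    amplitudes: np.ndarray
    events: np.ndarray
    frame_rate: float
    thresholds: np.ndarray
    excluded: np.ndarray

    @property
    def n_neurons(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.amplitudes.shape[1]


def binarize_events(
    amplitudes: np.ndarray, frame_rate: float = 30.0, k: float = 3.0
) -> EventMatrix:
    """Binarize deconvolved amplitudes at ``k`` x SD of each neuron's trace.

    The SD is the population standard deviation over all frames of the
    neuron, including zeros, so the rule is invariant to positive rescaling
    of a trace. Neurons with a constant nonzero trace (SD = 0 but activity
    present) cannot be thresholded and are flagged ``excluded``.
    """
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be non-negative")
    sd = amplitudes.std(axis=1)
    thresholds = k * sd
    excluded = (sd == 0) & (amplitudes.max(axis=1) > 0)
    events = amplitudes > thresholds[:, None]
    events[excluded] = False
    return EventMatrix(
        amplitudes=amplitudes,
        events=events,
        frame_rate=frame_rate,
        thresholds=thresholds,
        excluded=excluded,
    )


def read_trajectory_csv(path, arena: ArenaSpec | None = None) -> pd.DataFrame:
    """Load a trajectory from CSV (columns ``t, x, y`` at minimum).

    Speed, heading and the compartment label are derived when absent; ``t``
    must be strictly increasing.
    """
    traj = pd.read_csv(path)
    missing = {"t", "x", "y"} - set(traj.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    t = traj["t"].to_numpy(float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("trajectory timestamps must be strictly increasing")
    if "speed" not in traj.columns or "heading" not in traj.columns:
        x = traj["x"].to_numpy(float)
        y = traj["y"].to_numpy(float)
        dx = np.diff(x, prepend=x[0] if len(x) else 0.0)
        dy = np.diff(y, prepend=y[0] if len(y) else 0.0)
        dt = np.diff(t, prepend=t[0] - (t[1] - t[0]) if len(t) > 1 else 1.0)
        dt[dt <= 0] = np.inf
        if "speed" not in traj.columns:
            traj["speed"] = np.hypot(dx, dy) / dt
        if "heading" not in traj.columns:
            traj["heading"] = np.arctan2(dy, dx)
    if "compartment" not in traj.columns:
        if arena is None:
            arena = ArenaSpec()
        traj["compartment"] = arena.compartment_of(traj["x"].to_numpy())
    return traj


class EmptySelectionError(ValueError):
    """Raised when a filter removes every frame."""


def speed_filter(
    traj: pd.DataFrame, threshold: float = 2.0, require_nonempty: bool = True
) -> np.ndarray:
    """Boolean mask of frames with running speed >= threshold (cm/s)."""
    keep = traj["speed"].to_numpy() >= threshold
    if require_nonempty and not keep.any():
        raise EmptySelectionError("speed filter removed every frame")
    return keep


@dataclass
class OccupancyMap:
    """Per-bin occupancy seconds and probabilities on the flat bin grid.

    ``included`` marks bins with at least 0.1 s of occupancy; probabilities
    are normalized over included bins only.
    """

    seconds: np.ndarray  # (n_bins,)
    p: np.ndarray  # (n_bins,) sums to 1 over included
    included: np.ndarray  # (n_bins,) bool
    grid_shape: tuple[int, int]
    bin_cm: float


@dataclass
class RateMap:
    rate: np.ndarray  # unsmoothed events/s per bin
    smoothed: np.ndarray
    mean_rate: float  # session mean = sum P_i * rate_i over included bins
    peak_rate: float  # max of smoothed map over included bins
    n_events: int


def occupancy_map(
    bin_idx: np.ndarray,
    arena: ArenaSpec,
    frame_rate: float,
    bin_cm: float = DEFAULT_BIN_CM,
    min_occupancy_s: float = MIN_BIN_OCCUPANCY_S,
) -> OccupancyMap:
    nx, ny = arena.n_bins(bin_cm)
    n_bins = nx * ny
    counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
    seconds = counts / frame_rate
    included = seconds >= min_occupancy_s
    p = np.zeros(n_bins)
    tot = seconds[included].sum()
    if tot > 0:
        p[included] = seconds[included] / tot
    return OccupancyMap(
        seconds=seconds, p=p, included=included, grid_shape=(nx, ny), bin_cm=bin_cm
    )


def _smooth_map(
    rate: np.ndarray, included: np.ndarray, grid_shape: tuple[int, int], sd_bins: float
) -> np.ndarray:
    """Gaussian smoothing with the kernel renormalized over included bins."""
    r = np.where(included, rate, 0.0).reshape(grid_shape)
    m = included.reshape(grid_shape).astype(float)
    num = ndimage.gaussian_filter(r, sd_bins, mode="constant", truncate=4.0)
    den = ndimage.gaussian_filter(m, sd_bins, mode="constant", truncate=4.0)
    out = np.zeros_like(num)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return (out * m).ravel()


def rate_map(
    events_row: np.ndarray,
    bin_idx: np.ndarray,
    occ: OccupancyMap,
    smooth_sd_bins: float = 2.0,
) -> RateMap:
    """Event rate per spatial bin for one neuron (unsmoothed + smoothed)."""
    n_bins = len(occ.seconds)
    ev_counts = np.bincount(bin_idx[np.asarray(events_row, bool)], minlength=n_bins)
    rate = np.zeros(n_bins)
    vis = occ.seconds > 0
    rate[vis] = ev_counts[vis] / occ.seconds[vis]
    rate[~occ.included] = 0.0
    smoothed = _smooth_map(rate, occ.included, occ.grid_shape, smooth_sd_bins)
    mean_rate = float(np.sum(occ.p[occ.included] * rate[occ.included]))
    peak = float(smoothed[occ.included].max()) if occ.included.any() else 0.0
    return RateMap(
        rate=rate,
        smoothed=smoothed,
        mean_rate=mean_rate,
        peak_rate=peak,
        n_events=int(ev_counts[occ.included].sum()),
    )


def compute_maps(
    traj: pd.DataFrame,
    events_row: np.ndarray,
    arena: ArenaSpec,
    frame_rate: float = 30.0,
    bin_cm: float = DEFAULT_BIN_CM,
    smooth_sd_bins: float = 2.0,
) -> tuple[OccupancyMap, RateMap]:
    """Occupancy and rate map for one neuron from a (filtered) trajectory."""
    bin_idx = arena.bin_index(traj["x"].to_numpy(), traj["y"].to_numpy(), bin_cm)
    occ = occupancy_map(bin_idx, arena, frame_rate, bin_cm)
    return occ, rate_map(events_row, bin_idx, occ, smooth_sd_bins)


@dataclass
class MatchedSampleSet:
    """Frame indices retained per condition for each matching iteration."""

    keep_a: list[np.ndarray]
    keep_b: list[np.ndarray]
    seed: int

    @property
    def n_iterations(self) -> int:
        return len(self.keep_a)


def match_occupancy(
    bins_a: np.ndarray,
    bins_b: np.ndarray,
    n_bins: int,
    n_iterations: int = 50,
    seed: int = 0,
) -> MatchedSampleSet:
    """Down-sample two conditions so per-bin frame counts match.

    For every spatial bin both conditions retain min(count_a, count_b)
    frames, removing surplus frames uniformly at random from the denser
    condition. Returns retained frame indices (into the respective input
    arrays) for each iteration; one master seed spawns per-iteration seeds.
    """
    bins_a = np.asarray(bins_a)
    bins_b = np.asarray(bins_b)
    count_a = np.bincount(bins_a, minlength=n_bins)
    count_b = np.bincount(bins_b, minlength=n_bins)
    target = np.minimum(count_a, count_b)
    ss = np.random.SeedSequence(seed)
    keep_a: list[np.ndarray] = []
    keep_b: list[np.ndarray] = []

    order_a = np.argsort(bins_a, kind="stable")
    order_b = np.argsort(bins_b, kind="stable")
    starts_a = np.searchsorted(bins_a[order_a], np.arange(n_bins))
    starts_b = np.searchsorted(bins_b[order_b], np.arange(n_bins))
    ends_a = np.searchsorted(bins_a[order_a], np.arange(n_bins), side="right")
    ends_b = np.searchsorted(bins_b[order_b], np.arange(n_bins), side="right")

    for child in ss.spawn(n_iterations):
        rng = np.random.default_rng(child)
        ka: list[np.ndarray] = []
        kb: list[np.ndarray] = []
        for b in np.flatnonzero(target):
            ia = order_a[starts_a[b] : ends_a[b]]
            ib = order_b[starts_b[b] : ends_b[b]]
            if len(ia) > target[b]:
                ia = rng.choice(ia, size=target[b], replace=False)
            if len(ib) > target[b]:
                ib = rng.choice(ib, size=target[b], replace=False)
            ka.append(ia)
            kb.append(ib)
        keep_a.append(np.sort(np.concatenate(ka)) if ka else np.array([], int))
        keep_b.append(np.sort(np.concatenate(kb)) if kb else np.array([], int))
    return MatchedSampleSet(keep_a=keep_a, keep_b=keep_b, seed=seed)


def spatial_coverage(
    traj: pd.DataFrame, arena: ArenaSpec, bin_cm: float = DEFAULT_BIN_CM
) -> float:
    """Fraction of arena bins the trajectory physically visited."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    nx, ny = arena.n_bins(bin_cm)
    idx = arena.bin_index(traj["x"].to_numpy(), traj["y"].to_numpy(), bin_cm)
    return len(np.unique(idx)) / (nx * ny)
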