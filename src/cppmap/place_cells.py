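"""Place-cell identification and field metrics.

A neuron's spatial information content (bits/spike) is

    SI = sum_i P_i (lambda_i / lambda) log2(lambda_i / lambda)

over occupancy-included bins, with P_i the occupancy probability of bin i,
lambda_i the unsmoothed event rate in bin i, and lambda the mean rate. A
neuron is significantly tuned when its SI exceeds the 95th percentile of SI
values recomputed after circularly shifting its event train (1000 shuffles).
Place cells are called via a place-cell agreement index (PCI): the shuffle
test is repeated on 20 occupancy-matched down-samplings across the two
compartments, and the PCI is the fraction of iterations that pass; PCI >= 0.3
together with a mean event rate >= 0.1 Hz defines a place cell in a
compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .arena import DEFAULT_BIN_CM, LEFT, RIGHT, ArenaSpec
from .preprocessing import (
    MIN_BIN_OCCUPANCY_S,
    OccupancyMap,
    RateMap,
    _smooth_map,
    match_occupancy,
    speed_filter,
)

DEFAULT_SHIFT_RANGE = (0.05, 0.95)


# ---------------------------------------------------------------------------
# spatial information
# ---------------------------------------------------------------------------


def spatial_information(occ: OccupancyMap, rm: RateMap) -> float:
    """Spatial information in bits/spike from unsmoothed rates (NaN if silent)."""
    return _si_single(occ.p[occ.included], rm.rate[occ.included])


def _si_single(p: np.ndarray, rate: np.ndarray) -> float:
    lam = float(np.sum(p * rate))
    if lam <= 0:
        return float("nan")
    pos = rate > 0
    ratio = rate[pos] / lam
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


def _si_from_counts(counts: np.ndarray, seconds: np.ndarray) -> np.ndarray:
    """Vectorized SI for rows of per-bin event counts over included bins.

    ``counts`` is (n_shuffles, n_bins); ``seconds`` the occupancy seconds of
    the same bins. Rows with zero events give NaN.
    """
    total = seconds.sum()
    p = seconds / total
    lam = counts.sum(axis=1) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        lam_i = counts / seconds
        ratio = lam_i / lam[:, None]
        term = np.where(counts > 0, ratio * np.log2(ratio), 0.0)
    si = (p * term).sum(axis=1)
    si[lam <= 0] = np.nan
    return si


def _shuffled_event_counts(
    event_pos: np.ndarray,
    bin_of_frame: np.ndarray,
    inc_lookup: np.ndarray,
    n_inc: int,
    shifts: np.ndarray,
) -> np.ndarray:
    """(n_shifts, n_inc) event counts after circular shifts of the event train."""
    t = len(bin_of_frame)
    pos = (event_pos[None, :] + shifts[:, None]) % t
    cols = inc_lookup[bin_of_frame[pos]]
    rows = np.broadcast_to(np.arange(len(shifts))[:, None], cols.shape)
    ok = cols >= 0
    flat = rows[ok] * n_inc + cols[ok]
    return np.bincount(flat, minlength=len(shifts) * n_inc).reshape(len(shifts), n_inc)


def shuffle_threshold(
    events_row: np.ndarray,
    bin_of_frame: np.ndarray,
    seconds: np.ndarray,
    included: np.ndarray,
    rng: np.random.Generator,
    n_shuffles: int = 1000,
    pct: float = 95.0,
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE,
) -> tuple[float, float]:
    """(true SI, shuffle-percentile threshold) for one event train.

    Shifts are uniform over [5%, 95%] of the trace length, so the identity
    shift is never drawn. Neurons with fewer than 2 events return NaN.
    """
    event_pos = np.flatnonzero(np.asarray(events_row, bool))
    t = len(bin_of_frame)
    inc_ids = np.flatnonzero(included)
    inc_lookup = np.full(len(included), -1)
    inc_lookup[inc_ids] = np.arange(len(inc_ids))
    sec = seconds[inc_ids]

    true_counts = _shuffled_event_counts(
        event_pos, bin_of_frame, inc_lookup, len(inc_ids), np.zeros(1, int)
    )
    true_si = _si_from_counts(true_counts, sec)[0]
    if len(event_pos) < 2:
        return float(true_si), float("nan")
    lo = max(int(shift_range[0] * t), 1)
    hi = max(int(shift_range[1] * t), lo + 1)
    shifts = rng.integers(lo, hi, size=n_shuffles)

    # For counts c_b over bins with occupancy sec_b (T_s = sum sec_b) and k
    # retained events, Eq.-style SI reduces to
    #   SI = (1/k) [ sum_b c_b log2 c_b - sum_b c_b log2 sec_b ] + log2(T_s/k),
    # which needs only two table lookups per event instead of a full
    # per-bin rate map per shuffle.
    n_inc = len(inc_ids)
    pos = (event_pos[None, :] + shifts[:, None]) % t
    cols = inc_lookup[bin_of_frame[pos]]
    ok = cols >= 0
    rows = np.broadcast_to(np.arange(n_shuffles)[:, None], cols.shape)
    flat = rows[ok] * n_inc + cols[ok]
    counts = np.bincount(flat, minlength=n_shuffles * n_inc)
    nz = np.flatnonzero(counts)
    c = counts[nz]
    log_tab = np.log2(np.arange(1, len(event_pos) + 1, dtype=float))
    clogc = c * log_tab[c - 1]
    clogsec = c * np.log2(sec)[nz % n_inc]
    shuf_row = nz // n_inc
    k_row = np.bincount(shuf_row, weights=c.astype(float), minlength=n_shuffles)
    num = np.bincount(shuf_row, weights=clogc - clogsec, minlength=n_shuffles)
    total_sec = sec.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        si = num / k_row + np.log2(total_sec / k_row)
    si[k_row == 0] = np.nan
    return float(true_si), float(np.nanpercentile(si, pct))


# ---------------------------------------------------------------------------
# PCI classification
# ---------------------------------------------------------------------------


@dataclass
class PlaceCellConfig:
    bin_cm: float = DEFAULT_BIN_CM
    speed_threshold: float = 2.0
    n_iterations: int = 20
    n_shuffles: int = 1000
    pct: float = 95.0
    pci_threshold: float = 0.3
    min_rate_hz: float = 0.1
    min_matched_s: float = 60.0
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE


def _local_bins(
    x: np.ndarray, y: np.ndarray, arena: ArenaSpec, bin_cm: float
) -> np.ndarray:
    """Within-compartment (homotopic) flat bin index for each position."""
    nxl = int(np.ceil(arena.compartment_w / bin_cm))
    nyl = int(np.ceil(arena.height / bin_cm))
    xl = np.where(x >= arena.midline_x, x - arena.compartment_w, x)
    ix = np.clip((xl / bin_cm).astype(int), 0, nxl - 1)
    iy = np.clip((y / bin_cm).astype(int), 0, nyl - 1)
    return ix * nyl + iy


def compartment_grid_shape(arena: ArenaSpec, bin_cm: float = DEFAULT_BIN_CM) -> tuple[int, int]:
    return (
        int(np.ceil(arena.compartment_w / bin_cm)),
        int(np.ceil(arena.height / bin_cm)),
    )


def classify_place_cells(
    traj: pd.DataFrame,
    events: np.ndarray,
    arena: ArenaSpec,
    frame_rate: float = 30.0,
    config: PlaceCellConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-neuron, per-compartment place-cell decisions via the PCI.

    For each of ``n_iterations`` occupancy matchings across the two
    compartments (homotopic 1.8 cm bins), the circular-shuffle spatial
    information test is run within each compartment; the PCI is the fraction
    of iterations a neuron passes. Returns a tidy DataFrame with one row per
    neuron x compartment: ``neuron, compartment, si, pci, mean_rate_hz,
    is_place_cell, unreliable``.
    """
    cfg = config or PlaceCellConfig()
    events = np.atleast_2d(np.asarray(events, bool))
    n_neurons = events.shape[0]

    keep = speed_filter(traj, cfg.speed_threshold)
    x = traj["x"].to_numpy()[keep]
    y = traj["y"].to_numpy()[keep]
    ev = events[:, keep]
    mean_rate = ev.sum(axis=1) * frame_rate / ev.shape[1]
    rate_ok = mean_rate >= cfg.min_rate_hz

    local = _local_bins(x, y, arena, cfg.bin_cm)
    nxl, nyl = compartment_grid_shape(arena, cfg.bin_cm)
    n_local = nxl * nyl
    is_left = x < arena.midline_x
    frames = {LEFT: np.flatnonzero(is_left), RIGHT: np.flatnonzero(~is_left)}

    matched = match_occupancy(
        local[frames[LEFT]],
        local[frames[RIGHT]],
        n_local,
        n_iterations=cfg.n_iterations,
        seed=seed,
    )

    ss = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    rngs = [np.random.default_rng(c) for c in ss.spawn(cfg.n_iterations)]
    indicators = {c: np.zeros((cfg.n_iterations, n_neurons), bool) for c in (LEFT, RIGHT)}
    si_sum = {c: np.zeros(n_neurons) for c in (LEFT, RIGHT)}
    si_count = {c: np.zeros(n_neurons) for c in (LEFT, RIGHT)}
    unreliable = False

    for it in range(cfg.n_iterations):
        rng = rngs[it]
        for comp, keep_local in ((LEFT, matched.keep_a[it]), (RIGHT, matched.keep_b[it])):
            fidx = frames[comp][keep_local]  # indices into filtered sequence
            if len(fidx) / frame_rate < cfg.min_matched_s:
                unreliable = True
            bins_sub = local[fidx]
            seconds = np.bincount(bins_sub, minlength=n_local) / frame_rate
            included = seconds >= MIN_BIN_OCCUPANCY_S
            if not included.any():
                continue
            ev_sub = ev[:, fidx]
            for n in range(n_neurons):
                if not rate_ok[n]:
                    continue
                si, thr = shuffle_threshold(
                    ev_sub[n],
                    bins_sub,
                    seconds,
                    included,
                    rng,
                    n_shuffles=cfg.n_shuffles,
                    pct=cfg.pct,
                    shift_range=cfg.shift_range,
                )
                if np.isfinite(si):
                    si_sum[comp][n] += si
                    si_count[comp][n] += 1
                indicators[comp][it, n] = np.isfinite(thr) and si > thr

    rows = []
    for comp in (LEFT, RIGHT):
        pci = indicators[comp].mean(axis=0)
        with np.errstate(invalid="ignore"):
            si_mean = np.where(si_count[comp] > 0, si_sum[comp] / np.maximum(si_count[comp], 1), np.nan)
        for n in range(n_neurons):
            rows.append(
                {
                    "neuron": n,
                    "compartment": comp,
                    "si": si_mean[n],
                    "pci": pci[n],
                    "mean_rate_hz": mean_rate[n],
                    "is_place_cell": bool(
                        rate_ok[n] and pci[n] >= cfg.pci_threshold
                    ),
                    "unreliable": unreliable,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# field size and map metrics
# ---------------------------------------------------------------------------


@dataclass
class FieldMeasure:
    area_cm2: float
    n_fields: int
    peak_rate: float


_CONN8 = np.ones((3, 3), int)


def field_size(
    smoothed: np.ndarray,
    included: np.ndarray,
    grid_shape: tuple[int, int],
    bin_cm: float = DEFAULT_BIN_CM,
) -> FieldMeasure:
    """Area of the largest place field (>= 50% of peak, 8-connected bins)."""
    m = np.where(included, smoothed, 0.0).reshape(grid_shape)
    peak = m.max()
    if peak <= 0:
        return FieldMeasure(area_cm2=float("nan"), n_fields=0, peak_rate=0.0)
    above = m >= 0.5 * peak
    labels, n_fields = ndimage.label(above, structure=_CONN8)
    sizes = np.bincount(labels.ravel())[1:]
    area = float(sizes.max()) * bin_cm**2
    return FieldMeasure(area_cm2=area, n_fields=int(n_fields), peak_rate=float(peak))


def map_metrics(
    map_a: np.ndarray,
    map_b: np.ndarray,
    included_a: np.ndarray,
    included_b: np.ndarray,
    min_common: int = 10,
) -> dict[str, float]:
    """Pearson correlation and peak/mean rates of two matched rate maps.

    The correlation uses mutually included bins (pairwise complete); the
    peak-rate change is ``|peak_a - peak_b| / max(peak_a, peak_b)``.
    """
    common = included_a & included_b
    a = map_a[common]
    b = map_b[common]
    if common.sum() < min_common or a.std() == 0 or b.std() == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(a, b)[0, 1])
    peak_a = float(map_a[included_a].max()) if included_a.any() else 0.0
    peak_b = float(map_b[included_b].max()) if included_b.any() else 0.0
    top = max(peak_a, peak_b)
    change = float(abs(peak_a - peak_b) / top) if top > 0 else float("nan")
    return {
        "correlation": corr,
        "peak_a": peak_a,
        "peak_b": peak_b,
        "mean_a": float(a.mean()) if common.any() else float("nan"),
        "mean_b": float(b.mean()) if common.any() else float("nan"),
        "peak_rate_change": change,
    }


# ---------------------------------------------------------------------------
# matched cross-compartment maps (shared by cell typing)
# ---------------------------------------------------------------------------


def inter_compartment_correlations(
    traj: pd.DataFrame,
    events: np.ndarray,
    arena: ArenaSpec,
    frame_rate: float = 30.0,
    bin_cm: float = DEFAULT_BIN_CM,
    smooth_sd_bins: float = 2.0,
    n_iterations: int = 50,
    speed_threshold: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-neuron inter-compartment rate-map correlation, occupancy matched.

    Left and right compartment rate maps are built on the homotopic
    within-compartment grid from occupancy-matched frames and correlated;
    values are averaged over matching iterations. Neurons without a defined
    correlation in any iteration give NaN.
    """
    events = np.atleast_2d(np.asarray(events, bool))
    n_neurons = events.shape[0]
    keep = speed_filter(traj, speed_threshold)
    x = traj["x"].to_numpy()[keep]
    y = traj["y"].to_numpy()[keep]
    ev = events[:, keep]
    local = _local_bins(x, y, arena, bin_cm)
    nxl, nyl = compartment_grid_shape(arena, bin_cm)
    n_local = nxl * nyl
    is_left = x < arena.midline_x
    fl = np.flatnonzero(is_left)
    fr = np.flatnonzero(~is_left)
    matched = match_occupancy(local[fl], local[fr], n_local, n_iterations, seed)

    acc = np.zeros(n_neurons)
    cnt = np.zeros(n_neurons)
    for it in range(matched.n_iterations):
        maps = {}
        for comp, base, keep_local in ((LEFT, fl, matched.keep_a[it]), (RIGHT, fr, matched.keep_b[it])):
            fidx = base[keep_local]
            bins_sub = local[fidx]
            seconds = np.bincount(bins_sub, minlength=n_local) / frame_rate
            included = seconds >= MIN_BIN_OCCUPANCY_S
            ev_sub = ev[:, fidx]
            en, et = np.nonzero(ev_sub)
            counts = np.bincount(
                en * n_local + bins_sub[et], minlength=n_neurons * n_local
            ).reshape(n_neurons, n_local)
            with np.errstate(divide="ignore", invalid="ignore"):
                rate = np.where(seconds > 0, counts / seconds, 0.0)
            rate[:, ~included] = 0.0
            sm = np.stack(
                [_smooth_map(r, included, (nxl, nyl), smooth_sd_bins) for r in rate]
            )
            maps[comp] = (sm, included)
        sa, ia = maps[LEFT]
        sb, ib = maps[RIGHT]
        common = ia & ib
        if common.sum() < 10:
            continue
        a = sa[:, common]
        b = sb[:, common]
        a0 = a - a.mean(axis=1, keepdims=True)
        b0 = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((a0**2).sum(axis=1) * (b0**2).sum(axis=1))
        ok = denom > 0
        corr = np.full(n_neurons, np.nan)
        corr[ok] = (a0 * b0).sum(axis=1)[ok] / denom[ok]
        fin = np.isfinite(corr)
        acc[fin] += corr[fin]
        cnt[fin] += 1
    out = np.full(n_neurons, np.nan)
    ok = cnt > 0
    out[ok] = acc[ok] / cnt[ok]
    return out
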