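"""Synthetic two-compartment CPP experiments with known ground truth.

Generates the full substrate the analysis pipeline consumes: smoothed
random-walk foraging trajectories with a controllable compartment-occupancy
bias, populations of neurons with 2D Gaussian place tuning (homotopic fields
across compartments with rate differences, optional head-direction and speed
modulation), planted across-session effects (compartment-specific field
disappearance/appearance, global remapping), temporally co-active clusters
tied to spatial sectors, and anatomical centroids.

The trajectory model is a momentum random walk with reflective walls; the
midline wall can only be crossed through the door opening, and occupancy
bias is implemented as a gentle heading drift toward the target compartment
(never teleportation), which preserves the continuity assumptions of the
two-step decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .arena import LEFT, RIGHT, ArenaSpec

SESSION_ORDER = ("prebaseline", "baseline", "test1", "test2")
TEST_SESSIONS = ("test1", "test2")

EFFECT_STABLE = "stable"
EFFECT_DISAPPEAR = "disappear"
EFFECT_APPEAR = "appear"
EFFECT_REMAP = "remap"

SECTORS = ("SW", "NW", "SE", "NE", "center")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Behavioral simulation parameters for one session.

    Speeds are cm/s; the momentum random walk draws a target speed via an
    Ornstein-Uhlenbeck update and turns with Gaussian heading noise. Occupancy
    bias pulls the heading toward the centre of ``bias_compartment`` whenever
    the animal is in the other compartment; ``occupancy_bias`` = 0 leaves the
    walk unbiased.
    """

    duration_s: float = 1200.0
    frame_rate: float = 30.0
    speed_mean: float = 12.0
    speed_sd: float = 5.0
    max_speed: float = 30.0
    pause_prob: float = 0.03
    turn_sd: float = 0.35  # rad per frame
    hd_noise_sd: float = 0.25  # head direction vs heading, rad
    occupancy_bias: float = 0.0
    bias_compartment: str = LEFT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not 0.0 <= self.occupancy_bias <= 1.0:
            raise ValueError("occupancy_bias must be in [0, 1]")


@dataclass
class PopulationSpec:
    """Composition of a synthetic neuron population.

    Counts of session-effect labels; remaining neurons are stable. Peak event
    probabilities are per frame; field widths in cm. Each neuron carries
    homotopic fields in both compartments (independently present with
    ``field_prob``), with the secondary compartment's peak scaled into
    [rate_diff_lo, rate_diff_hi] to emulate rate remapping.
    """

    n_neurons: int = 200
    n_disappear_pref: int = 0
    n_disappear_nonpref: int = 0
    n_appear_pref: int = 0
    n_appear_nonpref: int = 0
    n_remap: int = 0
    n_untuned: int = 0
    peak_p: float = 0.12
    peak_p_sd: float = 0.04
    field_sigma: float = 4.0
    field_sigma_sd: float = 0.8
    field_prob: float = 0.85
    rate_diff_lo: float = 0.35
    rate_diff_hi: float = 1.0
    baseline_event_p: float = 0.002
    hd_kappa: float = 0.0
    speed_exp: float = 0.0
    n_clusters: int = 5
    cluster_jitter: float = 3.0
    cluster_coactivity: float = 0.6
    cluster_tau_s: float = 2.0
    anatomy_clustered: bool = False
    anatomy_extent_px: float = 600.0

    def total_effect(self) -> int:
        return (
            self.n_disappear_pref
            + self.n_disappear_nonpref
            + self.n_appear_pref
            + self.n_appear_nonpref
            + self.n_remap
            + self.n_untuned
        )


@dataclass
class ExperimentConfig:
    """Session roles and occupancy-bias schedule of one CPP experiment."""

    preferred_compartment: str = LEFT
    drug_compartment: str = RIGHT
    duration_s: float = 1200.0
    frame_rate: float = 30.0
    baseline_bias: float = 0.35
    test_bias: float = 0.5
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted tuning and session-effect labels for a neuron population.

    Arrays are indexed by neuron; ``centers[n, c]`` is the (x, y) field
    centre in compartment c (0 = left, 1 = right), ``peak_p[n, c]`` the
    peak per-frame event probability of that field (0 = no field).
    """

    centers: np.ndarray  # (N, 2, 2)
    peak_p: np.ndarray  # (N, 2)
    sigma: np.ndarray  # (N,)
    effect: np.ndarray  # (N,) str
    effect_compartment: np.ndarray  # (N,) str ('left'/'right'/'none')
    remap_centers: np.ndarray  # (N, 2, 2)
    cluster: np.ndarray  # (N,) int
    sector: np.ndarray  # (N,) str
    centroid: np.ndarray  # (N, 2) anatomical, px
    hd_pref: np.ndarray  # (N,) rad
    hd_kappa: np.ndarray  # (N,)
    speed_exp: np.ndarray  # (N,)
    baseline_event_p: float = 0.002
    cluster_coactivity: float = 0.6
    cluster_tau_s: float = 2.0
    frame_rate: float = 30.0

    @property
    def n_neurons(self) -> int:
        return self.centers.shape[0]


@dataclass
class Session:
    trajectory: pd.DataFrame
    amplitudes: np.ndarray  # (N, T)


@dataclass
class SyntheticExperiment:
    arena: ArenaSpec
    sessions: dict[str, Session]
    truth: GroundTruth
    config: ExperimentConfig

    @property
    def session_names(self) -> tuple[str, ...]:
        return SESSION_ORDER


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------


def simulate_trajectory(
    arena: ArenaSpec, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate a foraging trajectory in the two-compartment arena.

    Returns a DataFrame with columns ``t, x, y, speed, heading, compartment``.
    Speed is recomputed from frame-to-frame displacement; head direction is
    the movement heading plus wrapped Gaussian noise. Deterministic for a
    given config (seed) / rng.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.frame_rate
    n = int(round(config.duration_s * config.frame_rate))
    cols = ["t", "x", "y", "speed", "heading", "compartment"]
    if n == 0:
        return pd.DataFrame({c: [] for c in cols})

    x = np.empty(n)
    y = np.empty(n)
    # start in the centre of a random compartment
    side = rng.integers(2)
    px = (0.5 + side) * arena.compartment_w
    py = arena.compartment_h / 2.0
    theta = rng.uniform(-np.pi, np.pi)
    s = max(config.speed_mean, 0.0)

    # The animal shuttles between compartments in episodic "leave bouts"
    # (head for the door, cross, resume foraging). Occupancy bias is an
    # asymmetry in the bout rate — leaving the non-preferred compartment
    # sooner — rather than a continuous drift, so within-compartment
    # foraging coverage stays undistorted, which the occupancy-matching
    # analyses downstream assume.
    door_x = arena.midline_x
    door_y = arena.compartment_h / 2.0
    p_shuttle = 0.003
    p_bias = 0.004 * config.occupancy_bias
    bout_cap = int(3.0 * config.frame_rate)
    bout = 0
    bout_side = True

    turn = rng.normal(0.0, config.turn_sd, size=n)
    ou = rng.normal(0.0, 1.0, size=n)
    pauses = rng.random(n) < config.pause_prob
    leave_draw = rng.random(n)
    eps = 1e-9

    for i in range(n):
        # Ornstein-Uhlenbeck speed with occasional pauses; the slow mean
        # reversion gives speed an autocorrelation time of roughly a second
        s = s + 0.05 * (config.speed_mean - s) + 0.22 * config.speed_sd * ou[i]
        s = min(max(s, 0.0), config.max_speed)
        step = 0.0 if pauses[i] else s * dt

        theta += turn[i]
        on_left = px < arena.midline_x
        in_target = on_left == (config.bias_compartment == LEFT)
        if bout == 0:
            rate = p_shuttle if in_target else p_shuttle + p_bias
            if leave_draw[i] < rate:
                bout = bout_cap
                bout_side = on_left
        elif on_left != bout_side:
            bout = 0  # crossed; resume foraging
        if bout > 0:
            target = np.arctan2(door_y - py, door_x - px)
            d = np.angle(np.exp(1j * (target - theta)))
            theta += 0.25 * d
            bout -= 1

        nx = px + step * np.cos(theta)
        ny = py + step * np.sin(theta)

        # midline wall: crossing allowed only through the door
        if (px - arena.midline_x) * (nx - arena.midline_x) < 0:
            frac = (arena.midline_x - px) / (nx - px + eps)
            y_cross = py + frac * (ny - py)
            if not (arena.door_lo <= y_cross <= arena.door_hi):
                nx = 2.0 * arena.midline_x - nx  # reflect off the wall

        # outer walls
        if nx < 0.0:
            nx = -nx
        elif nx > arena.width:
            nx = 2.0 * arena.width - nx
        if ny < 0.0:
            ny = -ny
        elif ny > arena.height:
            ny = 2.0 * arena.height - ny
        nx = min(max(nx, 0.0), arena.width)
        ny = min(max(ny, 0.0), arena.height)

        if step > eps:
            theta = np.arctan2(ny - py, nx - px)
        px, py = nx, ny
        x[i] = px
        y[i] = py

    t = np.arange(n) * dt
    dx = np.diff(x, prepend=x[0])
    dy = np.diff(y, prepend=y[0])
    speed = np.hypot(dx, dy) / dt
    if n > 1:
        speed[0] = speed[1]
    heading = np.arctan2(dy, dx)
    if n > 1:
        heading[0] = heading[1]
    heading = np.angle(
        np.exp(1j * (heading + rng.normal(0.0, config.hd_noise_sd, size=n)))
    )
    return pd.DataFrame(
        {
            "t": t,
            "x": x,
            "y": y,
            "speed": speed,
            "heading": heading,
            "compartment": arena.compartment_of(x),
        }
    )


# ---------------------------------------------------------------------------
# population ground truth
# ---------------------------------------------------------------------------


def _sector_centers(arena: ArenaSpec) -> dict[str, np.ndarray]:
    """Homotopic field-centre pairs (left, right compartment) per sector."""
    w, h = arena.compartment_w, arena.compartment_h
    lo_x, hi_x = 0.25 * w, 0.75 * w
    lo_y, hi_y = 0.25 * h, 0.75 * h
    out = {
        "SW": np.array([[lo_x, lo_y], [w + lo_x, lo_y]]),
        "NW": np.array([[lo_x, hi_y], [w + lo_x, hi_y]]),
        "SE": np.array([[hi_x, lo_y], [w + hi_x, lo_y]]),
        "NE": np.array([[hi_x, hi_y], [w + hi_x, hi_y]]),
        "center": np.array([[w, h / 2.0], [w, h / 2.0]]),
    }
    return out


def make_population(
    arena: ArenaSpec, spec: PopulationSpec, rng: np.random.Generator
) -> GroundTruth:
    """Draw a neuron population with planted tuning, effects and clusters."""
    n = spec.n_neurons
    if spec.total_effect() > n:
        raise ValueError("effect counts exceed total neuron count")

    sectors = _sector_centers(arena)
    cluster = np.arange(n) % spec.n_clusters
    rng.shuffle(cluster)
    sector = np.array([SECTORS[c % len(SECTORS)] for c in cluster])

    centers = np.empty((n, 2, 2))
    for i in range(n):
        base = sectors[sector[i]]
        jit = rng.normal(0.0, spec.cluster_jitter, size=(2,))
        for c in range(2):
            cx = np.clip(base[c, 0] + jit[0], 1.0, arena.width - 1.0)
            cy = np.clip(base[c, 1] + jit[1], 1.0, arena.height - 1.0)
            centers[i, c] = (cx, cy)

    peak = np.clip(
        rng.normal(spec.peak_p, spec.peak_p_sd, size=n), 0.02, 0.6
    )
    diff = rng.uniform(spec.rate_diff_lo, spec.rate_diff_hi, size=n)
    strong = rng.integers(2, size=n)  # which compartment carries the full peak
    peak_p = np.empty((n, 2))
    peak_p[np.arange(n), strong] = peak
    peak_p[np.arange(n), 1 - strong] = peak * diff
    present = rng.random((n, 2)) < spec.field_prob
    peak_p[~present] = 0.0

    sigma = np.clip(
        rng.normal(spec.field_sigma, spec.field_sigma_sd, size=n), 1.5, None
    )

    effect = np.full(n, EFFECT_STABLE, dtype=object)
    effect_comp = np.full(n, "none", dtype=object)
    order = rng.permutation(n)
    pos = 0

    def take(k: int) -> np.ndarray:
        nonlocal pos
        idx = order[pos : pos + k]
        pos += k
        return idx

    # the "preferred" compartment is resolved at experiment-assembly time;
    # here we store left/right directly, with pref = left by convention of
    # ExperimentConfig defaults (simulate_experiment remaps if needed).
    for count, label, comp in (
        (spec.n_disappear_pref, EFFECT_DISAPPEAR, "pref"),
        (spec.n_disappear_nonpref, EFFECT_DISAPPEAR, "nonpref"),
        (spec.n_appear_pref, EFFECT_APPEAR, "pref"),
        (spec.n_appear_nonpref, EFFECT_APPEAR, "nonpref"),
        (spec.n_remap, EFFECT_REMAP, "none"),
        (spec.n_untuned, "untuned", "none"),
    ):
        idx = take(count)
        effect[idx] = label
        effect_comp[idx] = comp

    untuned = effect == "untuned"
    peak_p[untuned] = 0.0
    effect[untuned] = EFFECT_STABLE

    remap_centers = centers.copy()
    is_remap = effect == EFFECT_REMAP
    for i in np.flatnonzero(is_remap):
        for c in range(2):
            remap_centers[i, c] = (
                rng.uniform(2.0 + c * arena.compartment_w, (1 + c) * arena.compartment_w - 2.0),
                rng.uniform(2.0, arena.height - 2.0),
            )

    if spec.anatomy_clustered:
        grid = np.array(
            [
                [0.25, 0.25],
                [0.25, 0.75],
                [0.75, 0.25],
                [0.75, 0.75],
                [0.5, 0.5],
            ]
        ) * spec.anatomy_extent_px
        centroid = grid[cluster % 5] + rng.normal(0.0, 0.04 * spec.anatomy_extent_px, size=(n, 2))
    else:
        centroid = rng.uniform(0.0, spec.anatomy_extent_px, size=(n, 2))

    hd_pref = rng.uniform(-np.pi, np.pi, size=n)
    hd_kappa = np.full(n, spec.hd_kappa, dtype=float)
    speed_exp = np.full(n, spec.speed_exp, dtype=float)

    return GroundTruth(
        centers=centers,
        peak_p=peak_p,
        sigma=sigma,
        effect=effect,
        effect_compartment=effect_comp,
        remap_centers=remap_centers,
        cluster=cluster,
        sector=sector,
        centroid=centroid,
        hd_pref=hd_pref,
        hd_kappa=hd_kappa,
        speed_exp=speed_exp,
        baseline_event_p=spec.baseline_event_p,
        cluster_coactivity=spec.cluster_coactivity,
        cluster_tau_s=spec.cluster_tau_s,
    )


def resolve_effect_compartments(truth: GroundTruth, preferred: str) -> GroundTruth:
    """Replace 'pref'/'nonpref' effect-compartment tags with left/right."""
    nonpref = RIGHT if preferred == LEFT else LEFT
    comp = truth.effect_compartment.copy()
    comp[comp == "pref"] = preferred
    comp[comp == "nonpref"] = nonpref
    # a 'disappear' label is only meaningful if the neuron has a baseline
    # field in the designated compartment; plant one if the draw left it out
    peak_p = truth.peak_p.copy()
    fill = np.median(peak_p[peak_p > 0]) if np.any(peak_p > 0) else 0.1
    for c, name in enumerate((LEFT, RIGHT)):
        need = (truth.effect == EFFECT_DISAPPEAR) & (comp == name) & (peak_p[:, c] == 0.0)
        peak_p[need, c] = fill
    return replace(truth, effect_compartment=comp, peak_p=peak_p)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


def _field_probability(
    truth: GroundTruth, traj: pd.DataFrame, session: str
) -> np.ndarray:
    """Per-frame event probability (N, T) from planted tuning + effects."""
    x = traj["x"].to_numpy()
    y = traj["y"].to_numpy()
    v = traj["speed"].to_numpy()
    hd = traj["heading"].to_numpy()
    n = truth.n_neurons
    t = len(x)
    is_test = session in TEST_SESSIONS

    p = np.full((n, t), truth.baseline_event_p)
    comp_names = (LEFT, RIGHT)
    use_centers = np.where(
        (truth.effect == EFFECT_REMAP)[:, None, None] & is_test,
        truth.remap_centers,
        truth.centers,
    )
    for c in range(2):
        peak = truth.peak_p[:, c].copy()
        off = np.zeros(n, dtype=bool)
        if is_test:
            off |= (truth.effect == EFFECT_DISAPPEAR) & (
                truth.effect_compartment == comp_names[c]
            )
        else:
            off |= (truth.effect == EFFECT_APPEAR) & (
                truth.effect_compartment == comp_names[c]
            )
        on = (truth.effect == EFFECT_APPEAR) & (
            truth.effect_compartment == comp_names[c]
        )
        if is_test:
            # appeared fields switch on at a default strength if absent
            peak = np.where(on & (peak == 0.0), np.median(peak[peak > 0.0]) if np.any(peak > 0) else 0.1, peak)
        peak = np.where(off, 0.0, peak)
        cx = use_centers[:, c, 0][:, None]
        cy = use_centers[:, c, 1][:, None]
        d2 = (x[None, :] - cx) ** 2 + (y[None, :] - cy) ** 2
        p += peak[:, None] * np.exp(-d2 / (2.0 * truth.sigma[:, None] ** 2))

    mod = np.ones((n, t))
    tuned_hd = truth.hd_kappa > 0
    if np.any(tuned_hd):
        k = truth.hd_kappa[tuned_hd][:, None]
        pref = truth.hd_pref[tuned_hd][:, None]
        mod[tuned_hd] *= np.exp(k * (np.cos(hd[None, :] - pref) - 1.0))
    tuned_sp = truth.speed_exp != 0
    if np.any(tuned_sp):
        g = truth.speed_exp[tuned_sp][:, None]
        mod[tuned_sp] *= np.clip(v[None, :] / 12.0, 0.05, 2.5) ** g
    # normalize to unit session mean so modulation reshapes, not starves,
    # a neuron's event budget
    mod /= mod.mean(axis=1, keepdims=True)
    base = truth.baseline_event_p
    p = base + (p - base) * mod
    return np.clip(p, 0.0, 0.9)


def simulate_events(
    truth: GroundTruth,
    traj: pd.DataFrame,
    session: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a (neurons x frames) deconvolved-amplitude matrix for a session.

    Each frame each neuron emits an event with its tuning-derived probability
    (session-effect labels applied); event amplitudes are positive lognormal
    draws, non-event frames are exactly zero.
    """
    if session not in SESSION_ORDER:
        raise ValueError(f"unknown session label: {session!r}")
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    p = _field_probability(truth, traj, session)
    if truth.cluster_coactivity > 0:
        # shared slow multiplicative gain per temporal cluster (ensemble
        # co-fluctuation beyond pure place-field overlap)
        t = p.shape[1]
        n_clu = int(truth.cluster.max()) + 1
        a = np.exp(-1.0 / (truth.cluster_tau_s * truth.frame_rate))
        noise = rng.normal(0.0, np.sqrt(1.0 - a**2), size=(n_clu, t))
        x = np.empty((n_clu, t))
        x[:, 0] = rng.normal(0.0, 1.0, size=n_clu)
        for j in range(1, t):
            x[:, j] = a * x[:, j - 1] + noise[:, j]
        s = truth.cluster_coactivity
        gain = np.exp(s * x - 0.5 * s**2)
        p = p * gain[truth.cluster]
    p = np.clip(p, 0.0, 0.9)
    events = rng.random(p.shape) < p
    amps = np.zeros(p.shape)
    k = int(events.sum())
    if k:
        amps[events] = np.exp(rng.normal(0.0, 0.25, size=k))
    return amps


def calcium_traces(
    amplitudes: np.ndarray,
    frame_rate: float = 30.0,
    tau: float = 0.6,
    noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Denoised and raw calcium-like traces from deconvolved amplitudes.

    The denoised trace is the amplitude train filtered with an exponential
    indicator-decay kernel; the raw trace adds white noise. Returns
    ``(denoised, raw)``.
    """
    decay = np.exp(-1.0 / (tau * frame_rate))
    den = lfilter([1.0], [1.0, -decay], amplitudes, axis=-1)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        raw = den + rng.normal(0.0, noise_sd, size=den.shape)
    else:
        raw = den.copy()
    return den, raw


# ---------------------------------------------------------------------------
# experiment assembly
# ---------------------------------------------------------------------------


def simulate_experiment(
    arena: ArenaSpec,
    pop_spec: PopulationSpec,
    exp_config: ExperimentConfig | None = None,
) -> SyntheticExperiment:
    """Assemble a full synthetic CPP experiment.

    Baseline sessions are biased toward the naturally preferred compartment;
    test sessions shift the bias toward the drug-paired compartment
    (emulating conditioned place preference). All randomness derives from
    ``exp_config.seed``.
    """
    if exp_config is None:
        exp_config = ExperimentConfig()
    ss = np.random.SeedSequence(exp_config.seed)
    child = ss.spawn(1 + 2 * len(SESSION_ORDER))
    rng_pop = np.random.default_rng(child[0])
    truth = make_population(arena, pop_spec, rng_pop)
    truth = resolve_effect_compartments(truth, exp_config.preferred_compartment)

    sessions: dict[str, Session] = {}
    for i, name in enumerate(SESSION_ORDER):
        if name in TEST_SESSIONS:
            bias, comp = exp_config.test_bias, exp_config.drug_compartment
        else:
            bias, comp = exp_config.baseline_bias, exp_config.preferred_compartment
        cfg = SimConfig(
            duration_s=exp_config.duration_s,
            frame_rate=exp_config.frame_rate,
            occupancy_bias=bias,
            bias_compartment=comp,
        )
        rng_traj = np.random.default_rng(child[1 + 2 * i])
        rng_ev = np.random.default_rng(child[2 + 2 * i])
        traj = simulate_trajectory(arena, cfg, rng=rng_traj)
        amps = simulate_events(truth, traj, name, rng_ev)
        sessions[name] = Session(trajectory=traj, amplitudes=amps)
    return SyntheticExperiment(
        arena=arena, sessions=sessions, truth=truth, config=exp_config
    )


# ---------------------------------------------------------------------------
# fixture IO
# ---------------------------------------------------------------------------

_TRAJ_COLS = ("t", "x", "y", "speed", "heading")


def write_experiment(exp: SyntheticExperiment, path: str) -> None:
    """Write an experiment to an HDF5 container (one group per session)."""
    with h5py.File(path, "w") as f:
        f.attrs["compartment_w"] = exp.arena.compartment_w
        f.attrs["compartment_h"] = exp.arena.compartment_h
        f.attrs["door_width"] = exp.arena.door_width
        f.attrs["preferred_compartment"] = exp.config.preferred_compartment
        f.attrs["drug_compartment"] = exp.config.drug_compartment
        f.attrs["frame_rate"] = exp.config.frame_rate
        for name, sess in exp.sessions.items():
            g = f.create_group(f"sessions/{name}")
            tg = g.create_group("traj")
            for col in _TRAJ_COLS:
                tg.create_dataset(col, data=sess.trajectory[col].to_numpy())
            g.create_dataset("activity", data=sess.amplitudes, compression="gzip")
        tg = f.create_group("truth")
        tr = exp.truth
        tg.create_dataset("centers", data=tr.centers)
        tg.create_dataset("peak_p", data=tr.peak_p)
        tg.create_dataset("sigma", data=tr.sigma)
        tg.create_dataset("effect", data=tr.effect.astype("S"))
        tg.create_dataset("effect_compartment", data=tr.effect_compartment.astype("S"))
        tg.create_dataset("remap_centers", data=tr.remap_centers)
        tg.create_dataset("cluster", data=tr.cluster)
        tg.create_dataset("sector", data=tr.sector.astype("S"))
        tg.create_dataset("centroid", data=tr.centroid)
        tg.create_dataset("hd_pref", data=tr.hd_pref)
        tg.create_dataset("hd_kappa", data=tr.hd_kappa)
        tg.create_dataset("speed_exp", data=tr.speed_exp)
        tg.attrs["baseline_event_p"] = tr.baseline_event_p


def read_experiment(path: str) -> SyntheticExperiment:
    """Read an experiment written by :func:`write_experiment`."""
    with h5py.File(path, "r") as f:
        arena = ArenaSpec(
            compartment_w=float(f.attrs["compartment_w"]),
            compartment_h=float(f.attrs["compartment_h"]),
            door_width=float(f.attrs["door_width"]),
        )
        cfg = ExperimentConfig(
            preferred_compartment=str(f.attrs["preferred_compartment"]),
            drug_compartment=str(f.attrs["drug_compartment"]),
            frame_rate=float(f.attrs["frame_rate"]),
        )
        sessions = {}
        for name in f["sessions"]:
            g = f[f"sessions/{name}"]
            data = {col: g[f"traj/{col}"][()] for col in _TRAJ_COLS}
            traj = pd.DataFrame(data)
            traj["compartment"] = arena.compartment_of(traj["x"].to_numpy())
            sessions[name] = Session(trajectory=traj, amplitudes=g["activity"][()])
        tg = f["truth"]
        truth = GroundTruth(
            centers=tg["centers"][()],
            peak_p=tg["peak_p"][()],
            sigma=tg["sigma"][()],
            effect=tg["effect"][()].astype(str),
            effect_compartment=tg["effect_compartment"][()].astype(str),
            remap_centers=tg["remap_centers"][()],
            cluster=tg["cluster"][()],
            sector=tg["sector"][()].astype(str),
            centroid=tg["centroid"][()],
            hd_pref=tg["hd_pref"][()],
            hd_kappa=tg["hd_kappa"][()],
            speed_exp=tg["speed_exp"][()],
            baseline_event_p=float(tg.attrs["baseline_event_p"]),
        )
    return SyntheticExperiment(arena=arena, sessions=sessions, truth=truth, config=cfg)


def export_trajectory_csv(traj: pd.DataFrame, path: str) -> None:
    traj.to_csv(path, index=False)
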