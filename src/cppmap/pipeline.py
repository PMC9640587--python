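"""End-to-end CPP analysis: preprocessing through LN model selection.

``run_cpp_analysis`` executes the full stack on one experiment (synthetic or
read from the HDF5 fixture format): event binarization, behavioral scoring,
per-session place-cell classification, functional cell typing and CorrDiff,
Bayesian decoding with knock-out controls, baseline temporal clustering with
template sorting, and (optionally) LN model selection. All randomness
derives from the config's master seed; conditioning sessions are not part of
the analyzed set (baseline and the two tests are).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import cell_typing, clustering, decoding, place_cells, preprocessing
from .arena import LEFT, RIGHT
from .synthetic import SESSION_ORDER, SyntheticExperiment, calcium_traces

ANALYZED_SESSIONS = ("baseline", "test1", "test2")


@dataclass
class AnalysisConfig:
    """Parameters of every pipeline stage plus session roles."""

    seed: int = 0
    bin_cm: float = 1.8
    speed_threshold: float = 2.0
    event_k: float = 3.0
    smooth_sd_bins: float = 2.0
    n_match_iters: int = 50
    pci_iterations: int = 20
    pci_shuffles: int = 1000
    decoder_dt: float = 0.8
    decoder_two_step: bool = True
    cluster_k: int = 5
    cluster_iterations: int = 100
    run_ln_model: bool = False
    ln_dt: float = 0.5
    ln_beta: float = 5.0
    baseline_session: str = "baseline"
    test_sessions: tuple[str, ...] = ("test1", "test2")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class Report:
    behavior: pd.DataFrame
    place_cells: pd.DataFrame
    functional_types: pd.DataFrame
    type_fractions: pd.Series
    corr_diff: pd.DataFrame
    decoding: pd.DataFrame
    clusters: pd.DataFrame
    ln_classes: pd.Series | None
    provenance: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "behavior": self.behavior,
            "place_cells": self.place_cells,
            "functional_types": self.functional_types,
            "corr_diff": self.corr_diff,
            "decoding": self.decoding,
            "clusters": self.clusters,
        }
        return out


def run_cpp_analysis(exp: SyntheticExperiment, config: AnalysisConfig | None = None) -> Report:
    cfg = config or AnalysisConfig()
    arena = exp.arena
    fr = exp.config.frame_rate
    ss = np.random.SeedSequence(cfg.seed)
    seeds = iter(int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(32))

    # --- preprocessing -----------------------------------------------------
    ev = {}
    for name in ANALYZED_SESSIONS:
        em = preprocessing.binarize_events(exp.sessions[name].amplitudes, fr, cfg.event_k)
        ev[name] = em.events

    # --- behavior ----------------------------------------------------------
    base_traj = exp.sessions[cfg.baseline_session].trajectory
    preferred = cell_typing.preferred_compartment(base_traj, fr)
    drug = exp.config.drug_compartment
    behavior_rows = []
    for t in cfg.test_sessions:
        behavior_rows.append(
            {
                "test_session": t,
                "preferred": preferred,
                "drug_compartment": drug,
                "cpp_score_s": cell_typing.cpp_score(
                    base_traj, exp.sessions[t].trajectory, drug, fr
                ),
            }
        )
    behavior = pd.DataFrame(behavior_rows)

    # --- place cells -------------------------------------------------------
    pc_cfg = place_cells.PlaceCellConfig(
        bin_cm=cfg.bin_cm,
        speed_threshold=cfg.speed_threshold,
        n_iterations=cfg.pci_iterations,
        n_shuffles=cfg.pci_shuffles,
    )
    decisions = {}
    pc_tables = []
    for name in ANALYZED_SESSIONS:
        d = place_cells.classify_place_cells(
            exp.sessions[name].trajectory, ev[name], arena, fr, pc_cfg, seed=next(seeds)
        )
        d.insert(0, "session", name)
        decisions[name] = d
        pc_tables.append(d)
    pc_table = pd.concat(pc_tables, ignore_index=True)

    flags = cell_typing.place_cell_flags(decisions, preferred)
    types = cell_typing.assign_functional_types(flags)
    fractions = cell_typing.turnover_proportions(types)

    # --- CorrDiff ----------------------------------------------------------
    inter = {}
    for name in ANALYZED_SESSIONS:
        inter[name] = place_cells.inter_compartment_correlations(
            exp.sessions[name].trajectory,
            ev[name],
            arena,
            fr,
            bin_cm=cfg.bin_cm,
            smooth_sd_bins=cfg.smooth_sd_bins,
            n_iterations=cfg.n_match_iters,
            speed_threshold=cfg.speed_threshold,
            seed=next(seeds),
        )
    dis_mask = types["disPCp"].to_numpy()
    cd_rows = []
    for t in cfg.test_sessions:
        cd_rows.append(
            {
                "pair": f"{cfg.baseline_session}-vs-{t}",
                "cell_type": "disPCp",
                "corr_diff": cell_typing.corr_diff(
                    inter[cfg.baseline_session], inter[t], dis_mask
                ),
                "n_cells": int(dis_mask.sum()),
            }
        )
    corr_diff = pd.DataFrame(cd_rows)

    # --- decoding ----------------------------------------------------------
    train = decoding.bin_activity(
        ev[cfg.baseline_session], base_traj, arena, fr, cfg.decoder_dt, cfg.bin_cm,
        cfg.speed_threshold,
    )
    dec = decoding.NaiveBayesPositionDecoder(arena=arena, bin_cm=cfg.bin_cm).fit(
        train.X, train.y
    )
    dec_rows = []
    rng = np.random.default_rng(next(seeds))
    for t in cfg.test_sessions:
        binned = decoding.bin_activity(
            ev[t], exp.sessions[t].trajectory, arena, fr, cfg.decoder_dt, cfg.bin_cm,
            cfg.speed_threshold,
        )
        full = decoding.knockout_decode(dec, binned, None, two_step=cfg.decoder_two_step)
        dis_idx = np.flatnonzero(dis_mask)
        ko_dis = decoding.knockout_decode(dec, binned, dis_idx, two_step=cfg.decoder_two_step)
        rnd_idx = rng.choice(train.X.shape[1], size=len(dis_idx), replace=False)
        ko_rnd = decoding.knockout_decode(dec, binned, rnd_idx, two_step=cfg.decoder_two_step)
        dec_rows.append(
            {
                "test_session": t,
                "error_cm": full.error_cm,
                "error_disPCp_ko_cm": ko_dis.error_cm,
                "error_random_ko_cm": ko_rnd.error_cm,
                "time_drug_full": full.compartment_time[drug],
                "time_drug_disPCp_ko": ko_dis.compartment_time[drug],
                "time_drug_random_ko": ko_rnd.compartment_time[drug],
            }
        )
    dec_table = pd.DataFrame(dec_rows)

    # --- temporal clustering (baseline) -------------------------------------
    den, raw = calcium_traces(
        exp.sessions[cfg.baseline_session].amplitudes, fr, rng=np.random.default_rng(next(seeds))
    )
    filt = clustering.filter_traces(den, raw)
    active = filt.std(axis=1) > 0
    model = clustering.ConsensusKMeans(
        n_clusters=cfg.cluster_k,
        n_iterations=cfg.cluster_iterations,
        random_state=next(seeds),
    ).fit(filt[active])
    labels = np.full(len(filt), -1)
    labels[active] = model.labels_

    ens_maps = {}
    bin_idx = arena.bin_index(
        base_traj["x"].to_numpy(), base_traj["y"].to_numpy(), cfg.bin_cm
    )
    occ = preprocessing.occupancy_map(bin_idx, arena, fr, cfg.bin_cm)
    for cid in range(cfg.cluster_k):
        members = np.flatnonzero(labels == cid)
        total = np.zeros(len(occ.seconds))
        for nidx in members:
            rm = preprocessing.rate_map(ev[cfg.baseline_session][nidx], bin_idx, occ, cfg.smooth_sd_bins)
            total += rm.smoothed
        ens_maps[cid] = total
    sectors = clustering.match_templates(ens_maps, arena, cfg.bin_cm) if cfg.cluster_k == 5 else {}
    clusters = pd.DataFrame(
        {
            "neuron": np.arange(len(labels)),
            "cluster": labels,
            "sector": [sectors.get(int(c), "n/a") for c in labels],
        }
    )

    # --- LN model (optional, slowest stage) ---------------------------------
    ln_summary = None
    if cfg.run_ln_model:
        from . import lnp

        design, counts = lnp.build_design(
            base_traj, ev[cfg.baseline_session], arena, fr, dt=cfg.ln_dt,
            bin_cm=cfg.bin_cm, speed_threshold=cfg.speed_threshold,
        )
        sel = lnp.LNModelSelector(beta=cfg.ln_beta, random_state=next(seeds)).fit(
            design, counts
        )
        ln_summary = sel.summary()

    provenance = {"config_hash": cfg.hash(), "seed": cfg.seed, "config": asdict(cfg)}
    return Report(
        behavior=behavior,
        place_cells=pc_table,
        functional_types=types,
        type_fractions=fractions,
        corr_diff=corr_diff,
        decoding=dec_table,
        clusters=clusters,
        ln_classes=ln_summary,
        provenance=provenance,
    )


def write_report(report: Report, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in report.tables().items():
        table.to_csv(outdir / f"{name}.csv", index=False)
    report.type_fractions.to_csv(outdir / "type_fractions.csv", header=["fraction"])
    if report.ln_classes is not None:
        report.ln_classes.to_csv(outdir / "ln_classes.csv", header=["count"])
    with open(outdir / "provenance.json", "w") as f:
        json.dump(report.provenance, f, indent=2, default=str)


def validate_fixture(path: str | Path) -> list[str]:
    """Schema diagnostics for an HDF5 experiment fixture (empty = valid)."""
    problems: list[str] = []
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        return [f"cannot open file: {e}"]
    with f:
        if "sessions" not in f:
            return ["missing /sessions group"]
        n_neurons = None
        for name in SESSION_ORDER:
            if f"sessions/{name}" not in f:
                problems.append(f"missing session group: {name}")
                continue
            g = f[f"sessions/{name}"]
            if "traj" not in g:
                problems.append(f"session {name}: missing trajectory group")
                continue
            for col in ("t", "x", "y"):
                if col not in g["traj"]:
                    problems.append(f"session {name}: trajectory missing '{col}'")
            if "activity" not in g:
                problems.append(f"session {name}: missing activity matrix")
                continue
            act = g["activity"]
            if "x" in g["traj"] and act.shape[1] != g["traj/x"].shape[0]:
                problems.append(
                    f"session {name}: activity frames != trajectory frames"
                )
            if n_neurons is None:
                n_neurons = act.shape[0]
            elif act.shape[0] != n_neurons:
                problems.append(
                    f"session {name}: neuron count {act.shape[0]} != {n_neurons}"
                )
    return problems
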