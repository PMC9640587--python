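"""Behavioral scores and the functional place-cell taxonomy.

Cell types are pure functions of per-session, per-compartment place-cell
flags relative to the animal's naturally preferred compartment:

- disPCp / disPCnp: place cell in the preferred / non-preferred compartment
  at baseline that loses spatial tuning there in *both* test sessions.
- aPCp / aPCnp: untuned at baseline, place field in the respective
  compartment in *both* test sessions.
- rtPCp: baseline preferred-compartment place cell retaining tuning there in
  at least one test session (mutually exclusive with disPCp by construction).

CorrDiff is the per-animal difference in inter-compartment rate-map
correlation between baseline and a test session, aggregated over a
designated cell type; one value per (baseline, test) pair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arena import LEFT, RIGHT

FUNCTIONAL_TYPES = ("disPCp", "disPCnp", "aPCp", "aPCnp", "rtPCp")


def compartment_times(traj: pd.DataFrame, frame_rate: float) -> dict[str, float]:
    """Seconds spent in each compartment."""
    comp = traj["compartment"].to_numpy()
    return {
        LEFT: float((comp == LEFT).sum() / frame_rate),
        RIGHT: float((comp == RIGHT).sum() / frame_rate),
    }


def preferred_compartment(baseline_traj: pd.DataFrame, frame_rate: float) -> str:
    """Compartment with the majority of baseline time (ties -> left)."""
    t = compartment_times(baseline_traj, frame_rate)
    return LEFT if t[LEFT] >= t[RIGHT] else RIGHT


def cpp_score(
    baseline_traj: pd.DataFrame,
    test_traj: pd.DataFrame,
    drug_compartment: str,
    frame_rate: float,
) -> float:
    """Seconds in the drug-paired compartment: test minus baseline."""
    t_test = compartment_times(test_traj, frame_rate)[drug_compartment]
    t_base = compartment_times(baseline_traj, frame_rate)[drug_compartment]
    return t_test - t_base


def assign_functional_types(flags: pd.DataFrame) -> pd.DataFrame:
    """Functional labels from place-cell flags.

    ``flags`` has one row per neuron with boolean columns
    ``{session}_{side}`` for session in (baseline, test1, test2) and side in
    (pref, nonpref). Returns a DataFrame with one boolean column per type
    plus a ``label`` column (first matching type in the order disPCp,
    disPCnp, aPCp, aPCnp, rtPCp; otherwise 'other').
    """
    req = [f"{s}_{c}" for s in ("baseline", "test1", "test2") for c in ("pref", "nonpref")]
    missing = [c for c in req if c not in flags.columns]
    if missing:
        raise ValueError(f"missing flag columns: {missing}")
    b_p = flags["baseline_pref"].to_numpy(bool)
    b_n = flags["baseline_nonpref"].to_numpy(bool)
    t1_p = flags["test1_pref"].to_numpy(bool)
    t2_p = flags["test2_pref"].to_numpy(bool)
    t1_n = flags["test1_nonpref"].to_numpy(bool)
    t2_n = flags["test2_nonpref"].to_numpy(bool)

    out = pd.DataFrame(index=flags.index)
    out["disPCp"] = b_p & ~t1_p & ~t2_p
    out["disPCnp"] = b_n & ~t1_n & ~t2_n
    out["aPCp"] = ~b_p & t1_p & t2_p
    out["aPCnp"] = ~b_n & t1_n & t2_n
    out["rtPCp"] = b_p & (t1_p | t2_p)

    label = np.full(len(flags), "other", dtype=object)
    for t in reversed(FUNCTIONAL_TYPES):
        label[out[t].to_numpy()] = t
    out["label"] = label
    return out


def place_cell_flags(
    decisions: dict[str, pd.DataFrame], preferred: str
) -> pd.DataFrame:
    """Pivot per-session classify_place_cells tables into pref/nonpref flags.

    ``decisions`` maps session name -> the DataFrame returned by
    :func:`cppmap.place_cells.classify_place_cells`.
    """
    nonpref = RIGHT if preferred == LEFT else LEFT
    cols = {}
    for session, df in decisions.items():
        for side, comp in (("pref", preferred), ("nonpref", nonpref)):
            sub = df[df["compartment"] == comp].set_index("neuron")["is_place_cell"]
            cols[f"{session}_{side}"] = sub
    return pd.DataFrame(cols).fillna(False).astype(bool)


def classify_rate_remapping(correlation: float, threshold: float = 0.4) -> str:
    """'rate' if the baseline inter-compartment correlation exceeds 0.4."""
    if not np.isfinite(correlation):
        return "unclassified"
    return "rate" if correlation > threshold else "non-rate"


def turnover_proportions(types: pd.DataFrame, n_tracked: int | None = None) -> pd.Series:
    """Fraction of tracked neurons per functional type."""
    denom = n_tracked if n_tracked is not None else len(types)
    if denom == 0:
        raise ZeroDivisionError("no tracked neurons")
    return pd.Series({t: types[t].sum() / denom for t in FUNCTIONAL_TYPES})


def corr_diff(
    baseline_corr: np.ndarray,
    test_corr: np.ndarray,
    cell_mask: np.ndarray,
    aggregate: str = "mean",
) -> float:
    """Per-animal CorrDiff: baseline minus test inter-compartment correlation.

    ``baseline_corr`` and ``test_corr`` are per-neuron inter-compartment
    rate-map correlations (occupancy-matched); ``cell_mask`` selects the
    cell type over which to aggregate. NaN correlations are dropped
    pairwise; an empty selection gives NaN.
    """
    d = np.asarray(baseline_corr, float)[cell_mask] - np.asarray(test_corr, float)[cell_mask]
    d = d[np.isfinite(d)]
    if len(d) == 0:
        return float("nan")
    if aggregate == "mean":
        return float(np.mean(d))
    if aggregate == "median":
        return float(np.median(d))
    raise ValueError("aggregate must be 'mean' or 'median'")
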