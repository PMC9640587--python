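"""Consensus k-means clustering of temporally co-active neurons.

Neurons are clustered on the pairwise Pearson correlation of their
(noise-filtered) calcium traces: on each of many iterations, 90% of the
frames are sub-sampled, each neuron is represented by its correlation vector
to all neurons, and k-means (10 replicates) partitions the population; the
consensus matrix accumulates how often every neuron pair lands in the same
cluster. The final partition cuts a complete-linkage tree on
(1 - consensus). The number of clusters is selected by minimizing the
Proportion of Ambiguous Clustering (PAC: the fraction of pairs with
consensus in (0.1, 0.9)); the cophenetic correlation of the consensus
dendrogram is reported alongside.

Cluster identities are made comparable across animals by correlating each
cluster's summed ensemble rate map against two-Gaussian sector templates
(SW/NW/SE/NE, homotopic fields across the compartments) after the center
(junction) cluster is held out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .arena import ArenaSpec

SECTOR_NAMES = ("SW", "NW", "SE", "NE")


def filter_traces(denoised: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Zero sub-threshold samples of the denoised calcium traces.

    The per-neuron noise level is the RMS residual between the raw and the
    denoised trace; samples below 2x that level are set to zero. Idempotent.
    """
    denoised = np.atleast_2d(np.asarray(denoised, float))
    raw = np.atleast_2d(np.asarray(raw, float))
    if raw.shape[1] < denoised.shape[1]:
        raise ValueError("raw trace shorter than denoised trace")
    resid = raw[:, : denoised.shape[1]] - denoised
    noise = resid.std(axis=1)
    out = denoised.copy()
    out[out < 2.0 * noise[:, None]] = 0.0
    return out


def _correlation_features(traces: np.ndarray) -> np.ndarray:
    """Rows of the pairwise Pearson correlation matrix, NaNs (constant
    traces) replaced by zero."""
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(traces)
    return np.nan_to_num(c, nan=0.0)


def _standardized_traces(traces: np.ndarray) -> np.ndarray:
    """Rows centred and scaled to unit norm.

    Euclidean k-means on these vectors is k-means under the Pearson
    correlation distance on the raw traces (squared Euclidean distance of
    standardized rows is proportional to 1 - r).
    """
    m = traces - traces.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(m, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return m / norm


def _project_rows(feats: np.ndarray) -> np.ndarray:
    """Exact low-dimensional Euclidean embedding of the feature rows.

    N points in R^T span at most an N-dimensional subspace; eigendecomposing
    the Gram matrix gives coordinates with identical pairwise distances,
    which makes k-means independent of the trace length.
    """
    n, t = feats.shape
    if t <= n:
        return feats
    g = feats @ feats.T
    vals, vecs = np.linalg.eigh(g)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


class ConsensusKMeans(BaseEstimator, ClusterMixin):
    """Consensus k-means over frame-subsampled correlation features.

    Parameters
    ----------
    n_clusters : int
        Number of clusters K presented to k-means and to the final
        complete-linkage cut.
    n_iterations : int
        Number of subsampling iterations accumulated into the consensus.
    subsample : float
        Fraction of frames drawn (without replacement) per iteration.
    n_replicates : int
        k-means restarts (``n_init``) per iteration.
    feature_space : {'trace', 'corr_vector'}
        'trace' clusters the standardized subsampled traces themselves
        (k-means under the correlation distance); 'corr_vector' represents
        each neuron by its correlation vector to all neurons.
    random_state : int
        Master seed; per-iteration seeds are spawned from it.

    Attributes
    ----------
    consensus_matrix_ : (N, N) co-assignment frequencies, symmetric with
        unit diagonal.
    linkage_ : complete-linkage tree on (1 - consensus).
    labels_ : final cluster ids, contiguous 0..K-1.
    """

    def __init__(
        self,
        n_clusters: int = 5,
        n_iterations: int = 100,
        subsample: float = 0.9,
        n_replicates: int = 10,
        feature_space: str = "trace",
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.n_iterations = n_iterations
        self.subsample = subsample
        self.n_replicates = n_replicates
        self.feature_space = feature_space
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "ConsensusKMeans":
        traces = np.atleast_2d(np.asarray(X, float))
        n, t = traces.shape
        if n < self.n_clusters:
            raise ValueError("need at least n_clusters neurons")
        if np.any(traces.std(axis=1) == 0):
            raise ValueError(
                "constant trace(s) have undefined correlations; exclude them first"
            )
        ss = np.random.SeedSequence(self.random_state)
        co = np.zeros((n, n))
        n_sub = max(int(round(self.subsample * t)), 2)
        for child in ss.spawn(self.n_iterations):
            rng = np.random.default_rng(child)
            frames = np.sort(rng.choice(t, size=n_sub, replace=False))
            sub = traces[:, frames]
            if self.feature_space == "trace":
                feats = _project_rows(_standardized_traces(sub))
            elif self.feature_space == "corr_vector":
                feats = _correlation_features(sub)
            else:
                raise ValueError(f"unknown feature_space: {self.feature_space!r}")
            km = KMeans(
                n_clusters=self.n_clusters,
                n_init=self.n_replicates,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(feats)
            lab = km.labels_
            co += lab[:, None] == lab[None, :]
        co /= self.n_iterations
        np.fill_diagonal(co, 1.0)
        self.consensus_matrix_ = (co + co.T) / 2.0
        self.linkage_, self.labels_ = cut_consensus(
            self.consensus_matrix_, self.n_clusters
        )
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_


def cut_consensus(consensus: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Complete-linkage tree on (1 - consensus) cut at ``k`` clusters.

    Returns (linkage matrix, contiguous labels renumbered in order of first
    appearance).
    """
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="complete")
    raw = cut_tree(z, n_clusters=k).ravel()
    # renumber by first appearance for deterministic contiguous ids
    seen: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        labels[i] = seen.setdefault(int(r), len(seen))
    return z, labels


def pac(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: off-diagonal pairs with
    consensus strictly inside (lower, upper)."""
    iu = np.triu_indices(len(consensus), k=1)
    v = consensus[iu]
    return float(np.mean((v > lower) & (v < upper)))


def cophenetic_correlation(consensus: np.ndarray, z: np.ndarray | None = None) -> float:
    """Correlation between (1 - consensus) distances and the dendrogram's
    cophenetic distances."""
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    dv = squareform(d, checks=False)
    if z is None:
        z = linkage(dv, method="complete")
    c, _ = cophenet(z, dv)
    return float(c)


@dataclass
class KSelectionCurves:
    k_values: np.ndarray
    pac: np.ndarray
    cophenetic: np.ndarray
    chosen_k: int
    cophenetic_k: int


def _local_extremum(values: np.ndarray, minimum: bool, interior: slice) -> int:
    """Index of the first strict local extremum inside ``interior``; global
    extremum as fallback."""
    v = values if minimum else -values
    for i in range(interior.start, interior.stop):
        if v[i] < v[i - 1] and v[i] < v[i + 1]:
            return i
    return int(np.argmin(v))


def select_optimal_k(
    traces: np.ndarray,
    k_values: range = range(2, 11),
    n_iterations: int = 100,
    subsample: float = 0.9,
    n_replicates: int = 10,
    random_state: int = 0,
) -> KSelectionCurves:
    """PAC and cophenetic-correlation curves over K with the chosen K.

    Curves span K = 2..10; the search for the chosen K considers the interior
    of the curve (3..9). The PAC local minimum governs; the cophenetic local
    maximum is reported alongside.
    """
    ks = np.array(list(k_values))
    pacs = np.empty(len(ks))
    cophs = np.empty(len(ks))
    for i, k in enumerate(ks):
        model = ConsensusKMeans(
            n_clusters=int(k),
            n_iterations=n_iterations,
            subsample=subsample,
            n_replicates=n_replicates,
            random_state=random_state,
        ).fit(traces)
        pacs[i] = pac(model.consensus_matrix_)
        cophs[i] = cophenetic_correlation(model.consensus_matrix_, model.linkage_)
    interior = slice(1, len(ks) - 1)
    # lowest PAC within the interior search range governs the choice
    chosen = ks[interior][np.argmin(pacs[interior])]
    coph_k = ks[_local_extremum(cophs, minimum=False, interior=interior)]
    return KSelectionCurves(
        k_values=ks, pac=pacs, cophenetic=cophs, chosen_k=int(chosen), cophenetic_k=int(coph_k)
    )


# ---------------------------------------------------------------------------
# spatial template matching
# ---------------------------------------------------------------------------


def sector_templates(
    arena: ArenaSpec, bin_cm: float = 1.8
) -> dict[str, np.ndarray]:
    """Two-Gaussian sector templates on the arena bin grid.

    Each template places homotopic Gaussian fields in both compartments at
    the sector's within-compartment position; the field nearer the CPP
    midline has variance 12.5 cm^2, the field away from the midline
    25 cm^2.
    """
    centers = arena.bin_centers(bin_cm)
    w, h = arena.compartment_w, arena.compartment_h
    pos = {
        "SW": (0.25 * w, 0.25 * h),
        "NW": (0.25 * w, 0.75 * h),
        "SE": (0.75 * w, 0.25 * h),
        "NE": (0.75 * w, 0.75 * h),
    }
    out = {}
    for name, (lx, ly) in pos.items():
        tot = np.zeros(len(centers))
        for comp in range(2):
            cx = lx + comp * w
            # distance of the field to the midline decides its variance
            var = 12.5 if abs(cx - arena.midline_x) < w / 2.0 else 25.0
            d2 = (centers[:, 0] - cx) ** 2 + (centers[:, 1] - ly) ** 2
            tot += np.exp(-d2 / (2.0 * var))
        out[name] = tot
    return out


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)


def match_templates(
    ensemble_maps: dict[int, np.ndarray],
    arena: ArenaSpec,
    bin_cm: float = 1.8,
) -> dict[int, str]:
    """Assign sector labels to cluster ensemble rate maps.

    The center cluster (ensemble peak closest to the midline) is identified
    and held out first; the remaining four clusters are assigned to
    SW/NW/SE/NE templates by the permutation maximizing the summed Pearson
    correlation, which resolves ambiguous one-to-one assignments.
    """
    from itertools import permutations

    ids = sorted(ensemble_maps)
    if len(ids) != 5:
        raise ValueError("template matching expects exactly 5 clusters")
    centers = arena.bin_centers(bin_cm)
    peak_dx = {}
    for cid in ids:
        m = ensemble_maps[cid]
        peak_dx[cid] = abs(centers[int(np.argmax(m)), 0] - arena.midline_x)
    center_id = min(ids, key=lambda c: peak_dx[c])
    rest = [c for c in ids if c != center_id]

    templates = sector_templates(arena, bin_cm)
    corr = np.zeros((4, 4))
    for i, cid in enumerate(rest):
        m = _minmax(ensemble_maps[cid])
        for j, name in enumerate(SECTOR_NAMES):
            t = _minmax(templates[name])
            if m.std() == 0 or t.std() == 0:
                corr[i, j] = -np.inf
            else:
                corr[i, j] = np.corrcoef(m, t)[0, 1]
    best, best_sum = None, -np.inf
    for perm in permutations(range(4)):
        s = sum(corr[i, perm[i]] for i in range(4))
        if s > best_sum:
            best, best_sum = perm, s
    labels = {center_id: "center"}
    for i, cid in enumerate(rest):
        labels[cid] = SECTOR_NAMES[best[i]]
    return labels


def cluster_anatomy(
    centroids: np.ndarray,
    assignment: np.ndarray,
    subset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cell mean anatomical distance to same- vs other-cluster members.

    Distances are Euclidean between ROI centroids, restricted to ``subset``
    (e.g. the disPCp of one animal). Single-member clusters have an
    undefined intra distance (NaN).
    """
    centroids = np.asarray(centroids, float)
    assignment = np.asarray(assignment)
    if subset is None:
        subset = np.ones(len(centroids), bool)
    idx = np.flatnonzero(subset)
    pts = centroids[idx]
    lab = assignment[idx]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    rows = []
    for i in range(len(idx)):
        same = (lab == lab[i]) & (np.arange(len(idx)) != i)
        other = lab != lab[i]
        rows.append(
            {
                "neuron": int(idx[i]),
                "cluster": lab[i],
                "intra": float(d[i, same].mean()) if same.any() else float("nan"),
                "inter": float(d[i, other].mean()) if other.any() else float("nan"),
            }
        )
    return pd.DataFrame(rows)
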