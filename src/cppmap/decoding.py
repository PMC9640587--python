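"""Multinomial naive Bayes position decoding with a continuity constraint.

Event trains are summed into non-overlapping 0.8 s time bins; each bin is
labelled with the spatial bin of the animal's mean position. The decoder
models P(X | Y = y) per neuron as a multinomial "bag of tokens" with Laplace
smoothing,

    theta(X_i | y) = (count of neuron i's events at y + 1)
                     / (total events of all neurons at y + N),

combines it with an empirical location prior, and predicts the argmax of the
log posterior. The two-step variant multiplies the posterior by a 2D
Gaussian continuity prior centred on the previous decoded position with
sigma_t = a * v_t (a = 2.5, floored at one bin width) before the argmax.

Knock-out (KO) decoding zeroes a chosen neuron subset's activity at
prediction time only; reconstructed CPP time is the fraction of decoded bins
falling in each compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .arena import DEFAULT_BIN_CM, LEFT, ArenaSpec

DEFAULT_DT = 0.8


@dataclass
class BinnedActivity:
    """Time-binned event counts with spatial-bin labels.

    ``X`` is (time bins x neurons) integer counts; ``y`` the flat spatial-bin
    label of each time bin; ``coords`` the true mean (x, y) position and
    ``speed`` the mean running speed per time bin.
    """

    X: np.ndarray
    y: np.ndarray
    coords: np.ndarray
    speed: np.ndarray
    dt: float
    bin_cm: float


def bin_activity(
    events: np.ndarray,
    traj: pd.DataFrame,
    arena: ArenaSpec,
    frame_rate: float = 30.0,
    dt: float = DEFAULT_DT,
    bin_cm: float = DEFAULT_BIN_CM,
    speed_threshold: float = 2.0,
) -> BinnedActivity:
    """Sum speed-filtered events into non-overlapping ``dt`` time bins.

    Frames below the speed threshold are removed before binning; the
    remaining frames are grouped in order into windows of
    ``round(dt * frame_rate)`` frames (a trailing remainder is dropped). The
    label of a window is the spatial bin of its mean position.
    """
    events = np.atleast_2d(np.asarray(events))
    keep = traj["speed"].to_numpy() >= speed_threshold
    ev = events[:, keep]
    x = traj["x"].to_numpy()[keep]
    y = traj["y"].to_numpy()[keep]
    v = traj["speed"].to_numpy()[keep]

    frames_per_bin = int(round(dt * frame_rate))
    m = ev.shape[1] // frames_per_bin
    if m == 0:
        raise ValueError("not enough frames for a single time bin")
    t_used = m * frames_per_bin

    X = (
        ev[:, :t_used]
        .reshape(events.shape[0], m, frames_per_bin)
        .sum(axis=2)
        .T.astype(int)
    )
    mx = x[:t_used].reshape(m, frames_per_bin).mean(axis=1)
    my = y[:t_used].reshape(m, frames_per_bin).mean(axis=1)
    mv = v[:t_used].reshape(m, frames_per_bin).mean(axis=1)
    labels = arena.bin_index(mx, my, bin_cm)
    return BinnedActivity(
        X=X, y=labels, coords=np.column_stack([mx, my]), speed=mv, dt=dt, bin_cm=bin_cm
    )


class NaiveBayesPositionDecoder(BaseEstimator):
    """Multinomial naive Bayes decoder over spatial-bin labels.

    Parameters
    ----------
    arena : ArenaSpec
        Geometry used to map labels back to 2D coordinates.
    bin_cm : float
        Spatial bin pitch of the label vocabulary.
    prior_weighting : bool
        Rescale each location's event counts so they sum to the empirical
        prior of that location (times the grand total) before Laplace
        smoothing. Off by default; the plain Laplace-smoothed counts already
        match the estimator's stated form.
    continuity_a : float
        Speed scale of the two-step continuity prior (sigma_t = a * v_t).
    sigma_floor_cm : float or None
        Lower bound on sigma_t; defaults to one spatial bin width.

    Attributes
    ----------
    classes_ : visited location labels (flat bin indices).
    log_prior_ : empirical log prior per class.
    log_theta_ : (n_classes, n_neurons) log multinomial parameters.
    class_coords_ : (n_classes, 2) bin-centre coordinates.
    """

    def __init__(
        self,
        arena: ArenaSpec | None = None,
        bin_cm: float = DEFAULT_BIN_CM,
        prior_weighting: bool = False,
        continuity_a: float = 2.5,
        sigma_floor_cm: float | None = None,
    ):
        self.arena = arena
        self.bin_cm = bin_cm
        self.prior_weighting = prior_weighting
        self.continuity_a = continuity_a
        self.sigma_floor_cm = sigma_floor_cm

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NaiveBayesPositionDecoder":
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (time bins x neurons) aligned with y")
        self.classes_, inv = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        n_neurons = X.shape[1]

        counts = np.zeros((n_classes, n_neurons))
        np.add.at(counts, inv, X)
        prior = np.bincount(inv, minlength=n_classes).astype(float)
        prior /= prior.sum()

        if self.prior_weighting:
            row = counts.sum(axis=1)
            total = counts.sum()
            scale = np.where(row > 0, prior * total / np.where(row > 0, row, 1.0), 0.0)
            counts = counts * scale[:, None]

        theta = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + n_neurons)
        self.log_theta_ = np.log(theta)
        self.log_prior_ = np.log(prior)
        arena = self.arena if self.arena is not None else ArenaSpec()
        self.class_coords_ = arena.bin_centers(self.bin_cm)[self.classes_]
        self.n_features_in_ = n_neurons
        return self

    def _log_posterior(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X))
        return X @ self.log_theta_.T + self.log_prior_

    def predict(self, X: np.ndarray) -> np.ndarray:
        """One-step maximum-posterior labels (ties -> smallest label)."""
        return self.classes_[np.argmax(self._log_posterior(X), axis=1)]

    def predict_coords(self, X: np.ndarray) -> np.ndarray:
        return self.class_coords_[np.argmax(self._log_posterior(X), axis=1)]

    def predict_2step(
        self, X: np.ndarray, speed: np.ndarray | None = None
    ) -> np.ndarray:
        """Two-step decoded labels under the Gaussian continuity prior.

        The first bin (and any bin with missing speed) falls back to the
        one-step rule; sigma_t = continuity_a * v_t floored at one bin width
        so a momentarily stationary animal never freezes the trajectory.
        """
        logpost = self._log_posterior(X)
        coords = self.class_coords_
        floor = self.sigma_floor_cm if self.sigma_floor_cm is not None else self.bin_cm
        out = np.empty(len(logpost), dtype=int)
        prev_xy = None
        for t in range(len(logpost)):
            if prev_xy is None or speed is None or not np.isfinite(speed[t]):
                k = int(np.argmax(logpost[t]))
            else:
                sigma = max(self.continuity_a * float(speed[t]), floor)
                d2 = ((coords - prev_xy) ** 2).sum(axis=1)
                k = int(np.argmax(logpost[t] - d2 / (2.0 * sigma**2)))
            out[t] = k
            prev_xy = coords[k]
        return self.classes_[out]

    def coords_of(self, labels: np.ndarray) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.classes_)}
        idx = np.array([lookup[l] for l in np.asarray(labels)])
        return self.class_coords_[idx]


def decoding_error(pred_coords: np.ndarray, true_coords: np.ndarray) -> float:
    """Mean Euclidean distance (cm) between decoded and true positions."""
    pred_coords = np.atleast_2d(pred_coords)
    true_coords = np.atleast_2d(true_coords)
    return float(np.mean(np.linalg.norm(pred_coords - true_coords, axis=1)))


def shuffle_control(
    decoder: NaiveBayesPositionDecoder,
    binned: BinnedActivity,
    n_shuffles: int = 100,
    two_step: bool = False,
    per_neuron: bool = False,
    shift_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
) -> np.ndarray:
    """Chance-level decoding errors from circularly shifted test activity.

    Each shuffle shifts the binned event counts in time by a uniform draw
    from [5%, 95%] of the data length (jointly across neurons by default)
    and re-decodes; returns the error of every shuffle.
    """
    rng = np.random.default_rng(seed)
    m = len(binned.X)
    lo = max(int(shift_range[0] * m), 1)
    hi = max(int(shift_range[1] * m), lo + 1)
    errors = np.empty(n_shuffles)
    for s in range(n_shuffles):
        if per_neuron:
            Xs = np.empty_like(binned.X)
            for i in range(binned.X.shape[1]):
                Xs[:, i] = np.roll(binned.X[:, i], int(rng.integers(lo, hi)))
        else:
            Xs = np.roll(binned.X, int(rng.integers(lo, hi)), axis=0)
        if two_step:
            pred = decoder.coords_of(decoder.predict_2step(Xs, binned.speed))
        else:
            pred = decoder.predict_coords(Xs)
        errors[s] = decoding_error(pred, binned.coords)
    return errors


@dataclass
class DecodeResult:
    pred_labels: np.ndarray
    pred_coords: np.ndarray
    error_cm: float
    compartment_time: dict[str, float] = field(default_factory=dict)
    ko_set: np.ndarray | None = None


def reconstructed_compartment_time(
    pred_coords: np.ndarray, arena: ArenaSpec
) -> dict[str, float]:
    """Fraction of decoded time bins per compartment (sums to 1)."""
    comp = arena.compartment_of(pred_coords[:, 0])
    n = len(comp)
    return {c: float((comp == c).sum() / n) for c in ("left", "right")}


def knockout_decode(
    decoder: NaiveBayesPositionDecoder,
    binned: BinnedActivity,
    ko_set: np.ndarray | None = None,
    two_step: bool = False,
) -> DecodeResult:
    """Decode with a neuron subset's activity zeroed at prediction time.

    The decoder itself is left untouched (training never sees the KO). An
    empty/None KO set reproduces the plain decode.
    """
    arena = decoder.arena if decoder.arena is not None else ArenaSpec()
    X = binned.X.copy()
    if ko_set is not None and len(ko_set) > 0:
        ko_set = np.asarray(ko_set, int)
        if len(np.unique(ko_set)) >= X.shape[1]:
            import warnings

            warnings.warn("knocking out every neuron leaves no signal")
        X[:, ko_set] = 0
    if two_step:
        labels = decoder.predict_2step(X, binned.speed)
        coords = decoder.coords_of(labels)
    else:
        labels = decoder.predict(X)
        coords = decoder.coords_of(labels)
    return DecodeResult(
        pred_labels=labels,
        pred_coords=coords,
        error_cm=decoding_error(coords, binned.coords),
        compartment_time=reconstructed_compartment_time(coords, arena),
        ko_set=ko_set,
    )


def downsample_neurons(
    train: BinnedActivity,
    test: BinnedActivity,
    n: int = 150,
    n_iterations: int = 50,
    two_step: bool = False,
    seed: int = 0,
    **decoder_kwargs,
) -> float:
    """Mean decoding error over random ``n``-neuron subsets.

    With ``n`` equal to the population size a single iteration is run (the
    subset is the full population).
    """
    total = train.X.shape[1]
    if n > total:
        raise ValueError("cannot down-sample to more neurons than recorded")
    rng = np.random.default_rng(seed)
    iters = 1 if n == total else n_iterations
    errors = []
    for _ in range(iters):
        sel = np.sort(rng.choice(total, size=n, replace=False))
        dec = NaiveBayesPositionDecoder(**decoder_kwargs).fit(train.X[:, sel], train.y)
        if two_step:
            pred = dec.coords_of(dec.predict_2step(test.X[:, sel], test.speed))
        else:
            pred = dec.predict_coords(test.X[:, sel])
        errors.append(decoding_error(pred, test.coords))
    return float(np.mean(errors))
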