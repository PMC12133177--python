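"""Circular position decoding from epoched data.

A linear, L2-regularised decoder predicts the sine and cosine of the
stimulus angle from channel features; the decoded angle is
``atan2(sin_hat, cos_hat)``. Performance is summarised by the fractional
inverse absolute angular error ("decoding score"):

    score = (2 / pi) * (pi/2 - mean |circular error in radians|)

which is 1 for perfect prediction, 0 at chance (mean error 90 deg) and -1
when every prediction is maximally wrong (180 deg).

Cross-validated timecourses, temporal generalization, channel-searchlight,
frequency-specific and sequential-stimulus decoding are built on the same
fold structure (stratified by position, seeded) with per-training-timepoint
PCA denoising fitted on the training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from .epochs import EpochSet
from .geometry import angular_error
from .preprocess import TFREpochs, fit_pca_basis

__all__ = [
    "decoding_score",
    "CircularDecoder",
    "stratified_folds",
    "crossval_timecourse",
    "temporal_generalization",
    "GeneralizationMatrix",
    "searchlight",
    "frequency_decoding",
    "sequential_generalization",
    "SequentialGeneralization",
]


def decoding_score(predicted_deg, actual_deg) -> float:
    """Fractional inverse absolute angular error.

    1 = perfect, 0 = chance (mean absolute error 90 deg), -1 = maximal
    error. Invariant to a common rotation of both inputs.
    """
    predicted = np.asarray(predicted_deg, dtype=float)
    actual = np.asarray(actual_deg, dtype=float)
    if predicted.size == 0 or predicted.shape != actual.shape:
        raise ValueError("predicted and actual must be equal-length, non-empty")
    err = np.deg2rad(angular_error(predicted, actual))
    return float(2.0 * (np.pi / 2.0 - err.mean()) / np.pi)


class CircularDecoder:
    """L2-regularised linear maps onto (sin, cos) of the stimulus angle.

    Any L2-penalised linear regressor satisfies the model contract; ridge
    regression is used with a fixed default ``alpha = 1.0``. Predicted sine
    and cosine are passed to ``atan2`` without renormalisation.
    """

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._model: Ridge | None = None

    def fit(self, X: np.ndarray, angles_deg) -> "CircularDecoder":
        rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
        y = np.column_stack([np.sin(rad), np.cos(rad)])
        self._model = Ridge(alpha=self.alpha).fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted angles in degrees [0, 360)."""
        if self._model is None:
            raise RuntimeError("decoder is not fitted")
        sc = self._model.predict(X)
        return np.rad2deg(np.arctan2(sc[:, 0], sc[:, 1])) % 360.0


def stratified_folds(positions: np.ndarray, k_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded position-stratified fold assignment.

    Every fold must contain every position at least once; otherwise a
    ``ValueError`` is raised.
    """
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions)
    folds: list[list[int]] = [[] for _ in range(k_folds)]
    for pos in np.unique(positions):
        idx = np.flatnonzero(positions == pos)
        if idx.size < k_folds:
            raise ValueError(
                f"position {pos} has {idx.size} trials; needs >= {k_folds} "
                "for every fold to contain it")
        rng.shuffle(idx)
        for i, trial in enumerate(idx):
            folds[i % k_folds].append(trial)
    return [np.sort(np.array(f)) for f in folds]


def _cv_predictions(data: np.ndarray, angles: np.ndarray, folds,
                    train_times: np.ndarray, test_times: np.ndarray | None,
                    pca_var: float, alpha: float) -> np.ndarray:
    """Out-of-fold predicted angles.

    Returns ``(n_trials, n_train)`` when ``test_times is None`` (matched
    train/test time) else ``(n_trials, n_train, n_test)``.
    """
    n_trials = data.shape[0]
    diagonal = test_times is None
    if diagonal:
        pred = np.full((n_trials, len(train_times)), np.nan)
    else:
        pred = np.full((n_trials, len(train_times), len(test_times)), np.nan)
    for fold in folds:
        train_idx = np.setdiff1d(np.arange(n_trials), fold)
        for ti, t in enumerate(train_times):
            Xtr = data[train_idx, :, t]
            pca = fit_pca_basis(Xtr, pca_var) if pca_var is not None else None
            dec = CircularDecoder(alpha=alpha).fit(
                Xtr if pca is None else pca.transform(Xtr), angles[train_idx])
            if diagonal:
                Xte = data[fold, :, t]
                pred[fold, ti] = dec.predict(
                    Xte if pca is None else pca.transform(Xte))
            else:
                for si, tt in enumerate(test_times):
                    Xte = data[fold, :, tt]
                    pred[fold, ti, si] = dec.predict(
                        Xte if pca is None else pca.transform(Xte))
    return pred


def crossval_timecourse(epochs: EpochSet, k_folds: int = 5, seed: int = 0,
                        pca_var: float | None = 0.99, alpha: float = 1.0,
                        decim: int = 1):
    """Cross-validated decoding score per timepoint.

    Returns ``(times, scores)``; predictions are pooled over folds before
    scoring. PCA (``pca_var`` cumulative variance, fitted per training
    timepoint on the training folds) denoises the features; set
    ``pca_var=None`` to decode raw channels.
    """
    folds = stratified_folds(epochs.positions, k_folds, seed)
    t_idx = np.arange(0, epochs.n_samples, decim)
    pred = _cv_predictions(epochs.data, epochs.angles, folds, t_idx, None,
                           pca_var, alpha)
    scores = np.array([decoding_score(pred[:, i], epochs.angles)
                       for i in range(len(t_idx))])
    return epochs.times[t_idx], scores


@dataclass
class GeneralizationMatrix:
    """Train-time x test-time decoding scores."""

    scores: np.ndarray
    train_times: np.ndarray
    test_times: np.ndarray

    def diagonal(self) -> np.ndarray:
        if not np.array_equal(self.train_times, self.test_times):
            raise ValueError("diagonal undefined for mismatched axes")
        return np.diagonal(self.scores).copy()


def temporal_generalization(epochs: EpochSet, k_folds: int = 5, seed: int = 0,
                            pca_var: float | None = 0.99, alpha: float = 1.0,
                            decim: int = 1) -> GeneralizationMatrix:
    """Full train-time x test-time score matrix under matched CV folds.

    With the same ``seed``/``k_folds``/``decim``, the diagonal equals the
    output of :func:`crossval_timecourse` exactly.
    """
    folds = stratified_folds(epochs.positions, k_folds, seed)
    t_idx = np.arange(0, epochs.n_samples, decim)
    pred = _cv_predictions(epochs.data, epochs.angles, folds, t_idx, t_idx,
                           pca_var, alpha)
    n = len(t_idx)
    scores = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            scores[i, j] = decoding_score(pred[:, i, j], epochs.angles)
    times = epochs.times[t_idx]
    return GeneralizationMatrix(scores=scores, train_times=times,
                                test_times=times)


def searchlight(epochs: EpochSet, window_ms: tuple[float, float] = (75.0, 250.0),
                k_folds: int = 5, seed: int = 0, pca_var: float | None = None,
                alpha: float = 1.0, decim: int = 1,
                summary: str = "mean") -> np.ndarray:
    """Per-channel decoding using each channel plus its immediate neighbours.

    Scores are the ``summary`` ("mean" or "peak") of the CV timecourse over
    ``window_ms``. Note there is no monotonicity guarantee relating
    neighbourhood scores to the all-channel score.
    """
    if summary not in ("mean", "peak"):
        raise ValueError("summary must be 'mean' or 'peak'")
    cropped = epochs.crop(*window_ms)
    out = np.empty(epochs.n_channels)
    for ci in range(epochs.n_channels):
        picks = [ci, *epochs.channels.adjacency[ci]]
        sub = cropped.pick_channels(picks)
        _, scores = crossval_timecourse(sub, k_folds=k_folds, seed=seed,
                                        pca_var=pca_var, alpha=alpha,
                                        decim=decim)
        out[ci] = scores.mean() if summary == "mean" else scores.max()
    return out


def frequency_decoding(tfr: TFREpochs, k_folds: int = 5, seed: int = 0,
                       alpha: float = 1.0, decim: int = 1) -> tuple:
    """Decoding score per frequency x timepoint from normalised power.

    Power patterns are z-scored across channels (per trial, frequency and
    timepoint) before decoding, so only the relative spatial pattern of
    power carries information; a global gain applied to all channels
    leaves the scores unchanged.
    """
    folds = stratified_folds(tfr.positions, k_folds, seed)
    t_idx = np.arange(0, tfr.data.shape[-1], decim)
    n_freqs = len(tfr.freqs)
    scores = np.empty((n_freqs, len(t_idx)))
    for fi in range(n_freqs):
        power = tfr.data[:, :, fi, :]
        mu = power.mean(axis=1, keepdims=True)
        sd = power.std(axis=1, keepdims=True) + 1e-30
        norm = (power - mu) / sd
        pred = _cv_predictions(norm, tfr.angles, folds, t_idx, None,
                               None, alpha)
        scores[fi] = [decoding_score(pred[:, i], tfr.angles)
                      for i in range(len(t_idx))]
    return tfr.freqs, tfr.times[t_idx], scores


@dataclass
class SequentialGeneralization:
    """Generalization scores against the locked and following stimuli.

    ``scores[k]`` is the train-time x test-time score matrix computed
    against stimulus ``k`` of the 5 Hz stream (k = 0 is the locked one;
    stimulus k onsets ``k / localizer_rate`` after it).
    """

    scores: np.ndarray            # (n_targets, n_train, n_test)
    train_times: np.ndarray
    test_times: np.ndarray
    soa_ms: float


def sequential_generalization(epochs: EpochSet, soa_ms: float = 200.0,
                              n_targets: int = 5,
                              train_window_ms: tuple = (0.0, 500.0),
                              seed: int = 0, pca_var: float | None = 0.99,
                              alpha: float = 1.0,
                              decim: int = 1) -> SequentialGeneralization:
    """Decode the locked stimulus and its successors across time.

    Trials are split in half; decoders are trained per timepoint inside
    ``train_window_ms`` on one half and tested over the full epoch of the
    other half against the angle of each target stimulus (the locked one
    and the ``n_targets - 1`` following, whose positions must be present as
    ``pos_next{k}`` event columns). Halves are then swapped and the score
    matrices averaged.
    """
    geometry_spacing = 360.0 / (epochs.events["position"].max() + 1)
    targets = [epochs.angles]
    for k in range(1, n_targets):
        col = f"pos_next{k}"
        if col not in epochs.events.columns:
            raise ValueError(f"events lack column {col} needed for target {k}")
        targets.append(epochs.events[col].to_numpy(dtype=float) * geometry_spacing)

    rng = np.random.default_rng(seed)
    order = rng.permutation(epochs.n_trials)
    halves = [np.sort(order[: epochs.n_trials // 2]),
              np.sort(order[epochs.n_trials // 2:])]

    tr_mask = (epochs.times >= train_window_ms[0]) & (epochs.times <= train_window_ms[1])
    train_idx = np.flatnonzero(tr_mask)[::decim]
    test_idx = np.arange(0, epochs.n_samples, decim)

    n_train, n_test = len(train_idx), len(test_idx)
    scores = np.zeros((n_targets, n_train, n_test))
    for train_half, test_half in ((0, 1), (1, 0)):
        tr, te = halves[train_half], halves[test_half]
        for ti, t in enumerate(train_idx):
            Xtr = epochs.data[tr, :, t]
            pca = fit_pca_basis(Xtr, pca_var) if pca_var is not None else None
            dec = CircularDecoder(alpha=alpha).fit(
                Xtr if pca is None else pca.transform(Xtr), epochs.angles[tr])
            for si, tt in enumerate(test_idx):
                Xte = epochs.data[te, :, tt]
                pred = dec.predict(Xte if pca is None else pca.transform(Xte))
                for k in range(n_targets):
                    scores[k, ti, si] += 0.5 * decoding_score(pred, targets[k][te])
    return SequentialGeneralization(scores=scores,
                                    train_times=epochs.times[train_idx],
                                    test_times=epochs.times[test_idx],
                                    soa_ms=soa_ms)
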