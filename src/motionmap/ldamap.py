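"""Probabilistic spatio-temporal position maps from time-point-specific LDA.

A bank of multiclass LDA classifiers (one per training timepoint, fitted on
localizer epochs with each position as a class) emits 40-way posterior
probabilities for motion epochs. Averaging over a 75-125 ms training window
yields a probabilistic spatio-temporal map of the moving stimulus; keeping
the training-time axis yields the training-time x relative-position map on
which the progressive latency-shift analysis operates.

Point estimators over a position distribution:

* ``centroid`` — argument of the weighted complex mean
  ``sum_j w_j exp(i a_j)`` after normalising the weights; its modulus (the
  resultant length) is the certainty.
* ``peak`` — position of maximum weight (ties: smallest index, flagged).
* ``fwhm`` — full width at half maximum of the above-chance region around
  the peak, linearly interpolated between bins with circular wrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .epochs import EpochSet
from .geometry import StimulusGeometry, angular_difference, wrap_angle

__all__ = [
    "POSTERIOR_17",
    "PositionDistribution",
    "PointEstimate",
    "centroid",
    "peak",
    "fwhm",
    "LDABank",
    "fit_lda_bank",
    "PositionPosteriorMap",
    "posterior_map",
    "recenter_posteriors",
    "TrainTimeShiftMap",
    "traintime_shift_map",
    "recover_shift_ms",
    "LatencyShiftModel",
    "LatencyShiftResult",
    "slope_interaction_test",
]

#: Occipito-parietal channels used for mapping on a standard 64-channel montage.
POSTERIOR_17 = ("P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
                "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2")


# ---------------------------------------------------------------------------
# Position distributions and point estimators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionDistribution:
    """Non-negative weights over position angles at one time."""

    weights: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        a = np.asarray(self.angles_deg, dtype=float)
        if w.shape != a.shape or w.ndim != 1:
            raise ValueError("weights and angles must be matching 1-D arrays")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "angles_deg", a)


@dataclass(frozen=True)
class PointEstimate:
    """A point read-out of a position distribution.

    ``degenerate`` flags undefined estimates (flat distribution / zero
    resultant); ``angle_deg`` is NaN in that case.
    """

    angle_deg: float
    certainty: float
    degenerate: bool = False


def centroid(dist: PositionDistribution) -> PointEstimate:
    """Weighted circular vector average; certainty = resultant length."""
    w = dist.weights
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero weights: centroid undefined")
    z = np.sum((w / total) * np.exp(1j * np.deg2rad(dist.angles_deg)))
    r = float(np.abs(z))
    if r < 1e-12:
        return PointEstimate(np.nan, 0.0, degenerate=True)
    return PointEstimate(float(np.rad2deg(np.angle(z)) % 360.0), r)


def peak(dist: PositionDistribution) -> PointEstimate:
    """Angle of maximum weight; ties broken by the smallest index (flagged)."""
    w = dist.weights
    i = int(np.argmax(w))
    ties = np.isclose(w, w[i], rtol=0, atol=1e-12).sum() > 1
    return PointEstimate(float(dist.angles_deg[i] % 360.0), float(w[i]),
                         degenerate=bool(ties))


def fwhm(dist: PositionDistribution, chance: float | None = None) -> float:
    """FWHM (degrees) of the above-chance region around the peak.

    Half-maximum is ``chance + (max - chance) / 2``; crossings are linearly
    interpolated between bins and the circular wrap is handled. Returns NaN
    for flat distributions and 360 when the whole circle stays above the
    half-maximum.
    """
    w = np.asarray(dist.weights, dtype=float)
    n = w.size
    if chance is None:
        chance = 1.0 / n
    top = w.max()
    if top - chance <= 0 or np.ptp(w) < 1e-15:
        return float("nan")
    half = chance + (top - chance) / 2.0
    # assume equally spaced circular grid
    spacing = 360.0 / n
    ipk = int(np.argmax(w))

    def _walk(step: int) -> float:
        """Distance (deg) from the peak to the half-maximum crossing."""
        prev = ipk
        for k in range(1, n):
            cur = (ipk + step * k) % n
            if w[cur] < half:
                frac = (w[prev] - half) / (w[prev] - w[cur])
                return (k - 1 + frac) * spacing
            prev = cur
        return float("inf")

    left, right = _walk(-1), _walk(+1)
    if np.isinf(left) or np.isinf(right):
        return 360.0
    return float(min(left + right, 360.0))


# ---------------------------------------------------------------------------
# LDA bank and posterior maps
# ---------------------------------------------------------------------------

@dataclass
class LDABank:
    """Per-training-timepoint multiclass LDA models with posterior output."""

    models: list
    train_times_ms: np.ndarray
    channel_indices: np.ndarray
    classes: np.ndarray              # position indices
    class_angles_deg: np.ndarray
    n_positions: int

    def posteriors(self, epochs: EpochSet, model_index: int,
                   test_indices: np.ndarray) -> np.ndarray:
        """Posterior probabilities ``(n_trials, n_test, n_positions)``.

        Classes absent from training (never the case in practice) would
        receive zero probability at their position index.
        """
        X = epochs.data[:, self.channel_indices, :][:, :, test_indices]
        nt, nc, ns = X.shape
        flat = X.transpose(0, 2, 1).reshape(nt * ns, nc)
        proba = self.models[model_index].predict_proba(flat)
        out = np.zeros((nt * ns, self.n_positions))
        out[:, self.classes] = proba
        return out.reshape(nt, ns, self.n_positions)


def _resolve_channels(epochs: EpochSet, channels) -> np.ndarray:
    if channels is None or channels == "all":
        return np.arange(epochs.n_channels)
    if isinstance(channels, str):
        if channels == "posterior":
            return epochs.channels.posterior_indices
        if channels == "posterior17":
            return epochs.channels.index_of(POSTERIOR_17)
        raise ValueError(f"unknown channel selection {channels!r}")
    if len(channels) and isinstance(channels[0], str):
        return epochs.channels.index_of(channels)
    return np.asarray(channels, dtype=int)


def fit_lda_bank(localizers: EpochSet, train_times_ms,
                 channels="posterior", shrinkage: str | float = "auto",
                 geometry: StimulusGeometry | None = None) -> LDABank:
    """Fit one multiclass LDA per training timepoint.

    Uses covariance shrinkage (``lsqr`` solver, analytic shrinkage by
    default) so 40-class fits on modest trial counts remain stable, even
    with degenerate/duplicated trials. Requires at least two trials per
    class.
    """
    ch_idx = _resolve_channels(localizers, channels)
    y = localizers.positions
    classes, counts = np.unique(y, return_counts=True)
    geometry = geometry or StimulusGeometry(n_positions=int(y.max()) + 1)
    if len(classes) < geometry.n_positions:
        missing = sorted(set(range(geometry.n_positions)) - set(classes))
        raise ValueError(f"positions missing from training data: {missing}")
    if counts.min() < 2:
        raise ValueError("need at least 2 trials per class")
    train_times_ms = np.atleast_1d(np.asarray(train_times_ms, dtype=float))
    models = []
    for t in train_times_ms:
        X = localizers.data[:, ch_idx, localizers.time_index(t)]
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
        lda.fit(X, y)
        models.append(lda)
    return LDABank(models=models, train_times_ms=train_times_ms,
                   channel_indices=ch_idx, classes=classes,
                   class_angles_deg=geometry.angle_of(classes),
                   n_positions=geometry.n_positions)


@dataclass
class PositionPosteriorMap:
    """Posterior probabilities over positions, indexed by test time.

    ``probabilities`` has shape ``(n_trials, n_test, n_positions)`` (or
    ``(n_test, n_positions)`` after trial averaging). ``alignment`` is
    "absolute" (bins are the localizer angles) or "recentered" (bin 0 is
    the real-time stimulus position, positive = ahead in the motion
    direction). ``evidence`` subtracts chance (1/n), summing to 0 per cell.
    """

    probabilities: np.ndarray
    test_times_ms: np.ndarray
    position_angles_deg: np.ndarray
    alignment: str = "absolute"

    @property
    def n_positions(self) -> int:
        return self.probabilities.shape[-1]

    @property
    def chance(self) -> float:
        return 1.0 / self.n_positions

    @property
    def evidence(self) -> np.ndarray:
        return self.probabilities - self.chance

    def trial_average(self) -> "PositionPosteriorMap":
        if self.probabilities.ndim == 2:
            return self
        return PositionPosteriorMap(self.probabilities.mean(axis=0),
                                    self.test_times_ms,
                                    self.position_angles_deg, self.alignment)

    def distribution(self, time_index: int) -> PositionDistribution:
        prob = self.trial_average().probabilities
        return PositionDistribution(prob[time_index], self.position_angles_deg)

    def plot(self, ax=None, **imshow_kw):
        """Evidence heat map (test time x position)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ev = self.trial_average().evidence.T
        ax.imshow(ev, aspect="auto", origin="lower",
                  extent=(self.test_times_ms[0], self.test_times_ms[-1],
                          self.position_angles_deg[0] - 180 * (self.alignment == "recentered"),
                          self.position_angles_deg[-1] - 180 * (self.alignment == "recentered")),
                  cmap=imshow_kw.pop("cmap", "RdBu_r"), **imshow_kw)
        ax.set_xlabel("test time (ms)")
        ax.set_ylabel("position (deg)"
                      if self.alignment == "absolute" else "relative position (deg)")
        return ax


def posterior_map(bank: LDABank, motion: EpochSet,
                  train_window_ms: tuple[float, float] | None = (75.0, 125.0),
                  test_window_ms: tuple[float, float] | None = None,
                  decim: int = 1) -> PositionPosteriorMap:
    """Average posteriors from models trained inside ``train_window_ms``.

    With ``train_window_ms=None`` all models are averaged. Returns per-trial
    posteriors on the absolute position grid (row-normalised by
    construction: each posterior vector sums to 1).
    """
    if test_window_ms is None:
        test_idx = np.arange(0, motion.n_samples, decim)
    else:
        mask = motion.time_mask(*test_window_ms)
        test_idx = np.flatnonzero(mask)[::decim]
    if train_window_ms is None:
        sel = np.arange(len(bank.models))
    else:
        sel = np.flatnonzero((bank.train_times_ms >= train_window_ms[0])
                             & (bank.train_times_ms <= train_window_ms[1]))
        if sel.size == 0:
            raise ValueError("no models inside train window")
    acc = None
    for mi in sel:
        post = bank.posteriors(motion, mi, test_idx)
        acc = post if acc is None else acc + post
    probs = acc / len(sel)
    angles = np.arange(bank.n_positions) * (360.0 / bank.n_positions)
    return PositionPosteriorMap(probabilities=probs,
                                test_times_ms=motion.times[test_idx],
                                position_angles_deg=angles,
                                alignment="absolute")


def recenter_posteriors(probs: np.ndarray, true_angles_deg: np.ndarray,
                        directions, n_positions: int) -> np.ndarray:
    """Realign posteriors so the real-time stimulus angle maps to bin 0.

    ``probs``: (n_trials, n_test, n_positions) on the absolute grid;
    ``true_angles_deg``: (n_trials, n_test) real-time stimulus angle;
    ``directions``: per-trial "cw"/"ccw". Counter-clockwise trials are
    mirrored so the positive relative axis always points ahead of the
    stimulus in its motion direction, making averaging over directions
    coherent. Fractional shifts use circular linear interpolation, which
    preserves the unit sum of each posterior vector.
    """
    probs = np.asarray(probs, dtype=float)
    nt, ns, n = probs.shape
    spacing = 360.0 / n_positions
    out = np.empty_like(probs)
    k = np.arange(n)
    for i in range(nt):
        sign = 1.0 if directions[i] == "cw" else -1.0
        # relative bin r sits at absolute angle theta + sign * r * spacing
        shift = true_angles_deg[i] / spacing                    # (ns,)
        base = np.floor(shift).astype(int)
        frac = (shift - base)[:, None]
        idx0 = (sign * k[None, :] + base[:, None]) % n
        idx1 = (sign * k[None, :] + base[:, None] + 1) % n
        rows = np.arange(ns)[:, None]
        out[i] = (1 - frac) * probs[i][rows, idx0.astype(int)] \
            + frac * probs[i][rows, idx1.astype(int)]
    return out


@dataclass
class TrainTimeShiftMap:
    """Recentered training-time x relative-position map with point estimates.

    ``map`` is (n_train, n_positions) averaged over trials, directions and
    test times; relative bin 0 is the real-time position ("Full
    Compensation"), positive = ahead of the stimulus. ``estimates`` holds
    per-train-time peak and centroid read-outs plus the kinematic
    "No Compensation" locus ``-velocity * train_time``.
    """

    map: np.ndarray
    train_times_ms: np.ndarray
    relative_angles_deg: np.ndarray
    estimates: pd.DataFrame
    velocity_deg_ms: float

    def plot(self, ax=None, estimator: str = "peak"):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(self.map - self.map.mean(), aspect="auto", origin="lower",
                  extent=(self.relative_angles_deg[0], self.relative_angles_deg[-1],
                          self.train_times_ms[0], self.train_times_ms[-1]),
                  cmap="RdBu_r")
        est = self.estimates
        ax.plot(est[f"{estimator}_deg"], est["train_time_ms"], "wo", ms=3)
        ax.axvline(0.0, color="k", ls="--", lw=1)
        ax.plot(-self.velocity_deg_ms * est["train_time_ms"],
                est["train_time_ms"], "k--", lw=1)
        ax.set_xlabel("position relative to stimulus (deg)")
        ax.set_ylabel("training time (ms)")
        return ax


def traintime_shift_map(bank: LDABank, motion: EpochSet,
                        test_window_ms: tuple[float, float] = (-1000.0, 0.0),
                        decim: int = 4,
                        geometry: StimulusGeometry | None = None) -> TrainTimeShiftMap:
    """Recentered map across all training timepoints with peak/centroid rows.

    For every model in the bank, posteriors over the test window are
    recentered to the real-time stimulus position (mirroring ccw trials)
    and averaged over trials and test times, giving one relative-position
    distribution per training time. Peaks and centroids are extracted from
    these direction-merged, trial-averaged distributions.
    """
    if motion.trajectory is None:
        raise ValueError("motion epochs need a trajectory log")
    geometry = geometry or StimulusGeometry(n_positions=bank.n_positions)
    v_deg_ms = abs(geometry.velocity_deg_s) / 1000.0
    mask = motion.time_mask(*test_window_ms)
    test_idx = np.flatnonzero(mask)[::decim]
    truth = motion.trajectory[:, test_idx]
    directions = motion.events["direction"].to_numpy()

    n = bank.n_positions
    rel_bins = np.arange(n) * (360.0 / n)
    rel_centered = np.where(rel_bins > 180.0, rel_bins - 360.0, rel_bins)

    rows = []
    map_rows = np.empty((len(bank.models), n))
    for mi, t_train in enumerate(bank.train_times_ms):
        post = bank.posteriors(motion, mi, test_idx)
        rec = recenter_posteriors(post, truth, directions, n)
        dist_w = rec.mean(axis=(0, 1))
        map_rows[mi] = dist_w
        dist = PositionDistribution(dist_w, rel_bins)
        pk, cn = peak(dist), centroid(dist)
        rows.append({
            "train_time_ms": float(t_train),
            "peak_deg": float(angular_difference(pk.angle_deg, 0.0)),
            "peak_height": float(pk.certainty),
            "centroid_deg": float(angular_difference(cn.angle_deg, 0.0)),
            "certainty": float(cn.certainty),
            "no_comp_deg": float(-v_deg_ms * t_train),
        })
    estimates = pd.DataFrame(rows)
    return TrainTimeShiftMap(map=map_rows, train_times_ms=bank.train_times_ms,
                             relative_angles_deg=rel_centered,
                             estimates=estimates, velocity_deg_ms=v_deg_ms)


def recover_shift_ms(estimates: pd.DataFrame, velocity_deg_ms: float,
                     estimator: str = "centroid",
                     certainty_gate: float = 0.5) -> float:
    """Ground-truth latency-shift estimate from a shift-map estimate table.

    For each training time T the displacement of the read-out from the
    kinematic No-Compensation locus, divided by the stimulus speed, is a
    per-stage shift estimate ``delta(T) = est(T)/v + T``; the certainty-
    weighted average over training times is returned in ms. Training times
    whose certainty falls below ``certainty_gate`` times the maximum are
    excluded: between-stage timepoints carry no decodable pattern, and
    their read-outs are circularly wrapped noise that would otherwise
    dominate the average.
    """
    est = estimates[f"{estimator}_deg"].to_numpy(dtype=float)
    t = estimates["train_time_ms"].to_numpy(dtype=float)
    wcol = "certainty" if estimator == "centroid" else "peak_height"
    w = np.clip(estimates[wcol].to_numpy(dtype=float), 0, None)
    delta = est / velocity_deg_ms + t
    valid = np.isfinite(delta) & np.isfinite(w)
    if not valid.any():
        return float("nan")
    keep = valid & (w >= certainty_gate * np.nanmax(w[valid]))
    if not keep.any() or w[keep].sum() <= 0:
        keep = valid
        w = np.where(valid, np.maximum(w, 1e-12), 0.0)
    return float(np.average(delta[keep], weights=w[keep]))


# ---------------------------------------------------------------------------
# Slope interaction regression (actual vs synthetic-control peaks)
# ---------------------------------------------------------------------------

@dataclass
class LatencyShiftResult:
    """OLS fit of estimate ~ train_time * data_type."""

    params: pd.Series
    interaction_coef: float
    interaction_t: float
    interaction_p: float
    _sm_results: object = field(repr=False, default=None)

    def summary(self):
        return self._sm_results.summary()


class LatencyShiftModel:
    """Pooled regression comparing latency-shift slopes across data types.

    Observations are per-train-time position estimates (degrees relative to
    the real-time stimulus position) from the actual-motion analysis and
    the autocorrelation-only synthetic control. The model
    ``estimate ~ train_time * data_type`` tests whether the slopes differ;
    a significant interaction indicates a progressive (training-time-
    dependent) forward shift beyond what stimulus autocorrelation produces.
    """

    def __init__(self, actual: pd.DataFrame, control: pd.DataFrame,
                 estimator: str = "peak", certainty_gate: float = 0.5):
        col = f"{estimator}_deg"
        wcol = "certainty" if estimator == "centroid" else "peak_height"
        frames = []
        for name, df in (("actual", actual), ("synthetic", control)):
            est = df[col].to_numpy(dtype=float)
            nc = df["no_comp_deg"].to_numpy(dtype=float)
            # express each estimate in the wrap branch nearest the
            # No-Compensation locus so late training times do not alias
            est = nc + np.asarray(angular_difference(est, nc), dtype=float)
            w = np.clip(df[wcol].to_numpy(dtype=float), 0, None)
            keep = np.isfinite(est)
            if certainty_gate is not None and np.isfinite(w).any():
                keep &= w >= certainty_gate * np.nanmax(w)
            frames.append(pd.DataFrame({
                "estimate": est[keep],
                "train_time": df["train_time_ms"].to_numpy(dtype=float)[keep],
                "data_type": name,
            }))
        self.data = pd.concat(frames, ignore_index=True)

    def fit(self) -> LatencyShiftResult:
        res = smf.ols("estimate ~ train_time * C(data_type)", data=self.data).fit()
        name = "train_time:C(data_type)[T.synthetic]"
        return LatencyShiftResult(
            params=res.params,
            interaction_coef=float(res.params[name]),
            interaction_t=float(res.tvalues[name]),
            interaction_p=float(res.pvalues[name]),
            _sm_results=res,
        )


def slope_interaction_test(actual: pd.DataFrame, control: pd.DataFrame,
                           estimator: str = "peak",
                           certainty_gate: float = 0.5) -> LatencyShiftResult:
    """Convenience wrapper: fit the slope-interaction regression."""
    return LatencyShiftModel(actual, control, estimator=estimator,
                             certainty_gate=certainty_gate).fit()
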