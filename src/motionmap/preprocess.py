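"""Preprocessing applied before decoding.

Baseline correction, anti-aliased resampling, train/test-safe PCA
denoising, and Morlet time-frequency power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import PCA

from .epochs import ChannelSet, EpochSet

__all__ = [
    "baseline_correct",
    "resample",
    "pca_denoise",
    "fit_pca_basis",
    "morlet_power",
    "TFREpochs",
    "default_freqs",
    "default_n_cycles",
]


def baseline_correct(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window`` (ms).

    Idempotent: applying the same window twice leaves the data unchanged.
    """
    tmin, tmax = window
    mask = epochs.time_mask(tmin, tmax)
    if not mask.any():
        raise ValueError(f"baseline window {window} contains no samples")
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def resample(epochs: EpochSet, new_rate: float) -> EpochSet:
    """Polyphase anti-aliased resampling to ``new_rate`` Hz."""
    if new_rate <= 0:
        raise ValueError("new_rate must be positive")
    if new_rate > epochs.sfreq:
        raise ValueError("upsampling is not supported (new_rate > sfreq)")
    if new_rate == epochs.sfreq:
        return epochs.copy()
    from fractions import Fraction

    frac = Fraction(new_rate / epochs.sfreq).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(epochs.data, up, down, axis=2)
    n_new = data.shape[2]
    t0 = epochs.times[0]
    times = t0 + np.arange(n_new) * 1000.0 / new_rate
    trajectory = None
    if epochs.trajectory is not None:
        # trajectories are labels, not signals: interpolate on the unwrapped angle
        unwrapped = np.unwrap(np.deg2rad(epochs.trajectory), axis=1)
        trajectory = np.rad2deg(
            np.stack([np.interp(times, epochs.times, row) for row in unwrapped])
        ) % 360.0
    return EpochSet(data=data, times=times, channels=epochs.channels,
                    events=epochs.events.copy(), sfreq=float(new_rate),
                    trajectory=trajectory)


def fit_pca_basis(train_features: np.ndarray, variance_kept: float = 0.99) -> PCA:
    """Fit a PCA basis on training features only.

    Retains the minimal number of components whose cumulative explained
    variance reaches ``variance_kept``.
    """
    if not 0 < variance_kept <= 1:
        raise ValueError("variance_kept must be in (0, 1]")
    n_obs, n_feat = train_features.shape
    max_comp = min(n_obs, n_feat)
    if max_comp < 1:
        raise ValueError("need at least one observation and feature")
    pca = PCA(n_components=max_comp, svd_solver="full")
    pca.fit(train_features)
    if variance_kept == 1.0:
        n_keep = max_comp
    else:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_keep = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
        n_keep = min(n_keep, max_comp)
    pca.components_ = pca.components_[:n_keep]
    pca.explained_variance_ = pca.explained_variance_[:n_keep]
    pca.explained_variance_ratio_ = pca.explained_variance_ratio_[:n_keep]
    pca.n_components_ = n_keep
    return pca


def pca_denoise(train: EpochSet, test: EpochSet, variance_kept: float = 0.99,
                time_index: int | None = None):
    """Project train and test epochs through a train-fit PCA basis.

    The basis is computed from the training data only (channels as
    features, trial x sample rows — or a single time point when
    ``time_index`` is given) and applied unchanged to the test set, so no
    test-set statistics leak into the transformation.

    Returns ``(train_projected, test_projected, pca)`` where the projected
    arrays have components in place of channels.
    """
    if len(train.channels) != len(test.channels):
        raise ValueError("train and test must share channels")
    if time_index is None:
        feats = train.data.transpose(0, 2, 1).reshape(-1, train.n_channels)
    else:
        feats = train.data[:, :, time_index]
    pca = fit_pca_basis(feats, variance_kept)

    def _project(ep: EpochSet) -> np.ndarray:
        flat = ep.data.transpose(0, 2, 1).reshape(-1, ep.n_channels)
        proj = pca.transform(flat)
        return proj.reshape(ep.n_trials, ep.n_samples, -1).transpose(0, 2, 1)

    return _project(train), _project(test), pca


# ---------------------------------------------------------------------------
# Morlet time-frequency power
# ---------------------------------------------------------------------------

def default_freqs(n: int = 20, fmin: float = 2.0, fmax: float = 40.0) -> np.ndarray:
    """Linearly spaced analysis frequencies (Hz)."""
    return np.linspace(fmin, fmax, n)


def default_n_cycles(n: int = 20, low: float = 3.0, high: float = 10.0) -> np.ndarray:
    """Logarithmically increasing cycle counts across frequencies."""
    return np.logspace(np.log10(low), np.log10(high), n)


@dataclass
class TFREpochs:
    """Frequency-resolved power: ``(trials, channels, freqs, samples)``."""

    data: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: ChannelSet
    events: pd.DataFrame
    sfreq: float

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def angles(self) -> np.ndarray:
        return self.events["angle"].to_numpy(dtype=float)

    @property
    def positions(self) -> np.ndarray:
        return self.events["position"].to_numpy(dtype=int)


def _morlet_wavelet(f: float, n_cycles: float, sfreq: float) -> np.ndarray:
    sigma_t = n_cycles / (2.0 * np.pi * f)
    t = np.arange(0.0, 5.0 * sigma_t, 1.0 / sfreq)
    t = np.concatenate([-t[::-1], t[1:]])
    osc = np.exp(2j * np.pi * f * t)
    gauss = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    w = osc * gauss
    return w / np.sqrt(0.5 * np.abs(w ** 2).sum())


def morlet_power(epochs: EpochSet, freqs=None, n_cycles=None) -> TFREpochs:
    """Per-trial Morlet wavelet power.

    Defaults: 20 linearly spaced frequencies on [2, 40] Hz with cycle
    counts log-spaced from 3 to 10 across frequencies. Frequencies must be
    below Nyquist.
    """
    freqs = default_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    if n_cycles is None:
        n_cycles = default_n_cycles(len(freqs))
    n_cycles = np.broadcast_to(np.asarray(n_cycles, dtype=float), freqs.shape)
    nyq = epochs.sfreq / 2.0
    if np.any(freqs >= nyq):
        raise ValueError("analysis frequency at or above Nyquist")
    nt, nc, ns = epochs.data.shape
    out = np.empty((nt, nc, len(freqs), ns))
    flat = epochs.data.reshape(nt * nc, ns)
    for fi, (f, c) in enumerate(zip(freqs, n_cycles)):
        w = _morlet_wavelet(f, c, epochs.sfreq)
        analytic = signal.fftconvolve(flat, w[None, :], mode="same", axes=1)
        out[:, :, fi, :] = (np.abs(analytic) ** 2).reshape(nt, nc, ns)
    return TFREpochs(data=out, freqs=freqs, times=epochs.times.copy(),
                     channels=epochs.channels, events=epochs.events.copy(),
                     sfreq=epochs.sfreq)
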