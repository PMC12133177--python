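"""Epoched multichannel data containers.

`EpochSet` is the shared in-memory container for all analyses: a
``(n_trials, n_channels, n_samples)`` array with per-trial event metadata
(pandas DataFrame), channel layout/adjacency (`ChannelSet`) and a common
time axis in milliseconds relative to the locking event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ChannelSet", "EpochSet", "make_montage"]

EVENT_KINDS = ("localizer", "motion_onset", "motion_offset", "reversal")


@dataclass(frozen=True)
class ChannelSet:
    """Ordered channel labels with 2-D scalp coordinates and adjacency.

    ``adjacency[i]`` lists the indices of the immediate neighbours of
    channel ``i`` (not including itself). ``posterior`` flags channels over
    occipito-parietal sites; synthetic montages concentrate position
    information there.
    """

    names: tuple
    positions: np.ndarray          # (n_channels, 2)
    adjacency: tuple               # tuple of tuples of int
    posterior: np.ndarray          # (n_channels,) bool

    def __post_init__(self):
        n = len(self.names)
        if self.positions.shape != (n, 2):
            raise ValueError("positions must be (n_channels, 2)")
        if len(self.adjacency) != n or len(self.posterior) != n:
            raise ValueError("adjacency/posterior length mismatch")

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, names: Sequence[str]) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.names)}
        return np.array([lookup[n] for n in names], dtype=int)

    @property
    def posterior_indices(self) -> np.ndarray:
        return np.flatnonzero(self.posterior)


def make_montage(n_channels: int, posterior_fraction: float = 0.5) -> ChannelSet:
    """Build a simple synthetic scalp montage.

    Channels are laid out on a rough grid from front (+y) to back (-y);
    the rearmost ``posterior_fraction`` of channels are flagged posterior.
    Adjacency connects channels within 1.5 grid units.
    """
    n_cols = max(2, int(np.ceil(np.sqrt(n_channels))))
    rows, cols = np.divmod(np.arange(n_channels), n_cols)
    pos = np.column_stack([cols - cols.mean(), -(rows - rows.mean())]).astype(float)
    dists = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adjacency = tuple(
        tuple(np.flatnonzero((dists[i] > 0) & (dists[i] <= 1.5)))
        for i in range(n_channels)
    )
    n_post = max(1, int(round(posterior_fraction * n_channels)))
    posterior = np.zeros(n_channels, dtype=bool)
    posterior[np.argsort(pos[:, 1])[:n_post]] = True   # rearmost rows
    names = tuple(f"CH{i:02d}" for i in range(n_channels))
    return ChannelSet(names=names, positions=pos, adjacency=adjacency,
                      posterior=posterior)


@dataclass
class EpochSet:
    """Trials x channels x samples with angular labels and timing metadata.

    Attributes
    ----------
    data
        ``(n_trials, n_channels, n_samples)`` float array, arbitrary
        microvolt-scale units.
    times
        Sample timestamps in milliseconds relative to the locking event,
        strictly increasing, shared by all trials.
    channels
        `ChannelSet` shared by all trials.
    events
        One row per trial. Required columns: ``position`` (int index),
        ``angle`` (degrees), ``kind`` (event kind), ``direction``
        (``"cw"``, ``"ccw"`` or ``"none"``). Extra columns are preserved.
    sfreq
        Sampling rate in Hz.
    trajectory
        Optional ``(n_trials, n_samples)`` array of the true stimulus angle
        (degrees) at every sample — present for motion epochs.
    """

    data: np.ndarray
    times: np.ndarray
    channels: ChannelSet
    events: pd.DataFrame
    sfreq: float
    trajectory: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        nt, nc, ns = self.data.shape
        if len(self.times) != ns:
            raise ValueError("times length does not match samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.channels) != nc:
            raise ValueError("channel count mismatch")
        if len(self.events) != nt:
            raise ValueError("events rows must match trials")
        for col in ("position", "angle", "kind", "direction"):
            if col not in self.events.columns:
                raise ValueError(f"events missing column {col!r}")
        if self.trajectory is not None:
            self.trajectory = np.asarray(self.trajectory, dtype=float)
            if self.trajectory.shape != (nt, ns):
                raise ValueError("trajectory must be (trials, samples)")

    # -- basic introspection -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def angles(self) -> np.ndarray:
        return self.events["angle"].to_numpy(dtype=float)

    @property
    def positions(self) -> np.ndarray:
        return self.events["position"].to_numpy(dtype=int)

    # -- manipulation --------------------------------------------------------
    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times=self.times.copy(),
            channels=self.channels,
            events=self.events.copy(),
            sfreq=self.sfreq,
            trajectory=None if self.trajectory is None else self.trajectory.copy(),
        )

    def time_mask(self, tmin: float, tmax: float) -> np.ndarray:
        """Boolean mask over samples with ``tmin <= t <= tmax`` (ms)."""
        return (self.times >= tmin) & (self.times <= tmax)

    def time_index(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times - t_ms)))

    def crop(self, tmin: float, tmax: float) -> "EpochSet":
        mask = self.time_mask(tmin, tmax)
        if not mask.any():
            raise ValueError("crop window contains no samples")
        return EpochSet(
            data=self.data[:, :, mask],
            times=self.times[mask],
            channels=self.channels,
            events=self.events.copy(),
            sfreq=self.sfreq,
            trajectory=None if self.trajectory is None else self.trajectory[:, mask],
        )

    def select_trials(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            times=self.times.copy(),
            channels=self.channels,
            events=self.events.iloc[idx].reset_index(drop=True),
            sfreq=self.sfreq,
            trajectory=None if self.trajectory is None else self.trajectory[idx],
        )

    def pick_channels(self, indices) -> "EpochSet":
        """Subset channels (adjacency is restricted to the subset)."""
        indices = np.asarray(indices, dtype=int)
        remap = {old: new for new, old in enumerate(indices)}
        adjacency = tuple(
            tuple(remap[j] for j in self.channels.adjacency[i] if j in remap)
            for i in indices
        )
        channels = ChannelSet(
            names=tuple(self.channels.names[i] for i in indices),
            positions=self.channels.positions[indices],
            adjacency=adjacency,
            posterior=self.channels.posterior[indices],
        )
        return EpochSet(
            data=self.data[:, indices, :],
            times=self.times.copy(),
            channels=channels,
            events=self.events.copy(),
            sfreq=self.sfreq,
            trajectory=None if self.trajectory is None else self.trajectory.copy(),
        )
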