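"""Interchange container for epoch sets.

An `EpochSet` is stored as two files sharing a stem:

``<stem>.npz``
    NumPy zip archive with the arrays ``data`` (trials x channels x
    samples, float64), ``times`` (ms), optionally ``trajectory``
    (trials x samples, degrees) and the channel geometry arrays.
``<stem>.json``
    Human-readable sidecar with the sampling rate, channel names /
    adjacency / posterior flags, and the per-trial event table.

The round trip is bit-exact (arrays are written untouched at float64).
An optional EDF reader is provided for real recordings when ``mne`` is
installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import ChannelSet, EpochSet

__all__ = ["save_epochs", "load_epochs", "read_edf"]

_FORMAT_VERSION = 1


def save_epochs(epochs: EpochSet, stem) -> tuple[Path, Path]:
    """Write ``<stem>.npz`` + ``<stem>.json``; returns both paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    arrays = {
        "data": epochs.data,
        "times": epochs.times,
        "ch_positions": epochs.channels.positions,
    }
    if epochs.trajectory is not None:
        arrays["trajectory"] = epochs.trajectory
    npz_path = stem.with_suffix(".npz")
    json_path = stem.with_suffix(".json")
    np.savez(npz_path, **arrays)
    sidecar = {
        "format_version": _FORMAT_VERSION,
        "sfreq": epochs.sfreq,
        "channels": {
            "names": list(epochs.channels.names),
            "adjacency": [list(map(int, a)) for a in epochs.channels.adjacency],
            "posterior": [bool(p) for p in epochs.channels.posterior],
        },
        "events": json.loads(epochs.events.to_json(orient="table", index=False)),
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return npz_path, json_path


def load_epochs(stem) -> EpochSet:
    """Load an epoch container written by :func:`save_epochs`."""
    stem = Path(stem)
    npz_path = stem.with_suffix(".npz")
    json_path = stem.with_suffix(".json")
    if not npz_path.exists() or not json_path.exists():
        raise FileNotFoundError(f"container {stem}.npz/.json not found")
    sidecar = json.loads(json_path.read_text())
    if sidecar.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported container format version")
    with np.load(npz_path) as npz:
        data = npz["data"]
        times = npz["times"]
        positions = npz["ch_positions"]
        trajectory = npz["trajectory"] if "trajectory" in npz.files else None
    ch = sidecar["channels"]
    channels = ChannelSet(
        names=tuple(ch["names"]),
        positions=positions,
        adjacency=tuple(tuple(a) for a in ch["adjacency"]),
        posterior=np.asarray(ch["posterior"], dtype=bool),
    )
    events = pd.json_normalize(sidecar["events"]["data"])
    return EpochSet(data=data, times=times, channels=channels,
                    events=events, sfreq=float(sidecar["sfreq"]),
                    trajectory=trajectory)


def read_edf(path, **kwargs):
    """Read a continuous EDF recording into an mne Raw object.

    Thin convenience wrapper; requires the optional ``mne`` dependency.
    Epoching and event annotation are left to the caller since EDF files
    carry no standard position-label scheme.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - env without mne
        raise ImportError("EDF import requires the optional 'mne' dependency") from exc
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return mne.io.read_raw_edf(path, **kwargs)
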