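"""Autocorrelation-only "synthetic EEG" motion control.

Built from lagged localizer-evoked responses: for a virtual trajectory at
the nominal stimulus velocity, the trial-averaged response to each
successive localizer position is temporally offset by the inter-position
travel time (spacing / |velocity|, 25 ms at the defaults) and the offset
responses are averaged. The result carries exactly the spatial
autocorrelation structure of real motion — neighbouring positions evoke
overlapping patterns at the appropriate lags — but no predictive dynamics,
since every constituent response was evoked by an isolated static flash.
Peaks extracted from this control therefore sit on the kinematic
No-Compensation line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .geometry import StimulusGeometry, wrap_angle

__all__ = ["synthesize_motion"]


def _position_averages(localizers: EpochSet, n_positions: int) -> np.ndarray:
    """Trial-averaged evoked response per position: (n_pos, n_ch, n_samples)."""
    out = np.zeros((n_positions, localizers.n_channels, localizers.n_samples))
    pos = localizers.positions
    for p in range(n_positions):
        idx = np.flatnonzero(pos == p)
        if idx.size == 0:
            raise ValueError(f"no localizer trials for position {p}")
        out[p] = localizers.data[idx].mean(axis=0)
    return out


def synthesize_motion(
    localizers: EpochSet,
    geometry: StimulusGeometry,
    n_trials: int = 8,
    seed: int = 0,
    duration_s: float = 2.0,
    lock: str = "offset",
    tmin_ms: float = -1000.0,
    tmax_ms: float = 1000.0,
) -> EpochSet:
    """Construct synthetic-motion epochs from lagged localizer responses.

    Each virtual trial starts at a random localizer position and moves in a
    random direction for ``duration_s``. At epoch time ``t`` the signal is
    the average of the position-ordered localizer responses
    ``R_{p_j}(t - j * lag)`` over all steps ``j`` whose localizer epoch
    window covers ``t`` (``lag = spacing / |velocity|``). Epochs are locked
    to the virtual motion onset or offset and carry the virtual trajectory.
    """
    if lock not in ("motion_onset", "offset"):
        raise ValueError("lock must be 'motion_onset' or 'offset'")
    lag_ms = geometry.inter_position_interval_s * 1000.0
    loc_tmin, loc_tmax = localizers.times[0], localizers.times[-1]
    if loc_tmax - loc_tmin < lag_ms:
        raise ValueError("localizer epochs shorter than one inter-position lag")
    rng = np.random.default_rng(seed)
    sfreq = localizers.sfreq
    dt_ms = 1000.0 / sfreq
    times = np.arange(np.round(tmin_ms / dt_ms),
                      np.round(tmax_ms / dt_ms) + 1) * dt_ms
    n_pos = geometry.n_positions
    R = _position_averages(localizers, n_pos)
    v_deg_ms = geometry.velocity_deg_s / 1000.0
    duration_ms = duration_s * 1000.0
    n_steps = int(np.floor(duration_ms / lag_ms)) + 1

    data = np.zeros((n_trials, localizers.n_channels, times.size))
    trajectory = np.zeros((n_trials, times.size))
    rows = []
    for i in range(n_trials):
        p0 = int(rng.integers(0, n_pos))
        direction = 1 if rng.random() < 0.5 else -1
        t_lock = 0.0 if lock == "motion_onset" else duration_ms
        abs_t = t_lock + times                       # time since virtual onset
        acc = np.zeros((localizers.n_channels, times.size))
        count = np.zeros(times.size)
        for j in range(n_steps):
            pj = (p0 + direction * j) % n_pos
            rel = abs_t - j * lag_ms                 # time within R_pj's epoch
            valid = (rel >= loc_tmin) & (rel <= loc_tmax)
            if not valid.any():
                continue
            idx = np.round((rel[valid] - loc_tmin) / dt_ms).astype(int)
            idx = np.clip(idx, 0, localizers.n_samples - 1)
            acc[:, valid] += R[pj][:, idx]
            count[valid] += 1
        with np.errstate(invalid="ignore"):
            data[i] = np.where(count > 0, acc / np.maximum(count, 1), 0.0)
        theta0 = float(geometry.angle_of(p0))
        ang = theta0 + direction * v_deg_ms * np.clip(abs_t, 0.0, duration_ms)
        trajectory[i] = wrap_angle(ang)
        rows.append({
            "position": int(geometry.nearest_index(trajectory[i][np.argmin(np.abs(times))])),
            "angle": float(trajectory[i][np.argmin(np.abs(times))]),
            "kind": "motion_offset" if lock == "offset" else "motion_onset",
            "direction": "cw" if direction > 0 else "ccw",
            "t_lock_ms": t_lock,
            "t_onset_ms": 0.0,
            "t_offset_ms": duration_ms,
            "t_reversal_ms": np.nan,
        })
    events = pd.DataFrame(rows)
    return EpochSet(data=data, times=times, channels=localizers.channels,
                    events=events, sfreq=sfreq, trajectory=trajectory)
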