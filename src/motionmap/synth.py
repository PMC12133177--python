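"""Synthetic EEG-like data with known position coding and latency shifts.

The generator emulates the statistical structure the decoding analyses
assume: a cascade of temporally distinct, position-tuned evoked stages
(giving a diagonal temporal-generalization matrix), posterior-concentrated
topographies, smooth circular motion with optional reversals, and a
configurable per-stage extrapolation shift ``delta_s`` that advances the
stage's response in time during smooth motion only. ``delta_s`` is the
ground truth that the training-time latency-shift analysis recovers.

Forward model
-------------
Each stage *s* has an impulse response ``h_s(t) = A_s * hann(t - L_s; D_s)``
(optionally multiplied by an oscillatory carrier) and a position-to-
topography map ``T_s(theta) = B_s @ f_s(theta)``. ``B_s`` is a random
posterior-weighted channel basis, orthogonalised across stages so that
distinct stages occupy orthogonal channel subspaces — this is what makes
the temporal generalization matrix diagonal, and it is exact even at small
channel counts (a full-rank random mixing cannot be near-orthogonal when
the number of channels is small relative to the number of stages).
``f_s(theta)`` is the rank-limited von Mises position code: circular
harmonics ``cos(h theta), sin(h theta)`` weighted by the von Mises Fourier
coefficients ``I_h(kappa) / I_0(kappa)``, with a random reference phase
per stage. Pattern similarity therefore decays monotonically with angular
distance at a width set by ``tuning_kappa`` (as far as the per-stage
subspace dimension allows harmonics).

A localizer flash at angle ``theta`` evokes ``h_s(t) T_s(theta)``; smooth
motion evokes the superposition over the stimulus path,
``y(t) = sum_s (h_s * T_s(theta(.)))(t + delta_s)``, i.e. the stage's
response to the stimulus occupying position ``p`` at time ``t(p)`` begins
at ``t(p) + L_s - delta_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import ChannelSet, EpochSet, make_montage
from .geometry import StimulusGeometry, wrap_angle

__all__ = ["EvokedCascadeModel", "simulate_localizers", "simulate_motion"]


@dataclass(frozen=True)
class EvokedCascadeModel:
    """Forward model of the evoked processing cascade.

    Parameters
    ----------
    n_channels
        Number of synthetic channels (montage built automatically; the
        rearmost half are posterior and carry the position information).
    stage_latencies_ms
        Onset of each stage's response envelope relative to stimulus
        occupancy, ms. One stage per entry.
    stage_durations_ms, stage_amplitudes
        Hann-envelope duration and peak amplitude per stage (recycled if
        scalar).
    tuning_kappa
        von Mises concentration of the position -> topography tuning over
        polar angle. Larger = sharper position tuning.
    carrier_freq_hz
        Optional oscillatory carrier multiplying every stage envelope
        (used by the frequency-specific decoding checks). ``None`` keeps
        envelopes strictly positive, which is the default regime.
    noise_sd
        Additive Gaussian noise standard deviation per channel/sample.
    noise_exponent
        Spectral exponent for optional 1/f^a temporal colouring of the
        noise (0 = white).
    posterior_leak
        Relative amplitude of position information on non-posterior
        channels (information is concentrated posteriorly).
    stage_shift_ms
        Extrapolation shift delta_s per stage, applied only during smooth
        motion; the ground truth for parameter recovery.
    topography_seed
        Seed of the random stage-mixing matrices ("which brain"); distinct
        from the trial-noise seed passed to the simulate functions.
    """

    n_channels: int = 12
    posterior_fraction: float = 2.0 / 3.0
    stage_latencies_ms: tuple = (75.0, 150.0, 225.0, 300.0)
    stage_durations_ms: tuple = (80.0, 80.0, 80.0, 80.0)
    stage_amplitudes: tuple = (2.0, 2.0, 2.0, 2.0)
    tuning_kappa: float = 8.0
    carrier_freq_hz: float | None = None
    noise_sd: float = 0.25
    noise_exponent: float = 0.0
    posterior_leak: float = 0.05
    stage_shift_ms: tuple = (0.0, 0.0, 0.0, 0.0)
    topography_seed: int = 0

    @property
    def n_stages(self) -> int:
        return len(self.stage_latencies_ms)

    def with_shift(self, shift_ms) -> "EvokedCascadeModel":
        """Copy of the model with new per-stage shifts (scalar broadcast)."""
        shift = np.broadcast_to(np.asarray(shift_ms, dtype=float),
                                (self.n_stages,))
        from dataclasses import replace
        return replace(self, stage_shift_ms=tuple(shift))

    # -- derived structure ---------------------------------------------------
    def montage(self) -> ChannelSet:
        return make_montage(self.n_channels, self.posterior_fraction)

    def _stage_param(self, values) -> np.ndarray:
        return np.broadcast_to(np.asarray(values, dtype=float), (self.n_stages,))

    @property
    def n_harmonics(self) -> int:
        """Circular harmonics per stage, set by the posterior channel budget."""
        n_post = int(self.montage().posterior.sum())
        return max(1, n_post // (2 * self.n_stages))

    def stage_bases(self) -> np.ndarray:
        """Orthonormal channel bases per stage: ``(n_stages, n_ch, 2 H)``.

        Columns are orthonormal across all stages (QR of a random
        posterior-weighted matrix), so stage subspaces are mutually
        orthogonal and concentrated on posterior channels; anterior
        channels receive only ``posterior_leak``-scale loadings.
        Deterministic in ``topography_seed``. Requires at least
        ``2 * n_stages`` posterior channels.
        """
        montage = self.montage()
        n_post = int(montage.posterior.sum())
        d = 2 * self.n_harmonics
        if n_post < 2 * self.n_stages:
            raise ValueError(
                f"{self.n_stages} stages need >= {2 * self.n_stages} posterior "
                f"channels for orthogonal subspaces; montage has {n_post}")
        rng = np.random.default_rng(self.topography_seed)
        weights = np.where(montage.posterior, 1.0, self.posterior_leak)
        G = weights[:, None] * rng.standard_normal(
            (self.n_channels, self.n_stages * d))
        Q, _ = np.linalg.qr(G)
        return Q.T.reshape(self.n_stages, d, self.n_channels).transpose(0, 2, 1)

    def harmonic_coefficients(self) -> np.ndarray:
        """von Mises Fourier coefficients I_h(kappa)/I_0(kappa), h = 1..H."""
        from scipy.special import iv

        h = np.arange(1, self.n_harmonics + 1)
        return iv(h, self.tuning_kappa) / iv(0, self.tuning_kappa)

    def patterns(self, geometry: StimulusGeometry, angles_deg) -> np.ndarray:
        """Topography evoked per stage for each angle: (n_stages, n_ch, n_angles).

        Patterns are normalised so the RMS amplitude over channels and the
        canonical positions is one per stage; ``stage_amplitudes`` set the
        overall signal scale.
        """
        angles = np.deg2rad(np.atleast_1d(np.asarray(angles_deg, dtype=float)))
        B = self.stage_bases()                                  # (S, C, 2H)
        coef = self.harmonic_coefficients()                     # (H,)
        rng = np.random.default_rng(self.topography_seed + 1)
        phases = rng.uniform(0, 2 * np.pi, size=(self.n_stages,
                                                 self.n_harmonics))
        h = np.arange(1, self.n_harmonics + 1)
        out = np.empty((self.n_stages, self.n_channels, angles.size))
        # normalisation: RMS over channels x angles of the harmonic code
        # sum_h c_h^2 * (cos^2+sin^2) averaged -> sum c_h^2 / n_ch
        scale = 1.0 / np.sqrt(np.sum(coef ** 2) / self.n_channels)
        for s in range(self.n_stages):
            arg = h[:, None] * angles[None, :] - phases[s][:, None]
            f = np.concatenate([coef[:, None] * np.cos(arg),
                                coef[:, None] * np.sin(arg)], axis=0)
            out[s] = scale * (B[s] @ f)
        return out

    def impulse_response(self, times_ms: np.ndarray, stage: int) -> np.ndarray:
        """h_s evaluated on a time axis (ms relative to stimulus occupancy)."""
        L = self._stage_param(self.stage_latencies_ms)[stage]
        D = self._stage_param(self.stage_durations_ms)[stage]
        A = self._stage_param(self.stage_amplitudes)[stage]
        u = times_ms - L
        env = np.where((u >= 0) & (u <= D),
                       np.sin(np.pi * np.clip(u, 0, D) / D) ** 2, 0.0)
        if self.carrier_freq_hz is not None:
            env = env * np.cos(2e-3 * np.pi * self.carrier_freq_hz * u)
        return A * env

    def motion_kernel(self, times_ms: np.ndarray, stage: int) -> np.ndarray:
        """Impulse response normalised to unit envelope mass.

        Convolving the stimulus path with this kernel yields a response
        whose amplitude matches the stage amplitude times the (smeared)
        topography, i.e. the sustained analogue of the localizer response.
        """
        L = self._stage_param(self.stage_latencies_ms)[stage]
        D = self._stage_param(self.stage_durations_ms)[stage]
        u = times_ms - L
        env = np.where((u >= 0) & (u <= D),
                       np.sin(np.pi * np.clip(u, 0, D) / D) ** 2, 0.0)
        norm = env.sum()
        if norm == 0:
            return np.zeros_like(env)
        return self.impulse_response(times_ms, stage) / norm


def _noise(rng: np.random.Generator, shape, sd: float, exponent: float) -> np.ndarray:
    """Gaussian noise, optionally 1/f^a coloured along the last axis."""
    x = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    if exponent != 0.0:
        n = shape[-1]
        freqs = np.fft.rfftfreq(n, d=1.0)
        scale = np.ones_like(freqs)
        scale[1:] = freqs[1:] ** (-exponent / 2.0)
        spec = np.fft.rfft(x, axis=-1) * scale
        x = np.fft.irfft(spec, n=n, axis=-1)
        x /= x.std(axis=-1, keepdims=True) + 1e-30
    return sd * x


def simulate_localizers(
    geometry: StimulusGeometry,
    model: EvokedCascadeModel,
    n_reps: int,
    seed: int,
    sfreq: float = 250.0,
    tmin_ms: float = -200.0,
    tmax_ms: float = 400.0,
    n_following: int = 0,
    shuffle: bool = True,
) -> EpochSet:
    """Epochs locked to localizer onsets, one per flash.

    ``n_reps`` trials per position. With ``n_following > 0`` each epoch
    additionally contains the evoked cascades of that many subsequent
    flashes at the localizer rate (positions drawn independently and
    recorded in ``events['pos_next1']`` ...), emulating the overlapping
    5 Hz stimulus stream.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n_pos = geometry.n_positions
    positions = np.repeat(np.arange(n_pos), n_reps)
    if shuffle:
        rng.shuffle(positions)
    n_trials = positions.size
    times = np.arange(np.round(tmin_ms * sfreq / 1000.0),
                      np.round(tmax_ms * sfreq / 1000.0) + 1) * (1000.0 / sfreq)

    soa_ms = 1000.0 / geometry.localizer_rate_hz
    follow_pos = rng.integers(0, n_pos, size=(n_trials, n_following))

    patterns = model.patterns(geometry, geometry.position_angles)  # (S, C, P)
    data = np.zeros((n_trials, model.n_channels, times.size))
    for s in range(model.n_stages):
        h0 = model.impulse_response(times, s)
        data += patterns[s][:, positions].T[:, :, None] * h0[None, None, :]
        for k in range(n_following):
            hk = model.impulse_response(times - soa_ms * (k + 1), s)
            if np.any(hk):
                data += (patterns[s][:, follow_pos[:, k]].T[:, :, None]
                         * hk[None, None, :])
    data += _noise(rng, data.shape, model.noise_sd, model.noise_exponent)

    events = pd.DataFrame({
        "position": positions,
        "angle": geometry.angle_of(positions),
        "kind": "localizer",
        "direction": "none",
    })
    for k in range(n_following):
        events[f"pos_next{k + 1}"] = follow_pos[:, k]
    return EpochSet(data=data, times=times, channels=model.montage(),
                    events=events, sfreq=sfreq)


def _trajectory_fn(theta0: float, direction: int, velocity_deg_s: float,
                   t_reversal_ms: float | None):
    """True stimulus angle (deg) as a function of time since motion onset (ms)."""
    v = direction * velocity_deg_s / 1000.0  # deg per ms

    def theta(t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        ang = theta0 + v * t
        if t_reversal_ms is not None:
            past = t > t_reversal_ms
            ang = np.where(
                past, theta0 + v * t_reversal_ms - v * (t - t_reversal_ms), ang)
        return wrap_angle(ang)

    return theta


def simulate_motion(
    geometry: StimulusGeometry,
    model: EvokedCascadeModel,
    n_trials: int,
    seed: int,
    duration_range_s: tuple[float, float] = (1.5, 3.5),
    reversal_prob: float = 0.5,
    post_reversal_range_s: tuple[float, float] = (0.5, 1.0),
    sfreq: float = 250.0,
    lock: str = "offset",
    tmin_ms: float = -1000.0,
    tmax_ms: float = 1000.0,
) -> EpochSet:
    """Epochs around smooth-motion events, with a per-sample trajectory log.

    Each trial simulates a motion sequence: the stimulus appears at a
    random localizer position, moves at ``geometry.velocity_deg_s``
    (direction randomised) for 1.5-3.5 s, and either disappears or (with
    ``reversal_prob``) reverses and continues 0.5-1 s before disappearing.
    The epoch is locked to ``lock`` in {"motion_onset", "offset",
    "reversal"}; reversal-locked runs force every trial to reverse.

    The returned EpochSet carries ``trajectory`` (true angle per sample;
    held at the last visible angle outside the motion interval) and events
    columns ``t_lock_ms`` (lock time since motion onset), ``t_onset_ms``,
    ``t_offset_ms``, ``t_reversal_ms`` (NaN when absent).
    """
    if lock not in ("motion_onset", "offset", "reversal"):
        raise ValueError("lock must be 'motion_onset', 'offset' or 'reversal'")
    rng = np.random.default_rng(seed)
    n_pos = geometry.n_positions
    dt_ms = 1000.0 / sfreq
    times = np.arange(np.round(tmin_ms / dt_ms),
                      np.round(tmax_ms / dt_ms) + 1) * dt_ms

    lat = model._stage_param(model.stage_latencies_ms)
    dur = model._stage_param(model.stage_durations_ms)
    shift = model._stage_param(model.stage_shift_ms)
    max_kernel_ms = float((lat + dur).max())

    data = np.zeros((n_trials, model.n_channels, times.size))
    trajectory = np.zeros((n_trials, times.size))
    rows = []
    for i in range(n_trials):
        start_idx = rng.integers(0, n_pos)
        theta0 = float(geometry.angle_of(start_idx))
        direction = 1 if rng.random() < 0.5 else -1
        t_main = rng.uniform(*duration_range_s) * 1000.0
        reverses = (lock == "reversal") or (rng.random() < reversal_prob)
        if reverses:
            t_rev = t_main
            t_off = t_rev + rng.uniform(*post_reversal_range_s) * 1000.0
        else:
            t_rev = None
            t_off = t_main
        t_lock = {"motion_onset": 0.0, "offset": t_off,
                  "reversal": t_rev if t_rev is not None else t_off}[lock]

        theta = _trajectory_fn(theta0, direction, geometry.velocity_deg_s, t_rev)

        # absolute-time grid covering the epoch plus kernel history
        abs_lo = t_lock + times[0] - max_kernel_ms - float(shift.max(initial=0.0))
        abs_hi = t_lock + times[-1] + float(max(0.0, shift.max(initial=0.0)))
        grid = np.arange(np.floor(abs_lo / dt_ms), np.ceil(abs_hi / dt_ms) + 1) * dt_ms
        visible = (grid >= 0.0) & (grid <= t_off)
        ang_grid = theta(np.clip(grid, 0.0, t_off))
        P = model.patterns(geometry, ang_grid)                 # (S, n_ch, n_grid)
        P[:, :, ~visible] = 0.0

        epoch = np.zeros((model.n_channels, times.size))
        for s in range(model.n_stages):
            kernel_t = np.arange(0.0, max_kernel_ms + dt_ms, dt_ms)
            k = model.motion_kernel(kernel_t, s)
            if not np.any(k):
                continue
            path = P[s]                                        # (n_ch, n_grid)
            resp = signal.fftconvolve(path, k[None, :], mode="full", axes=1)
            # resp[:, j] corresponds to absolute time grid[0] + j*dt
            # stage response advanced by delta_s: sample at t + delta_s
            sample_t = t_lock + times + shift[s]
            idx = np.round((sample_t - grid[0]) / dt_ms).astype(int)
            idx = np.clip(idx, 0, resp.shape[1] - 1)
            epoch += resp[:, idx]
        data[i] = epoch
        trajectory[i] = theta(np.clip(t_lock + times, 0.0, t_off))
        rows.append({
            "position": int(geometry.nearest_index(theta(t_lock))),
            "angle": float(theta(t_lock)),
            "kind": lock if lock != "offset" else "motion_offset",
            "direction": "cw" if direction > 0 else "ccw",
            "t_lock_ms": t_lock,
            "t_onset_ms": 0.0,
            "t_offset_ms": t_off,
            "t_reversal_ms": np.nan if t_rev is None else t_rev,
        })

    data += _noise(rng, data.shape, model.noise_sd, model.noise_exponent)
    events = pd.DataFrame(rows)
    return EpochSet(data=data, times=times, channels=model.montage(),
                    events=events, sfreq=sfreq, trajectory=trajectory)
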