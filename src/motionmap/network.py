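"""Hierarchical velocity-tuned firing-rate network with STDP-shifted weights.

The model is a feedforward hierarchy of ``N_l`` layers, each holding
``N_v`` velocity-tuned subpopulations of ``N_n`` neurons whose spatial
tunings tile the circular interval [0, 1). A point stimulus traverses the
circle at 1 cycle/s; the input layer encodes its position as a Gaussian
bump (width ``sigma_p``, magnitude ``S * r_b`` on a baseline ``r_b``).
Higher layers integrate delayed input through leaky dynamics,

    r(t) = r(t - dt) * exp(-dt / tau_m) + (dt / tau_m) * I(t),
    I(t) = W @ r_below(t - t_delay),

with feedforward weights Gaussian over circular space (width ``sigma_w``)
centred on each neuron's own position plus ``beta * STDP(v, l)`` — the
spike-timing-dependent-plasticity receptive-field shift, which points
opposite to the preferred motion direction and lets downstream neurons
anticipate a moving stimulus. No learning is simulated: the shifts are
imposed on the connectivity, and only rates propagate.

Because neurons tile the circle uniformly and every neuron in a
subpopulation shares the same shift, each weight matrix is circulant;
layer input is computed as a circular cross-correlation via FFT. A banded
variant truncates the Gaussian kernel at a configurable multiple of
``sigma_w`` (the default); a dense-matrix path is retained for
verification.

A global position representation per layer/time is the velocity-weighted
average of subpopulation rates, with weights following a Gaussian over
velocity whose mean moves from 0 to the true stimulus velocity (and whose
width shrinks) over an initial integration period, applied to each layer
with its accumulated transmission delay.

Extrapolation is quantified at the final step against a ``beta = 0``
control run: the control's peak defines the (empirical) No-Compensation
locus, the real-time stimulus position the Full-Compensation locus, and
the magnitude is the fraction of that distance covered by the STDP
network's peak, averaged over layers 2..N_l.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkConfig",
    "STDPShiftProfile",
    "build_base_shift_curve",
    "build_weight_kernels",
    "dense_weight_matrix",
    "velocity_weights",
    "ExtrapolationNetwork",
    "NetworkRun",
    "extrapolation_magnitude",
    "NetworkFit",
    "fit_grid",
]

#: Named beta presets for the tabulated reference parameter set.
BETA_TABULATED = 0.6
BETA_FITTED = 0.3


def _wrap_unit(x):
    """Wrap circular-space coordinates into [-0.5, 0.5)."""
    return (np.asarray(x, dtype=float) + 0.5) % 1.0 - 0.5


@dataclass(frozen=True)
class NetworkConfig:
    """Simulation parameters.

    Defaults reproduce the reference parameter set: 5 layers of 1,000
    neurons, 21 velocity subpopulations spanning [-2, 2] cycles/s, weight
    and stimulus widths 1/32 of the circle, 5 Hz baseline, stimulus
    intensity 20 (a.u.), 1 ms steps for 300 steps with a 100-step velocity
    integration period, 10 ms membrane time constant and 11 ms transmission
    delay. ``beta`` scales the STDP shift profile; 0.3 is the fitted
    preset (``BETA_FITTED``) and 0.6 the tabulated one (``BETA_TABULATED``).
    """

    n_layers: int = 5
    n_neurons: int = 1000
    n_velocities: int = 21
    sigma_w: float = 1.0 / 32.0
    sigma_p: float = 1.0 / 32.0
    r_baseline: float = 5.0
    stim_intensity: float = 20.0
    dt_ms: float = 1.0
    n_steps: int = 300
    t_integration_steps: int = 100
    tau_m_ms: float = 10.0
    t_delay_ms: float = 11.0
    beta: float = BETA_FITTED
    sigma_g0: float = 2.0
    sigma_gT: float = 0.125
    v_span: float = 2.0
    stimulus_velocity: float = 1.0       # cycles/s (+ = clockwise)
    stimulus_start: float = 0.5          # circular units
    banded: bool = True
    band_halfwidth_sigmas: float = 6.0

    def __post_init__(self):
        for name in ("n_layers", "n_neurons", "n_velocities", "sigma_w",
                     "sigma_p", "dt_ms", "n_steps", "tau_m_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_delay_ms < 0:
            raise ValueError("t_delay_ms must be non-negative")
        ratio = self.t_delay_ms / self.dt_ms
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("t_delay_ms must be a multiple of dt_ms")

    @property
    def velocities(self) -> np.ndarray:
        """Velocity grid, cycles/s."""
        return np.linspace(-self.v_span, self.v_span, self.n_velocities)

    @property
    def positions(self) -> np.ndarray:
        """Neuron positions on the unit circle."""
        return np.arange(self.n_neurons) / self.n_neurons

    @property
    def delay_steps(self) -> int:
        return int(round(self.t_delay_ms / self.dt_ms))

    @property
    def decay(self) -> float:
        return float(np.exp(-self.dt_ms / self.tau_m_ms))

    def stimulus_position(self, step) -> np.ndarray:
        """Stimulus position (circular units) at integer step(s)."""
        t_s = np.asarray(step, dtype=float) * self.dt_ms / 1000.0
        return (self.stimulus_start + self.stimulus_velocity * t_s) % 1.0


# ---------------------------------------------------------------------------
# STDP receptive-field shift profile
# ---------------------------------------------------------------------------

#: Default anchor curve for the STDP-driven receptive-field shift magnitude
#: (circular units per layer transition) as a function of absolute stimulus
#: velocity (cycles/s): approximately linear at low velocities, saturating
#: above ~2 cycles/s. These anchors set only the overall scale; the fitted
#: ``beta`` multiplier absorbs it.
DEFAULT_ANCHOR_VELOCITIES = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
                             1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_ANCHOR_SHIFTS = (0.0008, 0.0016, 0.0024, 0.0032, 0.0040, 0.0048,
                         0.0056, 0.0064, 0.0072, 0.0080, 0.0110, 0.0122,
                         0.0125, 0.0125)


@dataclass(frozen=True)
class STDPShiftProfile:
    """Receptive-field shift per velocity and layer transition.

    ``shifts[l, v]`` is the signed shift (circular units) applied to the
    feedforward weights into layer ``l + 2`` (transitions are indexed from
    the input layer). The profile is odd in velocity — mirrored sign for
    opposite directions, zero at v = 0 — and points opposite to the motion
    direction, so positive velocities carry negative shifts.
    """

    shifts: np.ndarray               # (n_layers - 1, n_velocities)
    velocities: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.shifts, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        if s.ndim != 2 or s.shape[1] != v.size:
            raise ValueError("shifts must be (n_transitions, n_velocities)")
        object.__setattr__(self, "shifts", s)
        object.__setattr__(self, "velocities", v)


def build_base_shift_curve(
    velocities: np.ndarray,
    n_transitions: int,
    anchor_velocities=DEFAULT_ANCHOR_VELOCITIES,
    anchor_shifts=DEFAULT_ANCHOR_SHIFTS,
    layer_scales=None,
) -> STDPShiftProfile:
    """Interpolate the anchor curve onto a velocity grid, mirrored odd.

    Anchors give shift magnitudes for positive velocities; values between
    anchors (and between 0 and the first anchor) are linearly interpolated,
    and negative velocities receive the sign-inverted magnitudes. Shifts
    point opposite to the motion direction. ``layer_scales`` optionally
    scales each layer transition (default: identical across layers).
    """
    av = np.concatenate([[0.0], np.asarray(anchor_velocities, dtype=float)])
    ash = np.concatenate([[0.0], np.asarray(anchor_shifts, dtype=float)])
    if np.any(np.diff(av) <= 0):
        raise ValueError("anchor velocities must be increasing")
    velocities = np.asarray(velocities, dtype=float)
    mag = np.interp(np.abs(velocities), av, ash)
    base = -np.sign(velocities) * mag          # opposite to motion direction
    if layer_scales is None:
        layer_scales = np.ones(n_transitions)
    layer_scales = np.asarray(layer_scales, dtype=float)
    if layer_scales.size != n_transitions:
        raise ValueError("layer_scales must have one entry per transition")
    return STDPShiftProfile(shifts=layer_scales[:, None] * base[None, :],
                            velocities=velocities)


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

def build_weight_kernels(config: NetworkConfig,
                         profile: STDPShiftProfile,
                         beta: float | None = None) -> np.ndarray:
    """Feedforward weight kernels, one per (layer transition, velocity).

    ``kernels[l, v, m]`` is the weight from the presynaptic neuron offset
    ``m`` bins clockwise of the postsynaptic neuron: a wrapped Gaussian of
    width ``sigma_w`` centred at ``beta * STDP(v, l)``, normalised to unit
    sum (keeping the layer gain at one for uniform input). With
    ``config.banded`` the kernel is truncated at
    ``band_halfwidth_sigmas * sigma_w`` (default 6 sigma, keeping truncated
    rates within ~1e-8 of the dense computation) and renormalised.
    """
    beta = config.beta if beta is None else beta
    n = config.n_neurons
    offsets = _wrap_unit(np.arange(n) / n)                       # (n,)
    mu = beta * profile.shifts[:, :, None]                       # (L-1, V, 1)
    d = _wrap_unit(offsets[None, None, :] - mu)
    kernels = np.exp(-d ** 2 / (2.0 * config.sigma_w ** 2))
    if config.banded:
        half = config.band_halfwidth_sigmas * config.sigma_w
        kernels = np.where(np.abs(d) <= half, kernels, 0.0)
    return kernels / kernels.sum(axis=-1, keepdims=True)


def dense_weight_matrix(kernel: np.ndarray) -> np.ndarray:
    """Materialise the circulant weight matrix W[i, j] = kernel[(j - i) % n]."""
    n = kernel.shape[-1]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return kernel[..., (j - i) % n]


def _correlate(kernel_fft: np.ndarray, rates: np.ndarray, n: int) -> np.ndarray:
    """Circular cross-correlation I[i] = sum_m kernel[m] r[i + m] via FFT."""
    return np.fft.irfft(np.fft.rfft(rates, axis=-1) * np.conj(kernel_fft), n=n,
                        axis=-1)


# ---------------------------------------------------------------------------
# Velocity integration schedule
# ---------------------------------------------------------------------------

def velocity_weights(step: int, config: NetworkConfig, layer: int) -> np.ndarray:
    """Activity weights over velocity subpopulations at one step and layer.

    A Gaussian over the velocity grid whose mean moves linearly from 0 to
    the true stimulus velocity across the integration period and whose
    width shrinks from ``sigma_g0`` to ``sigma_gT``; the schedule reaches
    layer ``layer`` (1-based) delayed by ``(layer - 1) * t_delay``. Weights
    are normalised to unit sum.
    """
    t_eff = step - (layer - 1) * config.delay_steps
    u = np.clip(t_eff / config.t_integration_steps, 0.0, 1.0)
    mu = config.stimulus_velocity * u
    sigma = config.sigma_g0 + (config.sigma_gT - config.sigma_g0) * u
    g = np.exp(-(config.velocities - mu) ** 2 / (2.0 * sigma ** 2))
    return g / g.sum()


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class NetworkRun:
    """Results of one simulation.

    ``representation[l, :, t]`` is the normalised global position
    representation of layer ``l`` (0-based) at step ``t``; ``rates`` is the
    full layer x velocity x neuron x time array when stored.
    """

    config: NetworkConfig
    beta: float
    representation: np.ndarray          # (n_layers, n_neurons, n_steps)
    stimulus_positions: np.ndarray      # (n_steps,)
    g_weights: np.ndarray               # (n_layers, n_velocities, n_steps)
    rates: np.ndarray | None = None

    def peak_positions(self, step: int = -1, refine: bool = True) -> np.ndarray:
        """Peak of each layer's representation (circular units) at a step.

        With ``refine`` a parabolic interpolation around the maximum gives
        sub-bin resolution.
        """
        n = self.config.n_neurons
        out = np.empty(self.config.n_layers)
        for l in range(self.config.n_layers):
            prof = self.representation[l, :, step]
            i = int(np.argmax(prof))
            pos = i / n
            if refine:
                ym, y0, yp = prof[(i - 1) % n], prof[i], prof[(i + 1) % n]
                denom = ym - 2 * y0 + yp
                if denom < 0:
                    pos += 0.5 * (ym - yp) / denom / n
            out[l] = pos % 1.0
        return out

    def plot(self, step: int = -1, ax=None):
        """Layer profiles recentred on the real-time stimulus position."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        n = self.config.n_neurons
        true_pos = self.stimulus_positions[step]
        rel = _wrap_unit(np.arange(n) / n - true_pos)
        order = np.argsort(rel)
        for l in range(self.config.n_layers):
            ax.plot(rel[order], self.representation[l, order, step],
                    label=f"layer {l + 1}")
        ax.axvline(0.0, color="k", ls="--", lw=1)
        ax.set_xlabel("position relative to stimulus (cycles)")
        ax.set_ylabel("normalised activity")
        ax.legend()
        return ax


class ExtrapolationNetwork:
    """The hierarchical firing-rate model, ready to simulate or fit.

    Parameters
    ----------
    config
        Simulation parameters (`NetworkConfig`).
    profile
        STDP receptive-field shift profile; by default the built-in anchor
        curve interpolated onto the configured velocity grid.
    """

    def __init__(self, config: NetworkConfig | None = None,
                 profile: STDPShiftProfile | None = None):
        self.config = config or NetworkConfig()
        self.profile = profile or build_base_shift_curve(
            self.config.velocities, self.config.n_layers - 1)

    def input_rates(self, step: int) -> np.ndarray:
        """Input-layer rates: baseline plus the stimulus bump."""
        cfg = self.config
        d = _wrap_unit(cfg.positions - cfg.stimulus_position(step))
        bump = np.exp(-d ** 2 / (2.0 * cfg.sigma_p ** 2))
        return cfg.r_baseline + cfg.stim_intensity * cfg.r_baseline * bump

    def simulate(self, beta: float | None = None,
                 store_rates: bool = False) -> NetworkRun:
        """Run the forward simulation; deterministic.

        ``beta`` overrides the configured STDP scaling (0 gives the
        symmetric control network).
        """
        cfg = self.config
        beta = cfg.beta if beta is None else float(beta)
        n, L, V, T = cfg.n_neurons, cfg.n_layers, cfg.n_velocities, cfg.n_steps
        kernels = build_weight_kernels(cfg, self.profile, beta=beta)
        kernels_fft = np.fft.rfft(kernels, axis=-1)          # (L-1, V, nf)
        decay, gain = cfg.decay, cfg.dt_ms / cfg.tau_m_ms
        delay = cfg.delay_steps

        # rates[l] is (V, n) for layers >= 1; layer 0 is (n,) broadcast
        r_layer0 = self.input_rates(0)
        rates = [np.full((V, n), cfg.r_baseline) for _ in range(L)]
        history: list[list[np.ndarray]] = [[] for _ in range(L)]
        baseline = np.full((V, n), cfg.r_baseline)

        rep = np.empty((L, n, T))
        g_all = np.empty((L, V, T))
        stored = np.empty((L, V, n, T)) if store_rates else None

        for t in range(T):
            r_layer0 = self.input_rates(t)
            rates[0] = np.broadcast_to(r_layer0, (V, n))
            for l in range(1, L):
                if delay == 0:
                    below = rates[l - 1]
                elif t - delay >= 0:
                    below = history[l - 1][t - delay]
                else:
                    below = baseline
                I = _correlate(kernels_fft[l - 1], below, n)
                rates[l] = rates[l] * decay + gain * I
            for l in range(L):
                history[l].append(rates[l] if l == 0 else rates[l].copy())
                g = velocity_weights(t, cfg, l + 1)
                g_all[l, :, t] = g
                profile_l = g @ rates[l]
                total = profile_l.sum()
                rep[l, :, t] = profile_l / total if total > 0 else profile_l
                if store_rates:
                    stored[l, :, :, t] = rates[l]
            # drop history beyond the delay horizon to bound memory
            if len(history[0]) > delay + 1 and delay > 0:
                for l in range(L):
                    history[l][t - delay - 1] = None  # type: ignore[call-overload]

        return NetworkRun(config=replace(cfg, beta=beta), beta=beta,
                          representation=rep,
                          stimulus_positions=cfg.stimulus_position(np.arange(T)),
                          g_weights=g_all, rates=stored)

    # ------------------------------------------------------------------ fit
    def fit(self, target_ratio: float = 0.36,
            betas: np.ndarray | None = None,
            delays_ms: np.ndarray | None = None) -> "NetworkFit":
        """Grid search over (t_delay, beta) matching the target ratio."""
        return fit_grid(self.config, target_ratio=target_ratio, betas=betas,
                        delays_ms=delays_ms, profile=self.profile)


def extrapolation_magnitude(run: NetworkRun, control: NetworkRun,
                            step: int = -1,
                            min_layer: int = 2) -> tuple[float, np.ndarray]:
    """Extrapolation magnitude of a run against its ``beta = 0`` control.

    Per layer, the ratio of the (signed, circular) distance from the
    control peak — the empirical No-Compensation locus — to the run's peak,
    over the distance from the control peak to the real-time stimulus
    position (Full Compensation). Returns ``(mean over layers >=
    min_layer, per-layer ratios)``; a control peak coinciding with the true
    position makes the ratio undefined and raises ``ValueError``.
    """
    if run.config.n_layers != control.config.n_layers:
        raise ValueError("run and control differ in depth")
    peaks = run.peak_positions(step)
    ctrl = control.peak_positions(step)
    true_pos = run.stimulus_positions[step]
    num = _wrap_unit(peaks - ctrl)
    den = _wrap_unit(true_pos - ctrl)
    ratios = np.full(run.config.n_layers, np.nan)
    for l in range(min_layer - 1, run.config.n_layers):
        if abs(den[l]) < 1e-6:
            raise ValueError(
                f"layer {l + 1}: control peak sits at the true position; "
                "extrapolation ratio undefined")
        ratios[l] = num[l] / den[l]
    mean = float(ratios[min_layer - 1:].mean())
    return mean, ratios


@dataclass
class NetworkFit:
    """Grid-search fit of (t_delay, beta) to a target extrapolation ratio."""

    delays_ms: np.ndarray
    betas: np.ndarray
    magnitudes: np.ndarray            # (n_delays, n_betas)
    target_ratio: float
    best_delay_ms: float
    best_beta: float
    best_magnitude: float

    def best_in_row(self, delay_ms: float) -> tuple[float, float]:
        """(beta, magnitude) best matching the target at a fixed delay."""
        row = int(np.argmin(np.abs(self.delays_ms - delay_ms)))
        j = int(np.argmin(np.abs(self.magnitudes[row] - self.target_ratio)))
        return float(self.betas[j]), float(self.magnitudes[row, j])

    def summary(self) -> str:
        lines = [
            "STDP network extrapolation-magnitude fit",
            f"  target ratio: {self.target_ratio:.3f}",
            f"  delays (ms): {np.array2string(self.delays_ms, precision=1)}",
            f"  beta grid: [{self.betas[0]:.2f} .. {self.betas[-1]:.2f}] "
            f"({self.betas.size} values)",
            f"  best fit: t_delay = {self.best_delay_ms:.0f} ms, "
            f"beta = {self.best_beta:.2f}, magnitude = {self.best_magnitude:.3f}",
        ]
        return "\n".join(lines)


def fit_grid(config: NetworkConfig, target_ratio: float = 0.36,
             betas: np.ndarray | None = None,
             delays_ms: np.ndarray | None = None,
             profile: STDPShiftProfile | None = None) -> NetworkFit:
    """Sweep (t_delay, beta), measuring the extrapolation magnitude of each.

    Every grid cell runs the full simulation; each delay row gets its own
    ``beta = 0`` control defining the No-Compensation locus. The best cell
    minimises ``|magnitude - target_ratio|``.
    """
    betas = np.round(np.arange(0.10, 2.0001, 0.05), 4) if betas is None \
        else np.asarray(betas, dtype=float)
    delays_ms = np.array([config.t_delay_ms]) if delays_ms is None \
        else np.asarray(delays_ms, dtype=float)
    magnitudes = np.empty((delays_ms.size, betas.size))
    for di, delay in enumerate(delays_ms):
        cfg = replace(config, t_delay_ms=float(delay))
        net = ExtrapolationNetwork(cfg, profile)
        control = net.simulate(beta=0.0)
        for bi, beta in enumerate(betas):
            run = net.simulate(beta=float(beta))
            magnitudes[di, bi], _ = extrapolation_magnitude(run, control)
    flat = np.argmin(np.abs(magnitudes - target_ratio))
    di, bi = np.unravel_index(flat, magnitudes.shape)
    return NetworkFit(delays_ms=delays_ms, betas=betas, magnitudes=magnitudes,
                      target_ratio=target_ratio,
                      best_delay_ms=float(delays_ms[di]),
                      best_beta=float(betas[bi]),
                      best_magnitude=float(magnitudes[di, bi]))
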