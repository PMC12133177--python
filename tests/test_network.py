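"""Hierarchical STDP network: weights, dynamics and extrapolation metrics."""

import numpy as np
import pytest

from motionmap.network import (ExtrapolationNetwork, NetworkConfig,
                               STDPShiftProfile, build_base_shift_curve,
                               build_weight_kernels, dense_weight_matrix,
                               extrapolation_magnitude, fit_grid,
                               velocity_weights)


@pytest.fixture(scope="module")
def small_cfg():
    return NetworkConfig(n_neurons=100, n_steps=150)


@pytest.fixture(scope="module")
def small_net(small_cfg):
    return ExtrapolationNetwork(small_cfg)


# -- configuration ----------------------------------------------------------

def test_config_defaults_match_reference_table():
    cfg = NetworkConfig()
    assert cfg.n_layers == 5 and cfg.n_neurons == 1000
    assert cfg.n_velocities == 21
    assert cfg.sigma_w == pytest.approx(1 / 32)
    assert cfg.sigma_p == pytest.approx(1 / 32)
    assert cfg.r_baseline == 5.0 and cfg.stim_intensity == 20.0
    assert cfg.dt_ms == 1.0 and cfg.n_steps == 300
    assert cfg.t_integration_steps == 100
    assert cfg.tau_m_ms == 10.0 and cfg.t_delay_ms == 11.0
    assert cfg.sigma_g0 == 2.0 and cfg.sigma_gT == pytest.approx(1 / 8)
    assert np.allclose(np.diff(cfg.velocities), 0.2)


def test_config_validation():
    with pytest.raises(ValueError):
        NetworkConfig(n_neurons=0)
    with pytest.raises(ValueError):
        NetworkConfig(t_delay_ms=11.5, dt_ms=1.0)


# -- STDP shift profile -----------------------------------------------------

def test_base_curve_interpolation_odd_and_monotone():
    v = np.linspace(-2, 2, 21)
    prof = build_base_shift_curve(v, n_transitions=4)
    s = prof.shifts[0]
    # odd in velocity, zero at v = 0
    np.testing.assert_allclose(s, -s[::-1], atol=1e-15)
    assert s[10] == 0.0
    # monotone magnitude for monotone anchors
    mags = -s[11:]                         # positive-velocity magnitudes
    assert np.all(np.diff(mags) >= 0)
    # linear interpolation between anchors: value at 1.5 cycles/s
    prof2 = build_base_shift_curve(np.array([1.5]), 1,
                                   anchor_velocities=(1.0, 2.0),
                                   anchor_shifts=(0.008, 0.011))
    assert prof2.shifts[0, 0] == pytest.approx(-(0.008 + 0.011) / 2)


def test_layer_scales_validation():
    with pytest.raises(ValueError):
        build_base_shift_curve(np.linspace(-2, 2, 5), 4, layer_scales=[1.0])


# -- weights ----------------------------------------------------------------

def test_beta_zero_weights_are_symmetric(small_cfg, small_net):
    kernels = build_weight_kernels(small_cfg, small_net.profile, beta=0.0)
    np.testing.assert_allclose(kernels.sum(axis=-1), 1.0, atol=1e-12)
    k = kernels[0, 0]
    # symmetry about the neuron's own position: k[m] == k[-m]
    np.testing.assert_allclose(k[1:], k[1:][::-1], atol=1e-12)


def test_zero_velocity_subpopulation_never_shifts(small_cfg, small_net):
    i0 = small_cfg.n_velocities // 2
    assert small_cfg.velocities[i0] == 0.0
    k_any = build_weight_kernels(small_cfg, small_net.profile, beta=1.7)
    k_none = build_weight_kernels(small_cfg, small_net.profile, beta=0.0)
    np.testing.assert_allclose(k_any[:, i0], k_none[:, i0], atol=1e-12)


def test_integer_shift_rotates_weight_rows(small_cfg):
    n = small_cfg.n_neurons
    shift_bins = 3
    prof = STDPShiftProfile(
        shifts=np.full((small_cfg.n_layers - 1, small_cfg.n_velocities),
                       shift_bins / n),
        velocities=small_cfg.velocities)
    k0 = build_weight_kernels(small_cfg, prof, beta=0.0)[0, 0]
    k3 = build_weight_kernels(small_cfg, prof, beta=1.0)[0, 0]
    np.testing.assert_allclose(k3, np.roll(k0, shift_bins), atol=1e-12)


def test_banded_kernels_match_dense_matrices(small_cfg, small_net):
    """Banded (truncated) weights reproduce dense rates to < 1e-6."""
    from dataclasses import replace

    rng = np.random.default_rng(0)
    r = rng.uniform(1.0, 10.0, small_cfg.n_neurons)
    dense_cfg = replace(small_cfg, banded=False)
    kd = build_weight_kernels(dense_cfg, small_net.profile, beta=0.6)
    kb = build_weight_kernels(small_cfg, small_net.profile, beta=0.6)
    for l in range(2):
        for vi in (0, 10, 20):
            W = dense_weight_matrix(kd[l, vi])
            np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)
            expect = W @ r
            got = np.fft.irfft(np.fft.rfft(r) * np.conj(np.fft.rfft(kb[l, vi])),
                               n=small_cfg.n_neurons)
            assert np.abs(got - expect).max() < 1e-6


# -- dynamics ---------------------------------------------------------------

def test_leaky_update_decay_and_fixed_point(small_cfg):
    decay = small_cfg.decay
    gain = small_cfg.dt_ms / small_cfg.tau_m_ms
    # homogeneous decay
    r = 8.0
    for _ in range(5):
        r = r * decay
    assert r == pytest.approx(8.0 * np.exp(-5 * small_cfg.dt_ms
                                           / small_cfg.tau_m_ms))
    # one step from rest with input I -> (dt/tau) I
    assert 0.0 * decay + gain * 4.0 == pytest.approx(0.4)
    # fixed point under constant input after 10 tau
    I = 3.0
    r = 0.0
    for _ in range(int(10 * small_cfg.tau_m_ms / small_cfg.dt_ms)):
        r = r * decay + gain * I
    expect = gain * I / (1.0 - decay)
    assert abs(r - expect) / expect < 1e-4
    assert expect / I == pytest.approx(1.0508, abs=1e-4)


def test_velocity_weight_schedule():
    cfg = NetworkConfig(n_neurons=100)
    g0 = velocity_weights(0, cfg, layer=1)
    assert g0.sum() == pytest.approx(1.0)
    assert cfg.velocities[np.argmax(g0)] == 0.0
    # broad at onset
    assert g0.max() < 0.08
    # after integration (plus the layer's delay) weights centre on v_true
    step = cfg.t_integration_steps + 4 * cfg.delay_steps + 1
    g5 = velocity_weights(step, cfg, layer=5)
    assert cfg.velocities[np.argmax(g5)] == pytest.approx(
        cfg.stimulus_velocity)
    assert g5.max() > 0.5                       # narrow: sigma_gT = 1/8
    later = velocity_weights(step + 50, cfg, layer=5)
    np.testing.assert_allclose(later, g5, atol=1e-12)


def test_input_layer_peaks_at_stimulus(small_net):
    run = small_net.simulate(beta=0.6)
    cfg = small_net.config
    for t in (0, 60, 120):
        peak_bin = run.representation[0, :, t].argmax()
        expect = int(round(cfg.stimulus_position(t) * cfg.n_neurons)) \
            % cfg.n_neurons
        assert min(abs(peak_bin - expect),
                   cfg.n_neurons - abs(peak_bin - expect)) <= 1


def test_translation_equivariance(small_cfg):
    from dataclasses import replace

    net_a = ExtrapolationNetwork(replace(small_cfg, stimulus_start=0.5))
    net_b = ExtrapolationNetwork(replace(small_cfg, stimulus_start=0.75))
    ra = net_a.simulate(beta=0.6).representation
    rb = net_b.simulate(beta=0.6).representation
    shift = int(0.25 * small_cfg.n_neurons)
    np.testing.assert_allclose(np.roll(ra, shift, axis=1), rb, atol=1e-9)


def test_control_lag_grows_with_depth(small_net):
    """beta = 0: peaks fall progressively behind along the hierarchy."""
    run = small_net.simulate(beta=0.0)
    peaks = run.peak_positions(-1)
    true = run.stimulus_positions[-1]
    from motionmap.network import _wrap_unit
    lags = -np.asarray(_wrap_unit(peaks - true))    # positive = behind
    assert np.all(np.diff(lags) > 0)


# -- extrapolation magnitude and fit ---------------------------------------

def test_magnitude_anchor_cases(small_net):
    control = small_net.simulate(beta=0.0)
    m, ratios = extrapolation_magnitude(control, control)
    assert m == pytest.approx(0.0, abs=1e-12)
    run = small_net.simulate(beta=0.6)
    m2, _ = extrapolation_magnitude(run, control)
    assert 0.0 < m2 < 1.0


def test_magnitude_nondecreasing_in_beta(small_net):
    control = small_net.simulate(beta=0.0)
    mags = [extrapolation_magnitude(small_net.simulate(beta=b), control)[0]
            for b in (0.25, 0.5, 1.0, 1.5, 2.0)]
    assert np.all(np.diff(mags) > -1e-6)


def test_fit_grid_recovers_target(small_cfg):
    fit = fit_grid(small_cfg, target_ratio=0.3,
                   betas=np.arange(0.2, 2.01, 0.2))
    assert fit.magnitudes.shape == (1, 10)
    assert abs(fit.best_magnitude - 0.3) == np.abs(
        fit.magnitudes - 0.3).min()
    assert "best fit" in fit.summary()


def test_rates_storage_and_nonnegativity(small_cfg):
    net = ExtrapolationNetwork(small_cfg)
    run = net.simulate(beta=0.6, store_rates=True)
    assert run.rates.shape == (small_cfg.n_layers, small_cfg.n_velocities,
                               small_cfg.n_neurons, small_cfg.n_steps)
    assert np.all(run.rates >= 0.0)
    assert np.all(np.isfinite(run.rates))
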