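"""LDA posterior maps, point estimators and the latency-shift analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motionmap import (EvokedCascadeModel, centroid, fit_lda_bank, fwhm, peak,
                       posterior_map, recover_shift_ms, simulate_localizers,
                       simulate_motion, slope_interaction_test,
                       traintime_shift_map)
from motionmap.geometry import angular_difference
from motionmap.ldamap import PositionDistribution, recenter_posteriors

GRID = np.arange(40) * 9.0


# -- centroid ---------------------------------------------------------------

def brute_force_centroid(weights, angles_deg):
    """Independent oracle: direct complex sum."""
    w = np.asarray(weights, dtype=float)
    z = np.sum(w / w.sum() * np.exp(1j * np.deg2rad(angles_deg)))
    return np.rad2deg(np.angle(z)) % 360.0, np.abs(z)


def test_centroid_anchor_cases():
    w = np.zeros(40)
    w[10] = 1.0                        # 90 deg
    est = centroid(PositionDistribution(w, GRID))
    assert est.angle_deg == pytest.approx(90.0)
    assert est.certainty == pytest.approx(1.0)
    uniform = centroid(PositionDistribution(np.ones(40), GRID))
    assert uniform.degenerate and np.isnan(uniform.angle_deg)
    w = np.zeros(40)
    w[[0, 1, 39]] = [0.5, 0.25, 0.25]
    est = centroid(PositionDistribution(w, GRID))
    a, r = brute_force_centroid(w, GRID)
    assert float(np.abs(angular_difference(est.angle_deg, 0.0))) < 1e-9
    assert float(np.abs(angular_difference(est.angle_deg, a))) < 1e-9
    assert est.certainty == pytest.approx(r, abs=1e-12)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=100, deadline=None)
def test_centroid_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    w = rng.random(40)
    est = centroid(PositionDistribution(w, GRID))
    a, r = brute_force_centroid(w, GRID)
    assert float(np.abs(angular_difference(est.angle_deg, a))) < 1e-9
    assert est.certainty == pytest.approx(r, abs=1e-12)


@given(shift=st.integers(0, 39))
@settings(max_examples=40, deadline=None)
def test_centroid_and_peak_rotation_equivariance(shift):
    rng = np.random.default_rng(0)
    w = rng.random(40) ** 3
    base_c = centroid(PositionDistribution(w, GRID))
    base_p = peak(PositionDistribution(w, GRID))
    rolled = np.roll(w, shift)
    rot_c = centroid(PositionDistribution(rolled, GRID))
    rot_p = peak(PositionDistribution(rolled, GRID))
    expect = shift * 9.0
    assert float(np.abs(angular_difference(
        rot_c.angle_deg - base_c.angle_deg, expect))) < 1e-6
    assert float(np.abs(angular_difference(
        rot_p.angle_deg - base_p.angle_deg, expect))) < 1e-6


def test_centroid_all_zero_weights_error():
    with pytest.raises(ValueError):
        centroid(PositionDistribution(np.zeros(4), GRID[:4]))


# -- peak -------------------------------------------------------------------

def test_peak_cases():
    w = np.zeros(40)
    w[5] = 2.0
    est = peak(PositionDistribution(w, GRID))
    assert est.angle_deg == pytest.approx(45.0) and est.certainty == 2.0
    # bimodal with unequal modes -> larger mode
    w[20] = 1.5
    assert peak(PositionDistribution(w, GRID)).angle_deg == pytest.approx(45.0)
    # uniform -> flagged tie at smallest index
    tie = peak(PositionDistribution(np.ones(40), GRID))
    assert tie.degenerate and tie.angle_deg == 0.0


# -- FWHM -------------------------------------------------------------------

def test_fwhm_von_mises_matches_analytic():
    kappa = 4.0
    vm = np.exp(kappa * np.cos(np.deg2rad(GRID - 90.0)))
    vm /= vm.sum()
    got = fwhm(PositionDistribution(vm, GRID), chance=0.0)
    # analytic half width: exp(k cos x) = exp(k)/2 -> relative to chance=0
    half = np.exp(kappa) / 2.0
    hw = np.rad2deg(np.arccos(np.log(half) / kappa))
    assert got == pytest.approx(2 * hw, abs=9.0)


def test_fwhm_delta_and_flat():
    w = np.zeros(40)
    w[3] = 1.0
    assert fwhm(PositionDistribution(w, GRID)) <= 9.0
    assert np.isnan(fwhm(PositionDistribution(np.full(40, 0.025), GRID)))


def test_fwhm_wraps_across_zero():
    vm = np.exp(5.0 * np.cos(np.deg2rad(GRID - 0.0)))
    vm /= vm.sum()
    rolled = np.roll(vm, 20)            # peak at 180 deg, no seam crossing
    assert fwhm(PositionDistribution(vm, GRID), chance=0.0) == pytest.approx(
        fwhm(PositionDistribution(rolled, GRID), chance=0.0), abs=1e-9)


# -- LDA bank and posterior maps -------------------------------------------

def test_bank_posteriors_concentrate_on_true_class(geom, localizers, bank):
    pmap = posterior_map(bank, _as_motionless(localizers),
                         train_window_ms=(105.0, 125.0), decim=1,
                         test_window_ms=(110.0, 120.0))
    probs = pmap.probabilities            # (trials, times, 40)
    np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-9)
    picked = probs.mean(axis=1).argmax(axis=1)
    agreement = (picked == localizers.positions).mean()
    assert agreement > 0.5                # 40-way problem, chance 0.025


def _as_motionless(localizers):
    """Reuse localizer epochs as test epochs (no trajectory needed)."""
    return localizers


def test_bank_uniform_posteriors_on_pure_noise(geom):
    model = EvokedCascadeModel(stage_amplitudes=(0.0,) * 4, noise_sd=1.0)
    loc = simulate_localizers(geom, model, n_reps=5, seed=31, sfreq=125.0)
    bank = fit_lda_bank(loc, [115.0], geometry=geom)
    fresh = simulate_localizers(geom, model, n_reps=2, seed=32, sfreq=125.0)
    post = bank.posteriors(fresh, 0, np.array([fresh.time_index(115.0)]))
    assert post.mean() == pytest.approx(0.025, abs=1e-12)
    # uniform in expectation: per-class averages over trials sit at chance
    per_class = post.mean(axis=(0, 1))
    assert np.abs(per_class - 0.025).mean() < 0.01
    assert np.abs(per_class - 0.025).max() < 0.03


def test_bank_handles_duplicate_trials(geom):
    model = EvokedCascadeModel(noise_sd=0.0)
    loc = simulate_localizers(geom, model, n_reps=2, seed=33, sfreq=125.0)
    # exact duplicates -> degenerate within-class covariance
    bank = fit_lda_bank(loc, [115.0], geometry=geom)
    assert len(bank.models) == 1


def test_bank_missing_class_errors(geom, localizers):
    subset = localizers.select_trials(np.flatnonzero(localizers.positions != 7))
    with pytest.raises(ValueError):
        fit_lda_bank(subset, [115.0], geometry=geom)


def test_posterior_map_single_model_window_equals_model(bank, motion):
    one = posterior_map(bank, motion, train_window_ms=(75.0, 75.0), decim=8)
    direct = bank.posteriors(motion, 0,
                             np.arange(0, motion.n_samples, 8))
    np.testing.assert_allclose(one.probabilities, direct)


def test_recentering_maps_truth_to_bin_zero():
    # single-trial sanity: delta posterior at the true angle -> bin 0
    probs = np.zeros((1, 1, 40))
    probs[0, 0, 13] = 1.0
    rec = recenter_posteriors(probs, np.array([[13 * 9.0]]), ["cw"], 40)
    assert rec[0, 0].argmax() == 0
    rec = recenter_posteriors(probs, np.array([[13 * 9.0]]), ["ccw"], 40)
    assert rec[0, 0].argmax() == 0
    # mass sums preserved under fractional shifts
    rng = np.random.default_rng(2)
    probs = rng.random((2, 3, 40))
    probs /= probs.sum(axis=-1, keepdims=True)
    rec = recenter_posteriors(probs, rng.uniform(0, 360, (2, 3)),
                              ["cw", "ccw"], 40)
    np.testing.assert_allclose(rec.sum(axis=-1), 1.0, atol=1e-9)


def test_rotation_equivariance_end_to_end(geom):
    """Rotating all stimulus positions by k bins rotates the map by k bins."""
    quiet = EvokedCascadeModel(noise_sd=0.0)
    loc = simulate_localizers(geom, quiet, n_reps=2, seed=34, sfreq=125.0,
                              shuffle=False)
    k = 7
    rotated = loc.copy()
    rotated.events["position"] = (loc.positions + k) % 40
    rotated.events["angle"] = geom.angle_of(rotated.events["position"])
    bank = fit_lda_bank(loc, [115.0], geometry=geom)
    bank_rot = fit_lda_bank(rotated, [115.0], geometry=geom)
    t = np.array([loc.time_index(115.0)])
    post = bank.posteriors(loc, 0, t)
    post_rot = bank_rot.posteriors(loc, 0, t)
    np.testing.assert_allclose(post_rot, np.roll(post, k, axis=-1), atol=1e-6)


# -- training-time shift map and regression --------------------------------

@pytest.fixture(scope="module")
def shift_maps(geom, localizers, bank, motion):
    actual = traintime_shift_map(bank, motion, test_window_ms=(-900.0, 0.0),
                                 decim=4, geometry=geom)
    return actual


def test_shift_map_rows_are_distributions(shift_maps):
    np.testing.assert_allclose(shift_maps.map.sum(axis=1), 1.0, atol=1e-9)
    est = shift_maps.estimates
    assert (est["train_time_ms"].diff().dropna() == 15.0).all()


def test_null_shift_recovered_near_zero(shift_maps, geom):
    v = abs(geom.velocity_deg_s) / 1000.0
    delta = recover_shift_ms(shift_maps.estimates, v)
    assert abs(delta) < 15.0


def test_injected_shift_recovered(geom, localizers, bank):
    model = EvokedCascadeModel(topography_seed=0).with_shift(50.0)
    mot = simulate_motion(geom, model, n_trials=24, seed=41,
                          reversal_prob=0.0, lock="offset",
                          tmin_ms=-1000.0, tmax_ms=100.0)
    sm = traintime_shift_map(bank, mot, test_window_ms=(-900.0, 0.0),
                             decim=4, geometry=geom)
    v = abs(geom.velocity_deg_s) / 1000.0
    assert recover_shift_ms(sm.estimates, v) == pytest.approx(50.0, abs=15.0)
    # centroid substitution keeps the qualitative ordering (S2-style check)
    assert recover_shift_ms(sm.estimates, v, estimator="peak") > \
        recover_shift_ms(shiftless_table(sm), v, estimator="peak") - 60.0


def shiftless_table(sm):
    est = sm.estimates.copy()
    est["peak_deg"] = est["no_comp_deg"]
    est["peak_height"] = 1.0
    return est


def test_interaction_identical_inputs_is_null(shift_maps):
    res = slope_interaction_test(shift_maps.estimates, shift_maps.estimates)
    assert res.interaction_coef == pytest.approx(0.0, abs=1e-9)
    assert res.interaction_p > 0.99


def test_interaction_sign_matches_progressive_shift(geom, localizers, bank,
                                                    shift_maps):
    model = EvokedCascadeModel(topography_seed=0,
                               stage_shift_ms=(10.0, 40.0, 70.0, 100.0))
    mot = simulate_motion(geom, model, n_trials=24, seed=42,
                          reversal_prob=0.0, lock="offset",
                          tmin_ms=-1000.0, tmax_ms=100.0)
    sm = traintime_shift_map(bank, mot, test_window_ms=(-900.0, 0.0),
                             decim=4, geometry=geom)
    res = slope_interaction_test(sm.estimates, shift_maps.estimates)
    # actual slope shallower than control -> negative interaction for the
    # synthetic reference level (negative = actual slope shallower)
    assert res.interaction_coef < 0
    assert res.interaction_p < 0.05


def test_doubling_velocity_doubles_control_slope():
    """Kinematic scaling of the No-Compensation locus."""
    t = np.arange(75.0, 391.0, 15.0)
    for v, expect in ((0.36, -0.36), (0.72, -0.72)):
        est = pd.DataFrame({
            "train_time_ms": t, "peak_deg": -v * t, "peak_height": 1.0,
            "centroid_deg": -v * t, "certainty": 1.0, "no_comp_deg": -v * t,
        })
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.lstsq(X, est["peak_deg"], rcond=None)[0]
        assert beta[1] == pytest.approx(expect, abs=1e-9)
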