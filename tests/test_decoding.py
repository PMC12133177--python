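"""Circular decoding: score properties, CV analyses, generalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motionmap import (EvokedCascadeModel, crossval_timecourse, decoding_score,
                       frequency_decoding, searchlight,
                       sequential_generalization, simulate_localizers,
                       temporal_generalization)
from motionmap.decoding import stratified_folds
from motionmap.preprocess import morlet_power


# -- decoding score ---------------------------------------------------------

def test_score_anchor_values():
    actual = np.arange(0.0, 360.0, 1.0)
    assert decoding_score(actual, actual) == pytest.approx(1.0)
    assert decoding_score(actual + 90.0, actual) == pytest.approx(0.0)
    assert decoding_score(actual - 90.0, actual) == pytest.approx(0.0)
    assert decoding_score(actual + 180.0, actual) == pytest.approx(-1.0)


@given(rot=st.floats(-720, 720, allow_nan=False))
@settings(max_examples=50, deadline=None)
def test_score_invariant_to_global_rotation(rot):
    rng = np.random.default_rng(0)
    actual = rng.uniform(0, 360, 50)
    predicted = actual + rng.normal(0, 30, 50)
    s0 = decoding_score(predicted, actual)
    s1 = decoding_score(predicted + rot, actual + rot)
    assert s1 == pytest.approx(s0, abs=1e-9)


def test_score_strictly_decreasing_in_error():
    actual = np.zeros(100)
    errors = np.linspace(0, 180, 19)
    scores = [decoding_score(actual + e, actual) for e in errors]
    assert np.all(np.diff(scores) < 0)


def test_score_chance_under_uniform_predictions():
    rng = np.random.default_rng(1)
    n = 100_000
    s = decoding_score(rng.uniform(0, 360, n), rng.uniform(0, 360, n))
    assert abs(s) < 0.01


def test_score_rejects_empty_or_mismatched():
    with pytest.raises(ValueError):
        decoding_score([], [])
    with pytest.raises(ValueError):
        decoding_score([0.0, 1.0], [0.0])


# -- folds ------------------------------------------------------------------

def test_stratified_folds_cover_all_positions():
    positions = np.repeat(np.arange(10), 5)
    folds = stratified_folds(positions, 5, seed=0)
    assert sorted(np.concatenate(folds)) == list(range(50))
    for fold in folds:
        assert set(positions[fold]) == set(range(10))


def test_stratified_folds_missing_position_errors():
    positions = np.repeat(np.arange(10), 3)      # 3 reps < 5 folds
    with pytest.raises(ValueError):
        stratified_folds(positions, 5, seed=0)


# -- CV timecourse and TGM --------------------------------------------------

@pytest.fixture(scope="module")
def crisp_localizers(geom):
    """Low-noise localizers for fast, clean decoding checks."""
    model = EvokedCascadeModel(noise_sd=0.1, topography_seed=2)
    return simulate_localizers(geom, model, n_reps=5, seed=21, sfreq=125.0,
                               tmin_ms=-200.0, tmax_ms=400.0)


def test_timecourse_high_at_stage_latency_low_before_onset(crisp_localizers):
    times, scores = crossval_timecourse(crisp_localizers, seed=0, decim=2)
    pre = scores[times < 50.0]
    at_stage = scores[(times >= 100.0) & (times <= 140.0)]
    assert np.abs(pre).max() < 0.15
    assert at_stage.max() > 0.8


def test_timecourse_chance_with_permuted_labels(crisp_localizers):
    rng = np.random.default_rng(3)
    shuffled = crisp_localizers.copy()
    perm = rng.permutation(shuffled.n_trials)
    shuffled.events["position"] = shuffled.events["position"].to_numpy()[perm]
    shuffled.events["angle"] = shuffled.events["angle"].to_numpy()[perm]
    times, scores = crossval_timecourse(shuffled, seed=0, decim=4)
    assert np.abs(scores.mean()) < 0.05


def test_tgm_diagonal_matches_timecourse_and_stages_do_not_generalize(
        crisp_localizers):
    sub = crisp_localizers.crop(50.0, 400.0)
    gm = temporal_generalization(sub, seed=0, decim=2)
    times, scores = crossval_timecourse(sub, seed=0, decim=2)
    np.testing.assert_allclose(gm.diagonal(), scores, atol=1e-12)
    # train at stage 1 (~115 ms), test at stage 3 (~265 ms): orthogonal
    # topographies mean near-zero cross-stage generalization
    i = int(np.argmin(np.abs(gm.train_times - 115.0)))
    j = int(np.argmin(np.abs(gm.train_times - 265.0)))
    assert gm.scores[i, i] > 0.8
    assert abs(gm.scores[i, j]) < 0.15
    assert abs(gm.scores[j, i]) < 0.15


# -- searchlight ------------------------------------------------------------

def test_searchlight_localizes_posterior_information(geom):
    model = EvokedCascadeModel(noise_sd=0.3, topography_seed=4,
                               n_channels=16, posterior_fraction=0.5)
    loc = simulate_localizers(geom, model, n_reps=5, seed=22, sfreq=125.0)
    scores = searchlight(loc, seed=0, decim=4)
    post = scores[loc.channels.posterior]
    ant = scores[~loc.channels.posterior]
    assert post.mean() > ant.mean() + 0.1


def test_searchlight_zeroed_isolated_channel_scores_chance(geom):
    model = EvokedCascadeModel(noise_sd=0.3, topography_seed=4)
    loc = simulate_localizers(geom, model, n_reps=5, seed=23, sfreq=125.0)
    loc.data[:, 0, :] = 1e-12  # kill one channel (tiny jitter for PCA rank)
    channels = loc.channels
    # isolate channel 0 in the adjacency
    adjacency = tuple(() if i == 0 else tuple(j for j in a if j != 0)
                      for i, a in enumerate(channels.adjacency))
    from motionmap.epochs import ChannelSet, EpochSet
    loc = EpochSet(data=loc.data, times=loc.times,
                   channels=ChannelSet(names=channels.names,
                                       positions=channels.positions,
                                       adjacency=adjacency,
                                       posterior=channels.posterior),
                   events=loc.events, sfreq=loc.sfreq)
    scores = searchlight(loc, seed=0, decim=4)
    assert abs(scores[0]) < 0.1


# -- frequency decoding -----------------------------------------------------

def test_frequency_decoding_peaks_at_carrier(geom):
    model = EvokedCascadeModel(noise_sd=0.1, topography_seed=5,
                               carrier_freq_hz=15.0)
    loc = simulate_localizers(geom, model, n_reps=5, seed=24, sfreq=125.0)
    tfr = morlet_power(loc, freqs=np.arange(5.0, 41.0, 5.0))
    freqs, times, scores = frequency_decoding(tfr, seed=0, decim=6)
    window = (times >= 75.0) & (times <= 250.0)
    best_freq = freqs[np.argmax(scores[:, window].mean(axis=1))]
    assert abs(best_freq - 15.0) <= 5.0
    # global channel gain leaves normalised-power scores unchanged
    tfr2 = morlet_power(loc, freqs=np.arange(5.0, 41.0, 5.0))
    tfr2.data *= 7.3
    _, _, scores2 = frequency_decoding(tfr2, seed=0, decim=6)
    np.testing.assert_allclose(scores2, scores, atol=1e-9)


def test_frequency_decoding_white_noise_at_chance(geom):
    model = EvokedCascadeModel(noise_sd=1.0, stage_amplitudes=(0.0,) * 4)
    loc = simulate_localizers(geom, model, n_reps=5, seed=25, sfreq=125.0)
    tfr = morlet_power(loc, freqs=np.array([10.0, 20.0]))
    _, _, scores = frequency_decoding(tfr, seed=0, decim=8)
    assert np.abs(scores).max() < 0.15


# -- sequential stimuli -----------------------------------------------------

def test_sequential_generalization_tracks_successive_stimuli(geom):
    model = EvokedCascadeModel(noise_sd=0.1, topography_seed=6)
    loc = simulate_localizers(geom, model, n_reps=6, seed=26, sfreq=125.0,
                              tmin_ms=-200.0, tmax_ms=1300.0, n_following=4)
    sg = sequential_generalization(loc, seed=0, decim=2, pca_var=None)
    # pick the stage-1 training time and locate the best test time per target
    ti = int(np.argmin(np.abs(sg.train_times - 115.0)))
    for k in range(3):
        row = sg.scores[k, ti]
        best_t = sg.test_times[np.argmax(row)]
        # stimulus k's stage-1 response peaks ~115 ms after its onset (k*200)
        assert abs(best_t - (k * 200.0 + 115.0)) <= 40.0
        assert row.max() > 0.5
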