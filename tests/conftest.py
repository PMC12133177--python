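"""Shared fixtures: one small synthetic session reused across test modules."""

import numpy as np
import pytest

from motionmap import (EvokedCascadeModel, StimulusGeometry, fit_lda_bank,
                       simulate_localizers, simulate_motion)


@pytest.fixture(scope="session")
def geom():
    return StimulusGeometry()


@pytest.fixture(scope="session")
def model():
    return EvokedCascadeModel(topography_seed=0)


@pytest.fixture(scope="session")
def localizers(geom, model):
    """200 localizer trials (5 per position) at 250 Hz."""
    return simulate_localizers(geom, model, n_reps=5, seed=11)


@pytest.fixture(scope="session")
def motion(geom, model):
    """24 offset-locked smooth-motion trials, no reversals."""
    return simulate_motion(geom, model, n_trials=24, seed=12,
                           reversal_prob=0.0, lock="offset",
                           tmin_ms=-1000.0, tmax_ms=100.0)


@pytest.fixture(scope="session")
def bank(localizers, geom):
    """LDA bank at 15 ms steps over the stage cascade."""
    return fit_lda_bank(localizers, np.arange(75.0, 391.0, 15.0),
                        geometry=geom)
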