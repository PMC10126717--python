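"""Shared fixtures: all data is generated programmatically at test time.

The 1 kSps fast generation path is used throughout the suite (the
decimation path from 30 kSps has its own dedicated tests); expensive
artifacts (calibration session, trained decoder) are session-scoped.
"""

import numpy as np
import pytest

import rpnidecode as rd
from rpnidecode import decoders as dc, signal_processing as sp, synth_emg as se


@pytest.fixture(scope="session")
def grip_config():
    return rd.default_config(se.FUNCTIONAL_GRIPS, sample_rate=1000)


@pytest.fixture(scope="session")
def calibration(grip_config):
    """Baseline (unit-scale) five-rep calibration recording of the four
    functional grips, with MAV features and per-bin labels."""
    sess = se.identity_session(grip_config.channels, seed=999)
    rec = se.generate_calibration_session(
        grip_config.movements, 5, grip_config.channels, sess, sample_rate=1000
    )
    feats = sp.compute_mav(rec.samples, sample_rate=1000)
    labs = sp.bin_labels(rec.labels, 1000)[: feats.n_bins]
    return rec, feats, labs


@pytest.fixture(scope="session")
def grip_model(grip_config, calibration):
    _, feats, labs = calibration
    return dc.train_hmm_nb(feats, labs, classes=list(grip_config.movements))


@pytest.fixture(scope="session")
def rest_stats(calibration):
    _, feats, labs = calibration
    return sp.rest_mav_stats(feats, labs)
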