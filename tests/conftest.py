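"""Shared fixtures: small synthetic cohorts, preprocessed and featurized once."""

from __future__ import annotations

import numpy as np
import pytest

from pdeeg.feature_table import extract_features
from pdeeg.montages import Montage, iowa_like_montage, unm_like_montage
from pdeeg.preprocessing import PreprocessConfig, preprocess_recordings
from pdeeg.synthetic import EffectProfile, generate_cohort, generate_recording

SHORT_CFG = PreprocessConfig(n_segments=3)


@pytest.fixture(scope="session")
def unm():
    return unm_like_montage()


@pytest.fixture(scope="session")
def iowa():
    return iowa_like_montage()


@pytest.fixture(scope="session")
def tiny_montage():
    """Four-channel montage for cheap generator-level checks."""
    return Montage("tiny4", ("Oz", "F4", "P8", "C3"), "REF")


@pytest.fixture(scope="session")
def clean_cohort(unm, iowa):
    """8+8 subjects, eyes open, 12 s, strong beta effect on Oz/P8, preprocessed."""
    effect = EffectProfile(target_channels=("Oz", "P8"), band="beta", power_ratio=4.0)
    cohort = generate_cohort(8, 8, unm, effect, eye_states=("open",),
                             duration_s=12.0, seed=42)
    return preprocess_recordings(cohort, unm, iowa, SHORT_CFG)


@pytest.fixture(scope="session")
def wavelet_table(clean_cohort):
    return extract_features(clean_cohort, "wavelet", SHORT_CFG)


@pytest.fixture(scope="session")
def single_recording(unm):
    return generate_recording("solo", "control", "open", unm, EffectProfile(),
                              duration_s=12.0, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
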