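"""Shared fixtures: short synthetic sessions sized for fast tests.

Phase durations are minutes-scale (the generator's defaults are the full
multi-day study schedule); all statistical structure — hazards, novelty
boost and decay, the novel-side factor — is unchanged.
"""

import numpy as np
import pytest

from kagenor import detection
from kagenor.core import CageLayout
from kagenor.synthetic import SessionSimConfig, simulate_session


SHORT = dict(habituation_s=600.0, sample_s=1800.0, retention_s=1800.0, test_s=1800.0)


def short_config(**overrides) -> SessionSimConfig:
    params = {**SHORT, "seed": 1234, **overrides}
    return SessionSimConfig(**params)


@pytest.fixture(scope="session")
def session():
    return simulate_session(short_config())


@pytest.fixture(scope="session")
def layout():
    return CageLayout()


@pytest.fixture(scope="session")
def features(session):
    return detection.extract_features(session.keypoints, session.layout)


@pytest.fixture(scope="session")
def rule_series(features):
    return detection.rule_classify(features)


def class_codes(series) -> np.ndarray:
    """0 = none, 1 = left, 2 = right, for accuracy computations."""
    return np.where(series.explore_left, 1, np.where(series.explore_right, 2, 0))
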