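"""Shared fixtures: small synthetic datasets reused across test modules.

Everything is generated at run time from fixed seeds; no stored data.
"""

from __future__ import annotations

import numpy as np
import pytest

from pgesdetect import (
    RFParams,
    SimulationParams,
    build_feature_matrix,
    simulate_dataset,
    simulate_recording,
)
from pgesdetect.emd import artifact_feature_map
from pgesdetect.features import EpochFeatureMatrix
from pgesdetect.preprocess import EMD_BAND, bandpass


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recording():
    """One artifact-free 60-s recording with the transition at 25.4 s."""
    params = SimulationParams(duration=60.0, pges_duration=25.4, seed=42)
    return simulate_recording(params, recording_id="fix0")


@pytest.fixture(scope="session")
def small_dataset():
    """Eight artifact-free 60-s recordings, transitions in 10–40 s."""
    return simulate_dataset(
        8,
        seed=11,
        base_params=SimulationParams(duration=60.0),
        pges_sampler=lambda rng: float(rng.uniform(10.0, 40.0)),
    )


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Concatenated feature matrix + artifact maps for `small_dataset`."""
    feats, maps = [], []
    for item in small_dataset:
        feats.append(build_feature_matrix(item.recording, item.annotation))
        maps.append(
            artifact_feature_map(bandpass(item.recording, *EMD_BAND), T=300)
        )
    return EpochFeatureMatrix.concat(feats), maps


@pytest.fixture(scope="session")
def fast_rf():
    return RFParams(n_trees=30, seed=0)
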