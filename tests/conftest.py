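import numpy as np
import pytest

from lmrgait.features import extract_features
from lmrgait.preprocess import PreprocessConfig, estimate_hip_angles
from lmrgait.synth_gait import ZERO_NOISE, generate_dataset, generate_trial
from lmrgait.imu_core import Terrain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def zero_noise_trial():
    """Noise-free ramp-ascent trial with ground truth (10 strides, BPM 110)."""
    return generate_trial(Terrain.RA, bpm=110, n_strides=10, noise=ZERO_NOISE)


def _features_from_dataset(bpm, strides, seed):
    trials, _ = generate_dataset(bpm=bpm, strides_per_terrain=strides, seed=seed)
    cfg = PreprocessConfig()
    feats = []
    for trial in trials:
        angles = estimate_hip_angles(trial, cfg)
        feats.extend(
            extract_features(
                angles, trial.terrain, trial.fs, trial.bpm, trial_id=trial.trial_id
            )
        )
    return feats


@pytest.fixture(scope="session")
def small_features():
    """Stride features from a small noisy dataset (5 terrains x 6 strides)."""
    return _features_from_dataset(bpm=110, strides=6, seed=3)


@pytest.fixture(scope="session")
def benchmark_features():
    """The end-to-end benchmark dataset: 5 terrains x 40 strides, BPM 110."""
    return _features_from_dataset(bpm=110, strides=40, seed=7)
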