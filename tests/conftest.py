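import numpy as np
import pytest

from breathnet import (CANCER, HEALTHY, FeatureVector, PreprocessConfig,
                       SimulatorParams, simulate_recording)


@pytest.fixture(scope="session")
def default_params() -> SimulatorParams:
    return SimulatorParams()


@pytest.fixture(scope="session")
def quiet_params() -> SimulatorParams:
    """Noise-free, drift-free simulator for exact structural checks."""
    return SimulatorParams(noise_sd=0.0, drift_sd=0.0)


@pytest.fixture(scope="session")
def default_config() -> PreprocessConfig:
    return PreprocessConfig()


@pytest.fixture(scope="session")
def default_recording(default_params):
    return simulate_recording(default_params, CANCER, subject_seed=42)


def make_feature_cohort(n_healthy, n_cancer, effect=2.0, noise=0.3,
                        n_features=6, seed=0):
    """Tiny synthetic feature vectors with a controllable class shift.

    A lightweight stand-in for the full simulate->featurize path where
    only the evaluation machinery is under test.
    """
    rng = np.random.default_rng(seed)
    features = []
    i = 0
    for label, n in ((HEALTHY, n_healthy), (CANCER, n_cancer)):
        shift = effect if label == CANCER else 0.0
        for _ in range(n):
            i += 1
            values = rng.normal(shift, 1.0, size=n_features) \
                + rng.normal(0, noise, size=n_features)
            features.append(FeatureVector(f"s{i:03d}", label, values))
    return features
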