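import numpy as np
import pandas as pd
import pytest

from pollensense.blocks import SensorBlock, SpectralBlock


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectral_block(X, wavelengths=None, classes=None):
    """Small helper to wrap a matrix as a SpectralBlock with dummy metadata."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if wavelengths is None:
        wavelengths = 900.0 + 3.0 * np.arange(p)
    meta = pd.DataFrame(
        {
            "sample_id": classes if classes is not None else ["s"] * n,
            "class_label": classes if classes is not None else ["s"] * n,
            "replicate_id": np.arange(n) + 1,
            "scan_index": 1,
        }
    )
    return SpectralBlock(np.asarray(wavelengths, dtype=float), X, meta)


def make_sensor_block(X, sessions=None, classes=None, sensor_ids=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    ids = sensor_ids if sensor_ids is not None else [f"S{j:02d}" for j in range(p)]
    meta = pd.DataFrame(
        {
            "sample_id": classes if classes is not None else ["s"] * n,
            "class_label": classes if classes is not None else ["s"] * n,
            "replicate_id": np.arange(n) + 1,
            "session_id": sessions if sessions is not None else [1] * n,
        }
    )
    return SensorBlock(ids, X, meta)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study, generated once per test session."""
    from pollensense.synthetic import generate_study

    return generate_study(seed=7)


def pytest_configure(config):
    # keep hypothesis deterministic in CI-less environments
    try:
        from hypothesis import settings, HealthCheck

        settings.register_profile(
            "det",
            deadline=None,
            derandomize=True,
            max_examples=40,
            suppress_health_check=[HealthCheck.too_slow],
        )
        settings.load_profile("det")
    except ImportError:
        pass
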