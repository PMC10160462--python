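import numpy as np
import pytest

from pomhsi.core import CameraProfile, make_camera_profile
from pomhsi.spectra import SpectrumTable


@pytest.fixture(scope="session")
def swir() -> CameraProfile:
    return make_camera_profile("swir")


@pytest.fixture(scope="session")
def vnir() -> CameraProfile:
    return make_camera_profile("vnir")


@pytest.fixture()
def tiny_profile() -> CameraProfile:
    """A small SWIR-like profile for fast cube-level tests."""
    return make_camera_profile("mini-swir", lambda_min=930.0, lambda_max=2500.0, n_bands=20)


@pytest.fixture()
def random_table() -> SpectrumTable:
    """A 20-sample, 6-band random reflectance table."""
    rng = np.random.default_rng(42)
    X = 0.2 + 0.6 * rng.random((20, 6))
    wl = np.linspace(1000.0, 1500.0, 6)
    labels = ["no_drop", "drop_60", "drop_100", "no_drop"] * 5
    return SpectrumTable(X, wl, labels, [f"s{i}" for i in range(20)])
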