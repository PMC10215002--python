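import numpy as np
import pytest

from seedperturb import DoseMap, PeakModel, evaluate_model
from seedperturb.profiles import DoseProfile, PerturbationProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def profile_from_model(model: PeakModel, half_extent_mm: float = 6.0, bin_mm: float = 0.1):
    """Noiseless perturbation profile sampled from a peak model."""
    n = int(round(half_extent_mm / bin_mm))
    x = np.arange(-n, n + 1) * bin_mm
    return PerturbationProfile(positions=x, delta=evaluate_model(model, x), bin=bin_mm)


def flat_profile(value: float = 100.0, half_extent_mm: float = 65.0, bin_mm: float = 0.5):
    n = int(round(half_extent_mm / bin_mm))
    x = np.arange(-n, n + 1) * bin_mm
    return DoseProfile(positions=x, values=np.full(x.size, value), bin=bin_mm)


def centered_map(values: np.ndarray, spacing: float = 1.0) -> DoseMap:
    """Map with the isocenter at the grid center."""
    ny, nx = values.shape
    return DoseMap(
        values=values,
        spacing=(spacing, spacing),
        origin=(-(nx - 1) / 2.0 * spacing, -(ny - 1) / 2.0 * spacing),
    )
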