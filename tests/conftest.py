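import numpy as np
import pytest

from asymstroke.imaging import SegmentationConfig
from asymstroke.phantom import PhantomSpec, default_lesion_spec, make_phantom

# Small fast head geometry for unit tests (full-size phantoms are exercised
# by the acceptance suite).
SMALL_HEAD = dict(
    grid_shape=(48, 56, 44),
    voxel_spacing=(2.0, 2.0, 2.0),
    brain_semi_axes=(35.0, 45.0, 32.0),
    skull_thickness_mm=5.0,
)

# Full-size head at 2 mm: used where the lesion must be a small fraction of
# the brain (percentile threshold behaviour).
STANDARD_HEAD = dict(
    grid_shape=(96, 112, 88),
    voxel_spacing=(2.0, 2.0, 2.0),
)

FAST_CONFIG = SegmentationConfig(iso_spacing=2.0)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(noise_sd=2.0, seed=7, **SMALL_HEAD)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def lesion_phantom():
    """Full-size phantom with a ~12 mL lesion and its ground truth."""
    spec = default_lesion_spec(12.0, seed=5, noise_sd=2.0, **STANDARD_HEAD)
    volume, truth = make_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def fast_config() -> SegmentationConfig:
    return FAST_CONFIG


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 1.0
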