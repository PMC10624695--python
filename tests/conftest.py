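import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracle_scattering

from octscatter import (
    FilterParams,
    Image,
    build_filter_bank,
    default_class_specs,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_bank():
    """32x32 bank at J=2, r=4 — cheap enough for brute-force cross-checks."""
    return build_filter_bank(FilterParams(shape=(32, 32), J=2, r=4))


@pytest.fixture(scope="session")
def bank128_J3r8():
    """The bank of the energy-capture setting: 128x128, J=3, r=8."""
    return build_filter_bank(FilterParams(shape=(128, 128), J=3, r=8))


@pytest.fixture(scope="session")
def oct_images_128():
    """20 seeded synthetic OCT-like images, 4 per class, 128x128."""
    images, _ = generate_dataset(default_class_specs(), 4, (128, 128), seed=1)
    return images


@pytest.fixture(scope="session")
def textured_fixtures(oct_images_128):
    """Three textured pixel grids for shift/deformation experiments."""
    return [im.pixels for im in oct_images_128[:3]]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
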