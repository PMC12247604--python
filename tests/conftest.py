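import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # reference_impl importable

from hemibias import NetworkLayout, generate_dataset, preset_spec
from hemibias.synthetic import LatentSpec


@pytest.fixture(scope="session")
def face_layout():
    return NetworkLayout.named("face")


@pytest.fixture(scope="session")
def scene_layout():
    return NetworkLayout.named("scene")


@pytest.fixture(scope="session")
def early_visual_layout():
    return NetworkLayout.named("early_visual")


@pytest.fixture(scope="session")
def face_spec():
    return preset_spec("face")


@pytest.fixture(scope="session")
def two_region_spec():
    return LatentSpec(regions=("A", "B"), alpha=0.5, beta=0.6, gamma=0.4,
                      sigma=1.0, rho_g=0.3)


@pytest.fixture(scope="session")
def small_face_dataset(face_spec):
    """3 subjects, two short runs, face regime."""
    return generate_dataset(face_spec, n_subjects=3, run_lengths=[120, 80],
                            seed=101, network="face")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
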