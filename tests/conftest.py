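import numpy as np
import pytest

from insolekit.layout import default_layout
from insolekit.maps import build_template
from insolekit.simulate import GaitParams, SubjectProfile, simulate_walk


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def template(layout):
    return build_template(layout, resolution_mm=2.0)


@pytest.fixture(scope="session")
def subject():
    return SubjectProfile(age=30, weight_kg=70.0, height_cm=175.0, subject_id="S00")


@pytest.fixture(scope="session")
def walk(subject):
    """One deterministic walking trial with its ground-truth sidecar."""
    return simulate_walk(subject, GaitParams(speed_m_s=1.2), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
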