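import numpy as np
import pytest

from thetatrain.cluster import build_adjacency
from thetatrain.io_brainvision import ChannelMontage, load_montage
from thetatrain.synthetic import (
    SimulationConfig,
    SubjectProfile,
    build_protocol,
)


@pytest.fixture(scope="session")
def montage62():
    return load_montage("standard-62")


@pytest.fixture(scope="session")
def adjacency62(montage62):
    return build_adjacency(montage62)


@pytest.fixture()
def toy_montage():
    """Four channels in a row, 30 mm apart: a chain under the 50 mm rule."""
    pos = np.array([[0, 0, 0], [30, 0, 0], [60, 0, 0], [90, 0, 0]], float)
    return ChannelMontage(["A", "B", "C", "D"], pos)


@pytest.fixture()
def small_protocol():
    return build_protocol(1, 6, 2, seed=11)


@pytest.fixture()
def profile():
    return SubjectProfile(
        subject_id="S01", group="rhTMS",
        baseline_dprime_manip=1.5, baseline_dprime_simple=2.5,
        slope_manip=0.2, slope_simple=0.0,
        theta_gain=8.0, entrainment_gain=2.0, seed=1234,
    )


@pytest.fixture()
def sham_profile():
    return SubjectProfile(
        subject_id="S02", group="sham",
        baseline_dprime_manip=1.5, baseline_dprime_simple=2.5,
        slope_manip=0.0, slope_simple=0.0,
        theta_gain=8.0, entrainment_gain=0.0, seed=4321,
    )


@pytest.fixture()
def sim_config():
    return SimulationConfig(sampling_rate=500.0, seed=99)
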