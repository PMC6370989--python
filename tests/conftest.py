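import numpy as np
import pytest

from mlcdose.fixtures import generate_fixtures
from mlcdose.machine import load_machine_profile
from mlcdose.materials import VoxelPhantom
from mlcdose.transport import SourceModel


@pytest.fixture(scope="session")
def machine():
    return load_machine_profile()


@pytest.fixture(scope="session")
def source_6mv():
    return SourceModel.default_6mv()


@pytest.fixture(scope="session")
def fixture_sets(tmp_path_factory):
    """One generated DICOM fixture set per kind, shared across tests."""
    root = tmp_path_factory.mktemp("dicom_fixtures")
    return {kind: generate_fixtures(kind, root / kind, seed=7)
            for kind in ("closed_mlc", "open_10x10", "water_imrt", "water_vmat")}


@pytest.fixture()
def small_water_phantom():
    """10 cm water cube around the isocenter (beam enters at y=-50 mm)."""
    shape = (25, 25, 25)
    spacing = (4.0, 4.0, 4.0)
    origin = (-48.0, -48.0, -48.0)
    return VoxelPhantom.water_box(shape, spacing, origin)


def rng(seed=0):
    return np.random.default_rng(seed)
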