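import numpy as np
import pytest

from ugidose.materials import REFERENCE_MATERIALS
from ugidose.phantom import VoxelPhantom, build_phantom
from ugidose.spectra import Spectrum


@pytest.fixture(scope="session")
def newborn():
    return build_phantom("newborn", 2.0)


@pytest.fixture(scope="session")
def newborn_coarse():
    return build_phantom("newborn", 4.0)


@pytest.fixture(scope="session")
def one_year():
    return build_phantom("one_year", 3.0)


@pytest.fixture(scope="session")
def water_slab():
    """10 cm water slab along +y inside a 20x15x20 cm air box."""
    labels = np.zeros((40, 30, 40), dtype=np.uint16)
    labels[:, 5:25, :] = 1
    return VoxelPhantom(
        labels=labels, voxel_cm=(0.5, 0.5, 0.5),
        origin_cm=(-10.0, -7.5, -10.0),
        regions={0: ("air", "air"), 1: ("water", "water")},
        materials={"air": REFERENCE_MATERIALS["air"],
                   "water": REFERENCE_MATERIALS["water"]},
        age_class="slab", height_cm=20.0)


@pytest.fixture(scope="session")
def mono60():
    return Spectrum(kvp=60.5, energies=np.array([60.0]),
                    weights=np.array([1.0]))
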