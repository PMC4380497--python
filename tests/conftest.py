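"""Shared fixtures: a small noiseless study and its inverted result.

Session scope keeps the expensive forward/inverse computations to one run;
tests must treat fixture arrays as read-only.
"""

import numpy as np
import pytest

from hydromap.mr_forward import default_protocol, simulate_protocol
from hydromap.phantom import FieldMaps, make_fields, make_phantom
from hydromap.water_mapping import map_water

SMALL_SHAPE = (48, 48, 48)
VOXEL_MM = 3.0


@pytest.fixture(scope="session")
def phantom48():
    return make_phantom(SMALL_SHAPE, seed=7, voxel_size_mm=VOXEL_MM)


@pytest.fixture(scope="session")
def fields48(phantom48):
    return make_fields(SMALL_SHAPE, amplitude=0.15, smoothness_mm=60.0,
                       seed=11, voxel_size_mm=VOXEL_MM,
                       brain_mask=phantom48.brain_mask)


@pytest.fixture(scope="session")
def flat_fields48():
    one = np.ones(SMALL_SHAPE)
    return FieldMaps(b1t=one.copy(), b1r=one.copy())


@pytest.fixture(scope="session")
def acq48_noiseless(phantom48, fields48):
    return simulate_protocol(phantom48, fields48,
                             default_protocol(noise_sd=0.0), seed=3)


@pytest.fixture(scope="session")
def acq48_noisy(phantom48, fields48):
    return simulate_protocol(phantom48, fields48,
                             default_protocol(noise_sd=0.02), seed=3)


@pytest.fixture(scope="session")
def result48_noiseless(phantom48, acq48_noiseless):
    return map_water(acq48_noiseless, phantom48.ventricle_mask,
                     phantom48.brain_mask, voxel_size_mm=VOXEL_MM)


@pytest.fixture(scope="session")
def result48_noisy(phantom48, acq48_noisy):
    return map_water(acq48_noisy, phantom48.ventricle_mask,
                     phantom48.brain_mask, voxel_size_mm=VOXEL_MM)
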