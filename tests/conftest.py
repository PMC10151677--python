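"""Shared fixtures: scenes, phantoms and small density grids are built
once per session (voxelization and MC transport dominate test time)."""

from __future__ import annotations

import numpy as np
import pytest

from expanderdose import artifacts, mc, phantoms
from expanderdose.beams import BeamSpec
from expanderdose.materials import build_spectrum_6mv


@pytest.fixture(scope="session")
def spectrum():
    return build_spectrum_6mv()


@pytest.fixture(scope="session")
def water_grid():
    """Small homogeneous water phantom (coarse, for fast MC checks)."""
    sp = np.array([4.0, 4.0, 4.0])
    shape = (40, 50, 40)
    origin = np.array([-80.0 + 2.0, 2.0, -80.0 + 2.0])
    density = np.ones(shape, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.uint8)
    return artifacts.DensityGrid(origin, sp, density, labels, ("water",), "truth")


@pytest.fixture(scope="session")
def small_beam(spectrum):
    return BeamSpec(spectrum, 10.0, 10.0, 100.0, 0.0, 1.0)


@pytest.fixture(scope="session")
def wax_scene():
    return phantoms.build_wax_slab_scene("DermaSpan")


@pytest.fixture(scope="session")
def wax_phantom(wax_scene):
    return phantoms.voxelize(wax_scene)


@pytest.fixture(scope="session")
def wax_ct(wax_phantom):
    return phantoms.synthesize_ct(wax_phantom)


@pytest.fixture(scope="session")
def allox2_wax_ct():
    ph = phantoms.voxelize(phantoms.build_wax_slab_scene("AlloX2"))
    return phantoms.synthesize_ct(ph)


@pytest.fixture(scope="session")
def breast_phantom_allox2():
    return phantoms.voxelize(phantoms.build_breast_scene("AlloX2"))
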