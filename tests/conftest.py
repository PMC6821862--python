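"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from optij.opt_sim import ArtifactSpec, Phantom, forward_project, make_phantom
from optij.stack_io import AcquisitionGeometry

BEAD_RADIUS_PX = 18.0  # orbit radius of the fiducial in the shared phantoms
BEAD_ROW = 16


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bead_phantom():
    """Single bright Gaussian bead orbiting 18 px off-axis, at the center row."""
    return make_phantom(
        "bead", (32, 64, 64),
        {"center": (BEAD_ROW, 31.5, 31.5 + BEAD_RADIUS_PX),
         "radius": 1.5, "value": 10.0})


@pytest.fixture(scope="session")
def geometry_96():
    return AcquisitionGeometry(n_projections=96, modality="eOPT")


@pytest.fixture(scope="session")
def clean_bead_stack(bead_phantom, geometry_96):
    """96 artifact-free projections of the bead phantom."""
    return forward_project(bead_phantom, geometry_96)


@pytest.fixture(scope="session")
def disks_phantom():
    """Thin slab of uniform disks (slice-reconstruction ground truth)."""
    return make_phantom("disks", (8, 64, 64), {"z_band": (3, 5)})


@pytest.fixture(scope="session")
def bead_disks_phantom():
    """Disks slab plus an off-axis bead at a separate row: trackable fiducial
    and structured slices in one stack."""
    disks = make_phantom("disks", (32, 64, 64), {"z_band": (4, 12)})
    bead = make_phantom(
        "bead", (32, 64, 64),
        {"center": (22, 31.5, 31.5 + BEAD_RADIUS_PX), "radius": 1.5,
         "value": 10.0})
    return Phantom(disks.voxels + bead.voxels)


def inscribed_mask(n):
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= c ** 2


def rmse(a, b, mask=None):
    d = np.asarray(a, float) - np.asarray(b, float)
    if mask is not None:
        d = d[mask]
    return float(np.sqrt(np.mean(d ** 2)))
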