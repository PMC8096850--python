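"""Shared fixtures: toy channels, helix trace, synthetic maps."""

import numpy as np
import pytest

from cptk.structio import Atom, AtomicModel, DensityMap
from cptk.synth import (
    cylinder_channel,
    helix_model,
    synth_map,
    two_waist_channel,
    FWHM_TO_SIGMA,
)


@pytest.fixture(scope="session")
def cylinder():
    """Constant-radius channel: construction radius 5, vdW 1.5 -> pore 3.5 A."""
    return cylinder_channel(5.0)


@pytest.fixture(scope="session")
def two_waist():
    """Channel with waists of accessible radius 2.0 and 2.6 A at z = -/+12."""
    return two_waist_channel()


@pytest.fixture(scope="session")
def helix():
    """30-residue C-alpha helix trace."""
    return helix_model()


@pytest.fixture(scope="session")
def helix_map(helix):
    """The helix blurred at 3.15 A map resolution (FWHM), 1 A voxels."""
    return synth_map(helix, voxel_size=1.0, blur_width=3.15 * FWHM_TO_SIGMA,
                     pad=8.0)


@pytest.fixture()
def ring14():
    """14 atoms of vdW 1.7 A equally spaced on a circle of radius 10 A."""
    atoms = [
        Atom("A", 1, "RNG", f"X{k}", "C",
             [10 * np.cos(2 * np.pi * k / 14), 10 * np.sin(2 * np.pi * k / 14),
              0.0],
             vdw=1.7)
        for k in range(14)
    ]
    return AtomicModel(atoms)


def blob_map(centers, sigma=2.0, shape=(40, 40, 40), voxel=1.0, amp=None):
    """Sum of isotropic Gaussian blobs on a grid (test helper)."""
    centers = np.asarray(centers, float)
    amp = np.ones(len(centers)) if amp is None else np.asarray(amp, float)
    ax = [np.arange(s) * voxel for s in shape]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    vals = np.zeros(shape)
    for c, a in zip(centers, amp):
        vals += a * np.exp(
            -((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
            / (2 * sigma**2)
        )
    return DensityMap(vals, voxel, np.zeros(3))


def polyline_distance(points, vertices):
    """Distance of each point to a piecewise-linear path (test helper)."""
    points = np.asarray(points, float)
    vertices = np.asarray(vertices, float)
    dmin = np.full(len(points), np.inf)
    for a, b in zip(vertices[:-1], vertices[1:]):
        ab = b - a
        t = np.clip(((points - a) @ ab) / (ab @ ab), 0.0, 1.0)
        proj = a + t[:, None] * ab
        dmin = np.minimum(dmin, np.linalg.norm(points - proj, axis=1))
    return dmin
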