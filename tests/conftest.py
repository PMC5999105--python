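"""Shared fixtures: synthetic meshes at several resolutions.

All geometry is generated programmatically; session scope keeps the
expensive dense femur to a single build.
"""

import numpy as np
import pytest

from icpps.surface_model import SurfaceModel
from icpps.synthetic_anatomy import FemurParams, generate_synthetic_femur


@pytest.fixture(scope="session")
def femur():
    """Default dense labeled femur (the study-condition model)."""
    return generate_synthetic_femur(FemurParams())


@pytest.fixture(scope="session")
def coarse_femur():
    """Low-density femur for brute-force-oracle comparisons (~4k vertices)."""
    return generate_synthetic_femur(FemurParams(vertex_density=0.1))


@pytest.fixture()
def tetra_model():
    """Minimal valid mesh: a regular tetrahedron."""
    v = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return SurfaceModel(v, f)


def make_plane_model(n: int = 21, spacing: float = 1.0) -> SurfaceModel:
    """Flat square z=0 grid mesh, (n x n) vertices."""
    xs = spacing * (np.arange(n) - (n - 1) / 2)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    v = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + 1
            c = a + n
            d = c + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    return SurfaceModel(v, np.array(faces))


def make_cylinder_model(
    radius: float = 15.0,
    length: float = 60.0,
    ring_spacing: float = 1.0,
    sectors: int = 24,
) -> SurfaceModel:
    """Open cylinder along +z with vertex rings every ``ring_spacing`` mm."""
    n_z = int(round(length / ring_spacing)) + 1
    theta = np.linspace(0, 2 * np.pi, sectors, endpoint=False)
    z = ring_spacing * np.arange(n_z)
    verts = np.array(
        [
            [radius * np.cos(t), radius * np.sin(t), zz]
            for zz in z
            for t in theta
        ]
    )
    faces = []
    for i in range(n_z - 1):
        for j in range(sectors):
            a = i * sectors + j
            b = i * sectors + (j + 1) % sectors
            c = a + sectors
            d = b + sectors
            faces.append([a, b, d])
            faces.append([a, d, c])
    return SurfaceModel(verts, np.array(faces))


@pytest.fixture()
def plane_model():
    return make_plane_model()


@pytest.fixture()
def cylinder_model():
    return make_cylinder_model()
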