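"""Procedural femur-like surface model with labeled anatomical regions.

Real registration studies use a CT-derived bone surface; this module
generates a stand-in with the geometric features that matter for
axis-constrained registration: a long cylinder-like shaft (the source of
axial ICP local minima), an offset spherical head with a greater
trochanter bulge proximally, and two epicondylar bulges distally.  All
meshes produced here are synthetic.

Construction: the surface is a radial function r(theta, z) about the z
axis — the union of a shaft cylinder and bump spheres, each star-shaped
with respect to the axis — sampled on a regular (z, theta) grid and
closed with end caps, which makes the mesh watertight by construction.
A small smooth pseudo-random radial roughness field (seeded) breaks the
perfect rotational symmetry of the shaft, as a real bone would.

Region labels emulate the accessibility map of an ultrasound-based
protocol: the posterior shaft sector and the articular surfaces (femoral
head, distal condylar surface) are inaccessible, everything else is
accessible, and three pre-registration disks (greater trochanter 30 mm
diameter, medial/lateral epicondyles 20 mm diameter) are marked around
anchor vertices, plus four optional midshaft disks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GenerationError, ParameterError
from .surface_model import SurfaceModel, principal_axis

__all__ = ["FemurParams", "generate_synthetic_femur"]


@dataclass(frozen=True)
class FemurParams:
    """Parameters of the synthetic femur (mm unless stated).

    Defaults are typical adult-femur dimensions so that mm-scale
    registration thresholds keep their clinical meaning.
    """

    shaft_length: float = 400.0
    shaft_radius: float = 15.0
    head_radius: float = 24.0
    neck_offset: float = 25.0
    trochanter_radius: float = 16.0
    condyle_radius: float = 20.0
    condyle_offset: float = 14.0
    vertex_density: float = 1.0  # vertices per mm^2 of shaft surface
    roughness_mm: float = 0.3
    #: vertex-position jitter as a fraction of the grid spacing; an
    #: irregular vertex distribution (like a CT-derived mesh) avoids the
    #: artificial grid-locking minima a perfectly regular sampling creates
    jitter: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "shaft_length",
            "shaft_radius",
            "head_radius",
            "neck_offset",
            "trochanter_radius",
            "condyle_radius",
            "condyle_offset",
            "vertex_density",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.roughness_mm < 0:
            raise ParameterError("roughness_mm must be non-negative")
        if not (0 <= self.jitter < 0.5):
            raise ParameterError("jitter must be in [0, 0.5)")


def _sphere_outer_radius(theta, z, center, radius):
    """Largest t such that (t cos(theta), t sin(theta), z) lies on the
    sphere |p - center| = radius; 0 where the ray misses the sphere.

    ``theta`` and ``z`` are same-shape arrays, evaluated elementwise.
    """
    cx, cy, cz = center
    b = cx * np.cos(theta) + cy * np.sin(theta)
    c = cx * cx + cy * cy + (z - cz) ** 2 - radius * radius
    disc = b * b - c
    hit = disc > 0
    root = np.where(hit, b + np.sqrt(np.where(hit, disc, 0.0)), 0.0)
    return np.maximum(root, 0.0)


def _roughness_field(theta, z, length, amplitude, rng):
    """Smooth periodic-in-theta radial perturbation with RMS ~= amplitude."""
    field = np.zeros(np.shape(theta))
    for k in range(1, 5):  # angular harmonics
        for l in range(1, 7):  # axial harmonics
            a = rng.normal()
            phi = rng.uniform(0, 2 * np.pi)
            psi = rng.uniform(0, 2 * np.pi)
            field += a * np.cos(2 * np.pi * l * z / length + psi) * np.cos(
                k * theta + phi
            )
    if amplitude == 0:
        return np.zeros(np.shape(theta))
    field *= amplitude / max(field.std(), 1e-12)
    return field


def generate_synthetic_femur(params: FemurParams = FemurParams()) -> SurfaceModel:
    """Build the labeled synthetic femur mesh.

    The shaft runs along +z from z=0 (distal) to z=shaft_length
    (proximal).  The head is offset toward +x (medial side), the greater
    trochanter toward -x (lateral).  Deterministic given ``params``
    (including ``seed``).

    Raises
    ------
    GenerationError
        If the vertex density is too low for every pre-registration disk
        to contain at least 10 vertices.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    L = params.shaft_length
    rs = params.shaft_radius

    spacing = 1.0 / np.sqrt(params.vertex_density)
    n_theta = max(int(round(2 * np.pi * rs / spacing)), 8)
    n_z = max(int(round(L / spacing)) + 1, 4)
    theta_1d = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    z_1d = np.linspace(0.0, L, n_z)
    theta = np.broadcast_to(theta_1d[None, :], (n_z, n_theta)).copy()
    z = np.broadcast_to(z_1d[:, None], (n_z, n_theta)).copy()
    if params.jitter > 0:
        # irregular per-vertex sampling, as in a segmented CT mesh; end
        # rings keep their exact z so the caps stay planar
        d_theta = 2 * np.pi / n_theta
        d_z = L / (n_z - 1)
        theta += params.jitter * d_theta * rng.uniform(-1, 1, size=theta.shape)
        z[1:-1] += params.jitter * d_z * rng.uniform(-1, 1, size=z[1:-1].shape)

    head_center = np.array([params.neck_offset, 0.0, L - 0.8 * params.head_radius])
    troch_center = np.array([-rs - 2.0, 0.0, L - 12.0])
    cz = 0.6 * params.condyle_radius + 2.0
    med_condyle = np.array([params.condyle_offset, -4.0, cz])
    lat_condyle = np.array([-params.condyle_offset, -4.0, cz])

    r = np.full((n_z, n_theta), rs)
    for center, radius in (
        (head_center, params.head_radius),
        (troch_center, params.trochanter_radius),
        (med_condyle, params.condyle_radius),
        (lat_condyle, params.condyle_radius),
    ):
        r = np.maximum(r, _sphere_outer_radius(theta, z, center, radius))
    r += _roughness_field(theta, z, L, params.roughness_mm, rng)

    # grid vertices + two cap centres
    xx = r * np.cos(theta)
    yy = r * np.sin(theta)
    verts = np.column_stack([xx.ravel(), yy.ravel(), z.ravel()])
    bottom_center = np.array([[0.0, 0.0, 0.0]])
    top_center = np.array([[0.0, 0.0, L]])
    vertices = np.vstack([verts, bottom_center, top_center])
    i_bottom = n_z * n_theta
    i_top = i_bottom + 1

    faces = _tube_faces(n_z, n_theta, i_bottom, i_top)
    model = SurfaceModel(vertices, faces)
    model.axis, model.axis_point = principal_axis(model)

    _label_regions(model, params, n_z, n_theta)
    return model


def _tube_faces(n_z, n_theta, i_bottom, i_top):
    iz = np.arange(n_z - 1)
    it = np.arange(n_theta)
    itp = (it + 1) % n_theta
    a = (iz[:, None] * n_theta + it[None, :]).ravel()
    b = (iz[:, None] * n_theta + itp[None, :]).ravel()
    c = ((iz + 1)[:, None] * n_theta + it[None, :]).ravel()
    d = ((iz + 1)[:, None] * n_theta + itp[None, :]).ravel()
    side = np.concatenate(
        [np.column_stack([a, b, d]), np.column_stack([a, d, c])]
    )
    ring0 = np.arange(n_theta)
    ringN = (n_z - 1) * n_theta + np.arange(n_theta)
    bottom = np.column_stack(
        [np.full(n_theta, i_bottom), (ring0 + 1) % n_theta, ring0]
    )
    top = np.column_stack(
        [np.full(n_theta, i_top), ringN, (n_z - 1) * n_theta + (ring0 + 1) % n_theta]
    )
    return np.vstack([side, bottom, top]).astype(np.int64)


def _label_regions(model: SurfaceModel, params: FemurParams, n_z, n_theta):
    v = model.vertices
    L = params.shaft_length
    n = len(v)
    theta_v = np.arctan2(v[:, 1], v[:, 0])

    head_center = np.array([params.neck_offset, 0.0, L - 0.8 * params.head_radius])

    inaccessible = np.zeros(n, dtype=bool)
    # posterior shaft sector (-y side) over the shaft span
    posterior = (np.abs(theta_v + np.pi / 2) < np.radians(50)) & (
        v[:, 2] > 0.12 * L
    ) & (v[:, 2] < 0.88 * L)
    inaccessible |= posterior
    # articular surfaces: femoral head, and the distal condylar surface
    inaccessible |= np.linalg.norm(v - head_center, axis=1) <= params.head_radius + 0.8
    inaccessible |= v[:, 2] < 8.0

    accessible = ~inaccessible
    acc_idx = np.flatnonzero(accessible)
    acc_v = v[acc_idx]

    # pre-registration anchors, chosen on the accessible surface
    proximal = acc_v[:, 2] > L - 60.0
    if not proximal.any():
        raise GenerationError("no accessible proximal vertices for trochanter anchor")
    troch_anchor = acc_idx[np.flatnonzero(proximal)[np.argmin(acc_v[proximal, 0])]]
    distal = acc_v[:, 2] < 50.0
    if not distal.any():
        raise GenerationError("no accessible distal vertices for epicondyle anchors")
    d_idx = np.flatnonzero(distal)
    med_anchor = acc_idx[d_idx[np.argmax(acc_v[distal, 0])]]
    lat_anchor = acc_idx[d_idx[np.argmin(acc_v[distal, 0])]]

    regions = {}
    taken = np.zeros(n, dtype=bool)
    for name, anchor, diameter in (
        ("pre_greater_trochanter", troch_anchor, 30.0),
        ("pre_medial_epicondyle", med_anchor, 20.0),
        ("pre_lateral_epicondyle", lat_anchor, 20.0),
    ):
        within = np.linalg.norm(v - v[anchor], axis=1) <= diameter / 2.0
        disk = np.flatnonzero(within & accessible & ~taken)
        if len(disk) < 10:
            raise GenerationError(
                f"pre-registration region {name!r} has only {len(disk)} vertices; "
                "increase vertex_density"
            )
        taken[disk] = True
        regions[name] = disk

    # optional midshaft disks (lateral -x, medial +x, anterior +y, posterior -y)
    mid = np.array([0.0, 0.0, L / 2.0])
    rs = params.shaft_radius
    for name, anchor_pt in (
        ("shaft_lateral", mid + [-rs, 0, 0]),
        ("shaft_medial", mid + [rs, 0, 0]),
        ("shaft_anterior", mid + [0, rs, 0]),
        ("shaft_posterior", mid + [0, -rs, 0]),
    ):
        disk = np.flatnonzero(np.linalg.norm(v - anchor_pt, axis=1) <= 10.0)
        regions[name] = disk

    regions["accessible"] = np.flatnonzero(accessible)
    regions["inaccessible"] = np.flatnonzero(inaccessible)
    model.region_labels = {k: np.asarray(ix, dtype=np.int64) for k, ix in regions.items()}
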