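"""Triangulated bone-surface container with accelerated closest-point queries.

The surface model plays the role of the pre-operative model (POM): the
known, dense triangulation of the bone that sparse intraoperative points
are registered to.  Closest-point queries come in two modes:

``vertex``
    nearest mesh *vertex* through a k-d tree — the classic choice for a
    dense CT-derived mesh, and the package default;
``triangle``
    exact nearest point on the *surface* (point-to-triangle projection),
    which removes the vertex-sampling bias on coarse meshes.

Region labels (accessible / inaccessible areas, pre-registration areas)
are stored as vertex-index sets and serialized in a JSON sidecar next to
the STL, since STL itself carries no attributes.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, ParameterError, StlParseError

__all__ = ["SurfaceModel", "read_stl", "write_stl", "closest_point", "principal_axis"]

PRE_REGISTRATION_REGIONS = (
    "pre_greater_trochanter",
    "pre_medial_epicondyle",
    "pre_lateral_epicondyle",
)


@dataclass
class SurfaceModel:
    """A triangulated surface with optional region labels and long axis.

    Attributes
    ----------
    vertices : (n, 3) ndarray, mm
    faces : (m, 3) int ndarray
        Vertex-index triples.
    region_labels : dict[str, ndarray]
        Region name -> sorted array of vertex indices.
    axis, axis_point : ndarray or None
        Unit distal-proximal axis and a point on it (set lazily by
        :func:`principal_axis` if absent).
    """

    vertices: np.ndarray
    faces: np.ndarray
    region_labels: dict = field(default_factory=dict)
    axis: np.ndarray | None = None
    axis_point: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or len(v) < 4:
            raise DegenerateGeometryError("mesh needs at least 4 vertices")
        if f.ndim != 2 or f.shape[1] != 3 or len(f) < 4:
            raise DegenerateGeometryError("mesh needs at least 4 triangular faces")
        if f.min() < 0 or f.max() >= len(v):
            raise DegenerateGeometryError("face indices out of range")
        self.vertices = v
        self.faces = f
        self.region_labels = {
            k: np.unique(np.asarray(ix, dtype=np.int64))
            for k, ix in self.region_labels.items()
        }
        for name, ix in self.region_labels.items():
            if len(ix) and (ix[0] < 0 or ix[-1] >= len(v)):
                raise ParameterError(f"region {name!r} has out-of-range indices")
        if self.axis is not None:
            a = np.asarray(self.axis, dtype=float)
            n = np.linalg.norm(a)
            if abs(n - 1.0) > 1e-9:
                a = a / n
            self.axis = a
        if self.axis_point is not None:
            self.axis_point = np.asarray(self.axis_point, dtype=float)
        self._vertex_tree = None
        self._centroid_tree = None
        self._tri_reach = None

    # -- cached acceleration structures ---------------------------------
    @property
    def vertex_tree(self) -> cKDTree:
        if self._vertex_tree is None:
            self._vertex_tree = cKDTree(self.vertices)
        return self._vertex_tree

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def _triangle_index(self):
        """k-d tree over face centroids plus each face's maximal reach
        (centroid-to-vertex distance), used to make triangle-mode
        queries exact without an R-tree."""
        if self._centroid_tree is None:
            tri = self.triangles
            centroids = tri.mean(axis=1)
            self._centroid_tree = cKDTree(centroids)
            self._tri_reach = float(
                np.linalg.norm(tri - centroids[:, None, :], axis=2).max()
            )
        return self._centroid_tree, self._tri_reach

    def region(self, name: str) -> np.ndarray:
        try:
            return self.region_labels[name]
        except KeyError:
            raise ParameterError(f"model has no region {name!r}") from None

    def region_centroid(self, name: str) -> np.ndarray:
        ix = self.region(name)
        if len(ix) == 0:
            raise ParameterError(f"region {name!r} is empty")
        return self.vertices[ix].mean(axis=0)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    # -- label sidecar ---------------------------------------------------
    def write_labels(self, path: str | Path) -> None:
        payload = {k: [int(i) for i in ix] for k, ix in self.region_labels.items()}
        Path(path).write_text(json.dumps(payload))

    def read_labels(self, path: str | Path) -> None:
        payload = json.loads(Path(path).read_text())
        self.region_labels = {
            k: np.unique(np.asarray(v, dtype=np.int64)) for k, v in payload.items()
        }
        for name, ix in self.region_labels.items():
            if len(ix) and (ix[0] < 0 or ix[-1] >= len(self.vertices)):
                raise ParameterError(f"region {name!r} has out-of-range indices")


# -- STL I/O -------------------------------------------------------------


def _validate_stl_bytes(path: Path) -> None:
    """Cheap structural validation so malformed files produce a parse
    error with a byte offset instead of garbage geometry."""
    data = path.read_bytes()
    if len(data) == 0:
        raise StlParseError("empty file", byte_offset=0)
    if data[:5] == b"solid" and b"facet" in data[:4096]:
        return  # ASCII dialect; leave detailed parsing to the loader
    if len(data) < 84:
        raise StlParseError(
            "binary STL truncated before triangle count", byte_offset=len(data)
        )
    (n_tri,) = struct.unpack("<I", data[80:84])
    expected = 84 + 50 * n_tri
    if len(data) != expected:
        raise StlParseError(
            f"binary STL declares {n_tri} triangles ({expected} bytes) "
            f"but file has {len(data)} bytes",
            byte_offset=min(len(data), expected),
        )


def read_stl(path: str | Path, labels_path: str | Path | None = None) -> SurfaceModel:
    """Read a binary or ASCII STL file into a :class:`SurfaceModel`.

    Duplicate vertices from the STL facet soup are merged by exact
    coordinate match.  If ``labels_path`` is given (or a ``.labels.json``
    sidecar sits next to the STL), region labels are loaded from it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_stl_bytes(path)
    try:
        mesh = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # pragma: no cover - loader-specific messages
        raise StlParseError(f"could not parse STL: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise DegenerateGeometryError(f"{path} contains no triangles")

    soup = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    # exact-coordinate merge of the facet soup
    unique, inverse = np.unique(soup, axis=0, return_inverse=True)
    faces = inverse[faces]

    model = SurfaceModel(unique, faces)
    if labels_path is None:
        default = Path(str(path).removesuffix(".stl") + ".labels.json")
        labels_path = default if default.exists() else None
    if labels_path is not None:
        model.read_labels(labels_path)
    return model


def write_stl(
    model: SurfaceModel,
    path: str | Path,
    ascii: bool = False,
    labels_path: str | Path | None = None,
) -> None:
    """Write the model as STL (binary by default, ASCII on request) and,
    when labels are present, a JSON region-label sidecar."""
    mesh = model.as_trimesh()
    data = trimesh.exchange.stl.export_stl_ascii(mesh) if ascii else \
        trimesh.exchange.stl.export_stl(mesh)
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)
    if model.region_labels:
        if labels_path is None:
            labels_path = str(path).removesuffix(".stl") + ".labels.json"
        # STL stores an unordered facet soup; a reader reconstructs the
        # vertex list in its own (sorted) order, so label indices must be
        # remapped to the ordering the written file will produce.
        reread = read_stl(path)
        _, idx = reread.vertex_tree.query(model.vertices)
        dist = np.linalg.norm(reread.vertices[idx] - model.vertices, axis=1)
        if dist.max() > 1e-3:
            raise StlParseError(
                "written STL does not reproduce the model vertices "
                f"(max deviation {dist.max():.3g} mm)"
            )
        remapped = SurfaceModel(
            reread.vertices,
            reread.faces,
            {k: idx[ix] for k, ix in model.region_labels.items()},
        )
        remapped.write_labels(labels_path)


# -- queries -------------------------------------------------------------


def closest_point(
    model: SurfaceModel, query: np.ndarray, mode: str = "vertex"
) -> tuple[np.ndarray, np.ndarray]:
    """Closest point(s) on the model for one or many query points.

    Parameters
    ----------
    query : (3,) or (n, 3) array
    mode : {"vertex", "triangle"}
        ``vertex`` returns the nearest mesh vertex (k-d tree search);
        ``triangle`` returns the exact nearest point on the surface.

    Returns
    -------
    (points, distances) with the same leading shape as ``query``.
    """
    q = np.atleast_2d(np.asarray(query, dtype=float))
    single = np.asarray(query).ndim == 1
    if mode == "vertex":
        dist, idx = model.vertex_tree.query(q)
        pts = model.vertices[idx]
    elif mode == "triangle":
        pts, dist = _closest_on_triangles(model, q)
    else:
        raise ParameterError(f"mode must be 'vertex' or 'triangle', got {mode!r}")
    if single:
        return pts[0], float(dist[0])
    return pts, dist


def _closest_on_triangles(model: SurfaceModel, q: np.ndarray):
    """Exact point-to-surface projection.

    Strategy: the distance to the face whose centroid is nearest gives an
    upper bound d0; every face whose closest point could beat it has its
    centroid within d0 + reach, where reach is the largest
    centroid-to-vertex distance in the mesh.  Those candidates are then
    resolved exactly with point-to-triangle projection.
    """
    tree, reach = model._triangle_index()
    tri = model.triangles
    out_pts = np.empty_like(q)
    out_dist = np.empty(len(q))
    _, seed_face = tree.query(q)
    for i, (p, f0) in enumerate(zip(q, seed_face)):
        c0, = trimesh.triangles.closest_point(tri[f0][None], p[None])
        d0 = np.linalg.norm(c0 - p)
        cand = tree.query_ball_point(p, d0 + reach + 1e-9)
        cand_tri = tri[cand]
        pts = trimesh.triangles.closest_point(
            cand_tri, np.broadcast_to(p, (len(cand), 3))
        )
        d = np.linalg.norm(pts - p, axis=1)
        j = int(np.argmin(d))
        out_pts[i] = pts[j]
        out_dist[i] = d[j]
    return out_pts, out_dist


def principal_axis(model: SurfaceModel) -> tuple[np.ndarray, np.ndarray]:
    """Long axis of the mesh by principal component analysis.

    Returns the first principal component of the vertex cloud (unit norm)
    and the vertex centroid as a point on the axis.  The sign is fixed so
    the z component is non-negative (ties broken toward +x, then +y) so
    downstream perturbation grids are reproducible.
    """
    v = model.vertices
    centroid = v.mean(axis=0)
    dv = v - centroid
    if np.linalg.norm(dv, axis=1).max() < 1e-12:
        raise DegenerateGeometryError("all vertices coincide")
    # right singular vector of the centred cloud = first PC
    _, _, Vt = np.linalg.svd(dv, full_matrices=False)
    axis = Vt[0]
    for comp in (2, 0, 1):
        if abs(axis[comp]) > 1e-12:
            if axis[comp] < 0:
                axis = -axis
            break
    return axis / np.linalg.norm(axis), centroid
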