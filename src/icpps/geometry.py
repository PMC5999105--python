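"""Rigid-body transform algebra and closed-form rigid point-set fitting.

Conventions used throughout the package:

* lengths are millimetres, angles are degrees at the API surface
  (radians internally);
* a :class:`RigidTransform` maps a point ``p`` to ``R @ p + t``;
* point sets are ``(n, 3)`` float arrays wrapped in :class:`PointSet3`,
  whose ordering is stable under every operation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CorrespondenceError, DegenerateGeometryError, ParameterError

__all__ = [
    "RigidTransform",
    "PointSet3",
    "apply_transform",
    "fit_rigid_point_to_point",
    "random_rigid_transform",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion: rotation followed by translation.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Orthonormal matrix with determinant +1.
    translation : (3,) ndarray
        Translation vector in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ParameterError("transform contains non-finite values")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-6:
            raise ParameterError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ParameterError("rotation matrix is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- algebra ---------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an ``(n, 3)`` array (or a single 3-vector)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first,
        then ``self``: ``(self ∘ other)(p) == self(other(p))``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - np.eye(3)).max() <= tol
            and np.abs(self.translation).max() <= tol
        )

    def rotation_angle_deg(self) -> float:
        """Rotation angle of the motion, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": [float(x) for x in self.rotation.ravel()],
            "translation": [float(x) for x in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            np.asarray(d["rotation"], dtype=float).reshape(3, 3),
            np.asarray(d["translation"], dtype=float),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PointSet3:
    """An ordered set of 3-D points with optional per-point metadata.

    Attributes
    ----------
    points : (n, 3) ndarray, mm
    labels : list of str or None
        Optional per-point area tag (pre-registration area names on the
        first six points of a surface-sample set).
    uple : (n,) ndarray or None
        Per-point true localization-error magnitude in mm, filled in by
        the noise model.
    """

    points: np.ndarray
    labels: list | None = None
    uple: np.ndarray | None = None

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ParameterError(f"points must be (n, 3), got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ParameterError("points contain non-finite coordinates")
        self.points = p
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != len(p):
                raise ParameterError("labels length must match points")
        if self.uple is not None:
            self.uple = np.asarray(self.uple, dtype=float)
            if self.uple.shape != (len(p),):
                raise ParameterError("uple length must match points")

    def __len__(self) -> int:
        return len(self.points)

    def copy(self) -> "PointSet3":
        return PointSet3(
            self.points.copy(),
            None if self.labels is None else list(self.labels),
            None if self.uple is None else self.uple.copy(),
        )

    # -- CSV I/O (columns x,y,z[,label][,uple]) --------------------------
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.points, columns=["x", "y", "z"])
        if self.labels is not None:
            df["label"] = self.labels
        if self.uple is not None:
            df["uple"] = self.uple
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PointSet3":
        df = pd.read_csv(path, comment="#")
        labels = df["label"].tolist() if "label" in df.columns else None
        uple = df["uple"].to_numpy() if "uple" in df.columns else None
        return cls(df[["x", "y", "z"]].to_numpy(dtype=float), labels, uple)


def apply_transform(t: RigidTransform, p: PointSet3) -> PointSet3:
    """Transform every point; labels and uple metadata are carried through."""
    return PointSet3(
        t.apply(p.points),
        None if p.labels is None else list(p.labels),
        None if p.uple is None else p.uple.copy(),
    )


def fit_rigid_point_to_point(
    source: PointSet3 | np.ndarray, target: PointSet3 | np.ndarray
) -> tuple[RigidTransform, float]:
    """Closed-form least-squares rigid fit of ``source`` onto ``target``.

    Minimizes the mean squared residual

        f(R, T) = 1/n * sum_i || x_i - (R u_i + T) ||^2

    over proper rotations R and translations T, where ``u_i`` are the
    source points and ``x_i`` the corresponding target points.  The
    global minimizer is obtained from the SVD of the cross-covariance
    (the Kabsch solution) with a reflection guard: when the best
    orthogonal matrix would be a reflection, the sign of the singular
    vector of the smallest singular value is flipped.

    Returns
    -------
    (transform, objective)
        The fitted transform and the value of the 1/n-scaled objective
        at the minimizer (mm^2).

    Raises
    ------
    CorrespondenceError
        If the two sets differ in length.
    DegenerateGeometryError
        If n < 3 or the source points are (numerically) collinear.
    """
    u = source.points if isinstance(source, PointSet3) else np.asarray(source, float)
    x = target.points if isinstance(target, PointSet3) else np.asarray(target, float)
    if u.shape != x.shape:
        raise CorrespondenceError(
            f"source and target must have equal shape, got {u.shape} vs {x.shape}"
        )
    n = len(u)
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 correspondences, got {n}")

    cu = u.mean(axis=0)
    cx = x.mean(axis=0)
    du = u - cu
    dx = x - cx

    # collinearity check: a rank-<2 centred source leaves the rotation
    # about the line unconstrained
    s_src = np.linalg.svd(du, compute_uv=False)
    scale = s_src[0] if s_src[0] > 0 else 1.0
    if s_src[1] / scale < 1e-9:
        raise DegenerateGeometryError("source points are collinear or coincident")

    H = du.T @ dx  # cross-covariance (3, 3)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cx - R @ cu
    transform = RigidTransform(R, t)
    resid = x - transform.apply(u)
    objective = float(np.mean(np.sum(resid**2, axis=1)))
    return transform, objective


def random_rigid_transform(
    rng: np.random.Generator,
    max_rotation_deg: float,
    max_translation_mm: float,
) -> RigidTransform:
    """Draw a random rigid displacement with bounded magnitude.

    The rotation axis and the translation direction are uniform on the
    unit sphere; the rotation angle is uniform on [0, max_rotation_deg]
    and the translation norm uniform on [0, max_translation_mm], so the
    stated bounds hold surely (not just in expectation).
    """
    if max_rotation_deg < 0 or max_translation_mm < 0:
        raise ParameterError("displacement bounds must be non-negative")

    axis = _random_unit_vector(rng)
    angle = np.radians(rng.uniform(0.0, max_rotation_deg))
    direction = _random_unit_vector(rng)
    norm = rng.uniform(0.0, max_translation_mm)
    R = _axis_angle_matrix(axis, angle)
    return RigidTransform(R, norm * direction)


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _axis_angle_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1.0 - np.cos(angle_rad)) * (K @ K)
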