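"""The ICP-PS registration method.

Registers sparse surface sample points (SSP) to a known bone surface
model in four steps:

1. **Pre-registration** — closed-form point-to-point fit of six labeled
   points (two per pre-registration area) to the centroids of those
   areas; a coarse alignment that puts ICP inside its capture range.
2. **ICP** — alternating closest-point correspondence (k-d tree) and
   rigid least-squares fitting, at most 30 iterations.
3. **Perturbation search** — because a long bone is nearly cylindrical,
   ICP tends to stall in local minima displaced along the
   distal-proximal axis.  The registered points are perturbed over a
   grid of rotations about / translations along that axis (default
   -5..5 deg by 1 deg and -3..3 mm by 0.5 mm, 143 candidates) and the
   candidate with the lowest point-to-surface distance (PSD) replaces
   the ICP solution when it improves on it.
4. **Feedback** — steps 2-3 repeat from the perturbed pose until the
   PSD improvement drops below 1e-5 mm^2, at most 5 rounds.

The PSD (mean squared distance of the registered points to their
closest surface points, mm^2) is the quantity the search compares; the
trace also records its square root in mm for readability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError, ParameterError
from .geometry import (
    PointSet3,
    RigidTransform,
    apply_transform,
    fit_rigid_point_to_point,
    _axis_angle_matrix,
)
from .surface_model import (
    PRE_REGISTRATION_REGIONS,
    SurfaceModel,
    closest_point,
    principal_axis,
)

__all__ = [
    "RegistrationResult",
    "PerturbationGrid",
    "TraceEntry",
    "preregister",
    "run_icp",
    "build_perturbation_grid",
    "compute_psd",
    "perturbation_search",
    "register_icp_ps",
]

#: PSD improvement below which the perturbation->ICP feedback loop is
#: considered converged (mm^2).
FEEDBACK_TOL = 1e-5
#: maximum number of perturbation->ICP feedback rounds
MAX_FEEDBACK_ROUNDS = 5
#: maximum ICP iterations per pass
MAX_ICP_ITER = 30
#: ICP stops early when the per-iteration PSD improvement falls below this (mm^2)
ICP_TOL = 1e-6


@dataclass(frozen=True)
class TraceEntry:
    """One recorded stage of a registration run."""

    stage: str  # "preregister" | "icp" | "perturbation"
    round: int  # feedback round (0 = initial pass)
    psd: float  # mm^2
    transform: RigidTransform
    iterations: int = 0  # ICP iterations used (icp stages only)
    psd_history: tuple = ()  # per-iteration PSD sequence (icp stages only)

    @property
    def rms(self) -> float:
        """Root of the PSD, in mm."""
        return float(np.sqrt(self.psd))


@dataclass
class RegistrationResult:
    """Final transform (SSP frame -> model frame) plus the per-stage trace."""

    transform: RigidTransform
    trace: list = field(default_factory=list)
    converged: bool = False
    n_feedback_rounds: int = 0

    @property
    def final_psd(self) -> float:
        return self.trace[-1].psd

    def stage_entries(self, stage: str) -> list:
        return [e for e in self.trace if e.stage == stage]

    def transform_after_step(self, step: int) -> RigidTransform:
        """Transform after procedure step 2 (first ICP), 3 (first
        perturbation search) or 4 (end of the feedback loop)."""
        if step == 2:
            return self.stage_entries("icp")[0].transform
        if step == 3:
            pert = self.stage_entries("perturbation")
            return pert[0].transform if pert else self.stage_entries("icp")[0].transform
        if step == 4:
            return self.transform
        raise ParameterError(f"step must be 2, 3 or 4, got {step}")

    def psd_after_step(self, step: int) -> float:
        if step == 2:
            return self.stage_entries("icp")[0].psd
        if step == 3:
            pert = self.stage_entries("perturbation")
            return pert[0].psd if pert else self.stage_entries("icp")[0].psd
        if step == 4:
            return self.trace[-1].psd
        raise ParameterError(f"step must be 2, 3 or 4, got {step}")

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.to_dict(),
            "converged": self.converged,
            "n_feedback_rounds": self.n_feedback_rounds,
            "trace": [
                {
                    "stage": e.stage,
                    "round": e.round,
                    "psd_mm2": e.psd,
                    "rms_mm": e.rms,
                    "iterations": e.iterations,
                    "transform": e.transform.to_dict(),
                }
                for e in self.trace
            ],
        }


@dataclass
class PerturbationGrid:
    """Axis-constrained grid of candidate rigid perturbations.

    Each candidate rotates about the axis line through ``axis_point``
    and translates along the axis; candidates are ordered
    rotation-major, then translation.
    """

    axis: np.ndarray
    axis_point: np.ndarray
    rotations_deg: np.ndarray
    translations_mm: np.ndarray
    candidates: list  # list[RigidTransform], rotation-major order

    def __len__(self) -> int:
        return len(self.candidates)

    def magnitudes(self) -> np.ndarray:
        """Scalar size of each candidate, used only for tie-breaking:
        sqrt(rot_deg^2 + trans_mm^2)."""
        r = np.repeat(self.rotations_deg, len(self.translations_mm))
        t = np.tile(self.translations_mm, len(self.rotations_deg))
        return np.hypot(r, t)


def compute_psd(points: PointSet3, model: SurfaceModel, mode: str = "vertex") -> float:
    """Mean squared point-to-surface distance (PSD), mm^2."""
    if len(points) == 0:
        raise InputError("cannot compute PSD of an empty point set")
    _, dist = closest_point(model, points.points, mode=mode)
    return float(np.mean(dist**2))


def preregister(ssp: PointSet3, model: SurfaceModel) -> RigidTransform:
    """Coarse alignment from the six labeled pre-registration points.

    The first six SSP points must carry area labels, two per
    pre-registration area; each is matched to the centroid of its area's
    labeled vertices and a closed-form rigid fit (n = 6) is returned.
    """
    if len(ssp) < 6:
        raise InputError(f"pre-registration needs 6 labeled points, got {len(ssp)}")
    if ssp.labels is None:
        raise ConfigurationError("SSP carries no area labels")
    head = [lab for lab in ssp.labels[:6] if lab in PRE_REGISTRATION_REGIONS]
    if len(head) != 6:
        raise ConfigurationError(
            "first six SSP points must be labeled with pre-registration areas; "
            f"got {ssp.labels[:6]}"
        )
    for region in PRE_REGISTRATION_REGIONS:
        if head.count(region) != 2:
            raise ConfigurationError(
                f"expected exactly 2 points labeled {region!r}, got {head.count(region)}"
            )
        if region not in model.region_labels:
            raise ConfigurationError(f"model lacks region {region!r}")
    targets = np.array([model.region_centroid(lab) for lab in head])
    transform, _ = fit_rigid_point_to_point(ssp.points[:6], targets)
    return transform


def run_icp(
    ssp: PointSet3,
    model: SurfaceModel,
    init: RigidTransform | None = None,
    max_iter: int = MAX_ICP_ITER,
    tol: float = ICP_TOL,
    mode: str = "vertex",
    _round: int = 0,
    _trace: list | None = None,
) -> RegistrationResult:
    """Iterative closest point from an optional initial transform.

    Per iteration the closest model points of the current SSP pose
    establish the correspondence pairs, and the closed-form rigid fit of
    the *original* SSP onto those correspondences updates the pose.
    Stops after ``max_iter`` iterations or when the PSD improves by less
    than ``tol`` mm^2; the PSD sequence is non-increasing by
    construction (each fit minimizes the distance to the current
    correspondences).
    """
    transform = init if init is not None else RigidTransform.identity()
    trace = _trace if _trace is not None else []
    history: list[float] = []
    psd_prev = np.inf
    n_it = 0
    for n_it in range(1, max_iter + 1):
        moved = transform.apply(ssp.points)
        corr, dist = closest_point(model, moved, mode=mode)
        psd = float(np.mean(dist**2))
        history.append(psd)
        if psd_prev - psd < tol:
            break
        transform, _ = fit_rigid_point_to_point(ssp.points, corr)
        psd_prev = psd
    final_psd = compute_psd(apply_transform(transform, ssp), model, mode=mode)
    if not history or final_psd < history[-1]:
        history.append(final_psd)
    trace.append(
        TraceEntry(
            "icp", _round, final_psd, transform,
            iterations=n_it, psd_history=tuple(history),
        )
    )
    return RegistrationResult(transform, trace, converged=True, n_feedback_rounds=_round)


def build_perturbation_grid(
    axis: np.ndarray,
    axis_point: np.ndarray,
    rot_min: float = -5.0,
    rot_max: float = 5.0,
    rot_step: float = 1.0,
    trans_min: float = -3.0,
    trans_max: float = 3.0,
    trans_step: float = 0.5,
) -> PerturbationGrid:
    """Enumerate the axis-constrained perturbation candidates.

    With the defaults this is the 11 x 13 = 143-candidate grid:
    rotations -5..5 deg in 1 deg steps about the distal-proximal axis
    and translations -3..3 mm in 0.5 mm steps along it, both endpoints
    included.
    """
    if rot_step <= 0 or trans_step <= 0:
        raise ParameterError("grid steps must be positive")
    if rot_min > rot_max or trans_min > trans_max:
        raise ParameterError("grid ranges must satisfy min <= max")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    axis_point = np.asarray(axis_point, dtype=float)
    rotations = _inclusive_range(rot_min, rot_max, rot_step)
    translations = _inclusive_range(trans_min, trans_max, trans_step)
    candidates = []
    for rot in rotations:
        R = _axis_angle_matrix(axis, np.radians(rot))
        t_rot = axis_point - R @ axis_point  # rotate about the axis *line*
        for trans in translations:
            candidates.append(RigidTransform(R, t_rot + trans * axis))
    return PerturbationGrid(axis, axis_point, rotations, translations, candidates)


def _inclusive_range(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    vals = lo + step * np.arange(n)
    if hi - vals[-1] > 1e-9:  # range not an exact multiple of step
        vals = np.append(vals, hi)
    return vals


def perturbation_search(
    transform: RigidTransform,
    psd: float,
    ssp: PointSet3,
    model: SurfaceModel,
    grid: PerturbationGrid,
    mode: str = "vertex",
) -> tuple[RigidTransform, float]:
    """Exhaustive PSD minimization over the perturbation grid.

    Every candidate is applied *after* the incoming transform (the
    registered points are perturbed from their current pose) and scored
    by PSD.  Ties are broken toward the smallest perturbation magnitude,
    then enumeration order.  If no candidate strictly beats the incoming
    PSD, the incoming state is returned unchanged.
    """
    moved = transform.apply(ssp.points)
    mags = grid.magnitudes()
    best_psd = np.inf
    best_idx = -1
    for i, cand in enumerate(grid.candidates):
        pts = cand.apply(moved)
        _, dist = closest_point(model, pts, mode=mode)
        cand_psd = float(np.mean(dist**2))
        if cand_psd < best_psd or (
            cand_psd == best_psd and best_idx >= 0 and mags[i] < mags[best_idx]
        ):
            best_psd = cand_psd
            best_idx = i
    if best_idx < 0 or best_psd >= psd:
        return transform, psd
    return grid.candidates[best_idx].compose(transform), best_psd


def register_icp_ps(
    ssp: PointSet3,
    model: SurfaceModel,
    mode: str = "vertex",
    grid: PerturbationGrid | None = None,
    max_icp_iter: int = MAX_ICP_ITER,
    icp_tol: float = ICP_TOL,
    feedback_tol: float = FEEDBACK_TOL,
    max_feedback_rounds: int = MAX_FEEDBACK_ROUNDS,
    with_perturbation: bool = True,
) -> RegistrationResult:
    """Full four-step registration (pre-registration, ICP, perturbation
    search, feedback loop).

    With ``with_perturbation=False`` the procedure stops after the ICP
    pass, i.e. it is the standard pre-registered ICP baseline.

    The final PSD never exceeds the PSD after the first ICP pass: a
    perturbation is only accepted when it strictly lowers the PSD, and
    each subsequent ICP pass starts from the accepted pose and is itself
    non-increasing.
    """
    pre = preregister(ssp, model)
    trace = [
        TraceEntry(
            "preregister", 0, compute_psd(apply_transform(pre, ssp), model, mode), pre
        )
    ]
    result = run_icp(
        ssp, model, init=pre, max_iter=max_icp_iter, tol=icp_tol, mode=mode,
        _round=0, _trace=trace,
    )
    if not with_perturbation:
        return result

    if grid is None:
        if model.axis is None or model.axis_point is None:
            model.axis, model.axis_point = principal_axis(model)
        grid = build_perturbation_grid(model.axis, model.axis_point)

    transform = result.transform
    psd = result.final_psd
    converged = False
    rounds = 0
    for rounds in range(1, max_feedback_rounds + 1):
        pert_t, pert_psd = perturbation_search(transform, psd, ssp, model, grid, mode)
        trace.append(TraceEntry("perturbation", rounds, pert_psd, pert_t))
        if pert_psd >= psd:  # no better adjacent minimum: converged
            converged = True
            rounds -= 1
            break
        res = run_icp(
            ssp, model, init=pert_t, max_iter=max_icp_iter, tol=icp_tol, mode=mode,
            _round=rounds, _trace=trace,
        )
        improvement = psd - res.final_psd
        transform, psd = res.transform, res.final_psd
        if improvement < feedback_tol:
            converged = True
            break
    return RegistrationResult(
        transform, trace, converged=converged, n_feedback_rounds=rounds
    )
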