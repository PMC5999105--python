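"""Monte-Carlo framework for registration accuracy.

The simulated registration procedure mirrors the clinical one: a set of
ground-truth surface sample points (GT-SSP) is drawn from the model,
rigidly displaced to an arbitrary nearby pose, corrupted with isotropic
point localization noise (UPLE), registered back with standard ICP or
ICP-PS, and scored with a bone-to-bone RMSE — the root-mean-square
displacement of *all* model vertices under the residual transform.  A
factorial design sweeps the number of points (6-25) and the UPLE
interval (0, [0-1], [1-2] mm); at full scale (100 repeats) this is the
6000-trial design.

Trial seeds are derived from the master seed with
``numpy.random.SeedSequence`` spawn keys indexed by the factor levels,
so adding factor levels never perturbs existing trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, SamplingError
from .geometry import (
    PointSet3,
    RigidTransform,
    apply_transform,
    random_rigid_transform,
)
from .registration import register_icp_ps
from .surface_model import PRE_REGISTRATION_REGIONS, SurfaceModel

__all__ = [
    "TrialConfig",
    "TrialRecord",
    "ExperimentTable",
    "select_gt_ssp",
    "add_uple_noise",
    "rmse_bone_to_bone",
    "run_trial",
    "run_experiment",
    "incremental_uple_evaluation",
]

DEFAULT_UPLE_INTERVALS = ((0.0, 0.0), (0.0, 1.0), (1.0, 2.0))


@dataclass(frozen=True)
class TrialConfig:
    """One cell of the simulation design."""

    n_points: int = 25
    uple_interval: tuple = (0.0, 0.0)
    max_rotation_deg: float = 10.0
    max_translation_mm: float = 20.0
    seed: int = 0
    method: str = "icp-ps"  # {"icp", "icp-ps"}
    mode: str = "vertex"  # closest-point mode

    def __post_init__(self):
        if self.n_points < 6:
            raise ParameterError("n_points must be at least 6")
        a, b = self.uple_interval
        if not (0 <= a <= b):
            raise ParameterError("uple_interval must satisfy 0 <= a <= b")
        if self.method not in ("icp", "icp-ps"):
            raise ParameterError(f"unknown method {self.method!r}")


@dataclass
class TrialRecord:
    """Outcome of one simulated registration trial."""

    config: TrialConfig
    rmse_by_step: dict  # step (2, 3, 4) -> bone-to-bone RMSE mm
    psd_by_step: dict  # step -> PSD mm^2
    true_displacement: RigidTransform
    estimated: RigidTransform
    n_feedback_rounds: int
    converged: bool

    def rows(self) -> list:
        c = self.config
        return [
            {
                "method": c.method,
                "step": step,
                "n_points": c.n_points,
                "uple_lo": c.uple_interval[0],
                "uple_hi": c.uple_interval[1],
                "seed": c.seed,
                "psd_mm2": self.psd_by_step[step],
                "rmse_mm": self.rmse_by_step[step],
            }
            for step in sorted(self.rmse_by_step)
        ]


@dataclass
class ExperimentTable:
    """Tidy collection of trial outcomes (one row per trial x step)."""

    records: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, rec in enumerate(self.records):
            for row in rec.rows():
                rows.append({"trial_id": i, "repeat": rec.config.seed, **row})
        return pd.DataFrame(rows)

    def mean_rmse(self) -> pd.DataFrame:
        """Mean RMSE by method x step x n_points x UPLE interval (the
        accuracy-vs-point-count curves)."""
        df = self.to_dataframe()
        return (
            df.groupby(["method", "step", "n_points", "uple_lo", "uple_hi"])
            ["rmse_mm"].mean().reset_index()
        )


def select_gt_ssp(
    model: SurfaceModel, n_points: int, rng: np.random.Generator
) -> PointSet3:
    """Draw ground-truth surface sample points from the labeled model.

    The first six points are two uniformly chosen vertices from each
    pre-registration area (labels attached); the remaining ``n - 6`` are
    drawn uniformly without replacement from the accessible vertices.
    """
    if n_points < 6:
        raise ParameterError("n_points must be at least 6")
    points = []
    labels = []
    for region in PRE_REGISTRATION_REGIONS:
        idx = model.region(region)
        if len(idx) < 2:
            raise SamplingError(f"region {region!r} has fewer than 2 vertices")
        chosen = rng.choice(idx, size=2, replace=False)
        points.extend(model.vertices[chosen])
        labels.extend([region, region])
    accessible = model.region("accessible")
    n_rest = n_points - 6
    if n_rest > len(accessible):
        raise SamplingError(
            f"accessible region has {len(accessible)} vertices, need {n_rest}"
        )
    if n_rest:
        chosen = rng.choice(accessible, size=n_rest, replace=False)
        points.extend(model.vertices[chosen])
        labels.extend(["accessible"] * n_rest)
    return PointSet3(np.array(points), labels)


def add_uple_noise(
    points: PointSet3, interval: tuple, rng: np.random.Generator
) -> PointSet3:
    """Isotropic point-localization noise.

    Each point is displaced by ``m * d`` with ``d`` uniform on the unit
    sphere and ``m ~ Uniform(a, b)``; the drawn magnitude is stored in
    the ``uple`` field.
    """
    a, b = interval
    if a < 0 or b < a:
        raise ParameterError("interval must satisfy 0 <= a <= b")
    n = len(points)
    directions = rng.normal(size=(n, 3))
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    directions /= norms
    magnitudes = rng.uniform(a, b, size=n)
    return PointSet3(
        points.points + magnitudes[:, None] * directions,
        None if points.labels is None else list(points.labels),
        magnitudes,
    )


def rmse_bone_to_bone(
    true_displacement: RigidTransform,
    estimated_registration: RigidTransform,
    model: SurfaceModel,
) -> float:
    """Bone-to-bone registration error, mm.

    The estimated registration is applied on top of the true
    displacement; a perfect registration makes that residual the
    identity.  The error is the root-mean-square displacement of all
    model vertices under the residual transform — a whole-bone target
    registration error rather than a fiducial error.
    """
    residual = estimated_registration.compose(true_displacement)
    moved = residual.apply(model.vertices)
    return float(np.sqrt(np.mean(np.sum((moved - model.vertices) ** 2, axis=1))))


def run_trial(model: SurfaceModel, config: TrialConfig) -> TrialRecord:
    """Run one simulated registration trial.

    GT-SSP are sampled, displaced by a bounded random rigid transform,
    noised, and registered with the configured method; the bone-to-bone
    RMSE and the PSD are recorded after procedure steps 2 (ICP), 3
    (first perturbation search) and 4 (feedback loop) by re-scoring the
    intermediate transforms from the registration trace.  For the plain
    ICP method only step 2 exists.
    """
    rng = np.random.default_rng(config.seed)
    gt = select_gt_ssp(model, config.n_points, rng)
    displacement = random_rigid_transform(
        rng, config.max_rotation_deg, config.max_translation_mm
    )
    ssp = apply_transform(displacement, gt)
    ssp = add_uple_noise(ssp, config.uple_interval, rng)

    result = register_icp_ps(
        ssp, model, mode=config.mode,
        with_perturbation=(config.method == "icp-ps"),
    )
    steps = (2,) if config.method == "icp" else (2, 3, 4)
    rmse_by_step = {
        s: rmse_bone_to_bone(displacement, result.transform_after_step(s), model)
        for s in steps
    }
    psd_by_step = {s: result.psd_after_step(s) for s in steps}
    return TrialRecord(
        config=config,
        rmse_by_step=rmse_by_step,
        psd_by_step=psd_by_step,
        true_displacement=displacement,
        estimated=result.transform,
        n_feedback_rounds=result.n_feedback_rounds,
        converged=result.converged,
    )


def trial_seed(master_seed: int, *indices: int) -> int:
    """Deterministic per-trial seed from the master seed and the factor
    indices; stable under extension of any factor list."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(indices))
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(
    model: SurfaceModel,
    n_points_list=tuple(range(6, 26)),
    uple_intervals=DEFAULT_UPLE_INTERVALS,
    repeats: int = 100,
    methods: tuple = ("icp-ps",),
    master_seed: int = 0,
    mode: str = "vertex",
    displacement=(10.0, 20.0),
    progress=None,
) -> ExperimentTable:
    """Sweep the factorial design (one trial per cell per repeat per method).

    At the full scale — 20 point counts x 3 UPLE intervals x 100
    repeats, one method — this enumerates 6000 trials.
    """
    if not n_points_list or not uple_intervals or not methods or repeats < 1:
        raise ParameterError("factor lists must be non-empty and repeats >= 1")
    table = ExperimentTable()
    for mi, method in enumerate(methods):
        for ni, n_points in enumerate(n_points_list):
            for ui, interval in enumerate(uple_intervals):
                for rep in range(repeats):
                    cfg = TrialConfig(
                        n_points=int(n_points),
                        uple_interval=tuple(interval),
                        max_rotation_deg=displacement[0],
                        max_translation_mm=displacement[1],
                        seed=trial_seed(master_seed, mi, ni, ui, rep),
                        method=method,
                        mode=mode,
                    )
                    table.records.append(run_trial(model, cfg))
                    if progress is not None:
                        progress()
    return table


def design_size(n_points_list, uple_intervals, repeats, methods) -> int:
    """Number of trials the factorial design enumerates."""
    return len(n_points_list) * len(uple_intervals) * repeats * len(methods)


def incremental_uple_evaluation(
    model: SurfaceModel,
    rng: np.random.Generator,
    n_areas: int = 25,
    repeats_per_area: int = 10,
    selection: str = "closest",
    uple_interval: tuple = (0.0, 2.0),
    displacement=(10.0, 20.0),
    mode: str = "vertex",
) -> pd.DataFrame:
    """Incremental evaluation with per-area repeated measurements.

    Emulates a measurement protocol in which each of ``n_areas``
    anatomical sites (the six pre-registration points plus accessible
    sites) is measured ``repeats_per_area`` times with noise; per site
    the single measurement with minimal ("closest") or maximal
    ("farthest") localization error is kept.  The non-pre-registration
    sites are then sorted in descending order of their kept error and
    added one at a time, registering with both standard ICP and ICP-PS
    at every point count from 6 up to ``n_areas``.

    Returns a tidy frame with one row per (method, n_points).
    """
    if selection not in ("closest", "farthest"):
        raise ParameterError("selection must be 'closest' or 'farthest'")
    if n_areas < 7:
        raise ParameterError("need at least 7 areas (6 pre-registration + 1)")

    anchors = select_gt_ssp(model, n_areas, rng)
    displacement_t = random_rigid_transform(rng, *displacement)
    moved = apply_transform(displacement_t, anchors)

    # repeated noisy measurements per site; keep the min- or max-error one
    kept_pts = np.empty((n_areas, 3))
    kept_uple = np.empty(n_areas)
    for i in range(n_areas):
        site = PointSet3(np.repeat(moved.points[i][None], repeats_per_area, axis=0))
        noisy = add_uple_noise(site, uple_interval, rng)
        j = int(np.argmin(noisy.uple) if selection == "closest" else np.argmax(noisy.uple))
        kept_pts[i] = noisy.points[j]
        kept_uple[i] = noisy.uple[j]

    order = np.argsort(-kept_uple[6:], kind="stable") + 6  # descending UPLE
    rows = []
    for k in range(6, n_areas + 1):
        idx = np.concatenate([np.arange(6), order[: k - 6]])
        ssp = PointSet3(kept_pts[idx], [moved.labels[i] for i in idx], kept_uple[idx])
        for method in ("icp", "icp-ps"):
            result = register_icp_ps(
                ssp, model, mode=mode, with_perturbation=(method == "icp-ps")
            )
            rows.append(
                {
                    "selection": selection,
                    "method": method,
                    "n_points": k,
                    "max_uple_mm": float(kept_uple[idx].max()),
                    "added_uple_mm": float(kept_uple[idx[-1]]),
                    "psd_mm2": result.final_psd,
                    "rmse_mm": rmse_bone_to_bone(
                        displacement_t, result.transform, model
                    ),
                }
            )
    return pd.DataFrame(rows)
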