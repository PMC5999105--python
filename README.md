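# icpps

Rigid registration of sparse, noisy bone-surface points to a known
surface model, for computer-aided orthopedic surgery (CAOS) workflows in
which the intraoperative data are a handful of 3-D points measured on
the bone (for example with a tracked A-mode ultrasound transducer) and
the preoperative data are a dense CT-derived triangulation of the same
bone.

The package implements **ICP-PS** — iterative closest point combined
with an axis-constrained **perturbation search** — together with a
Monte-Carlo simulation framework that quantifies registration accuracy
as a function of the number of registration points and the per-point
ultrasound localization error (UPLE).

## The method

Given surface sample points `U = {u_i}` and a surface model (the
pre-operative model, POM), registration runs in four steps:

1. **Pre-registration.** Six labeled points (two from each of three
   pre-registration areas: greater trochanter, medial epicondyle,
   lateral epicondyle) are fitted to the centroids of those areas by the
   closed-form rigid least-squares solution of

   `f(R, T) = 1/n Σ ‖x_i − (R u_i + T)‖²`,

   computed by SVD of the cross-covariance with a proper-rotation guard.
2. **ICP.** Closest points on the POM (k-d tree over the mesh vertices)
   define correspondences; the closed-form fit updates the pose; at most
   30 iterations.
3. **Perturbation search.** A long bone is nearly cylindrical about its
   distal–proximal axis, so ICP tends to stall in local minima displaced
   along that axis. The registered points are perturbed over a grid of
   rotations about / translations along the axis (−5°…5° by 1°, −3…3 mm
   by 0.5 mm: 11 × 13 = 143 candidates) and each candidate is scored by
   the point-to-surface distance `PSD = 1/n Σ ‖s_i − u_i‖²` (mm², with
   `s_i` the closest surface point of `u_i`). The best candidate
   replaces the ICP pose when it strictly lowers the PSD.
4. **Feedback.** Steps 2–3 repeat from the perturbed pose until the PSD
   improvement is below 1e−5 mm², at most 5 rounds.

Accuracy is measured by a whole-bone metric: the residual transform
(estimated registration composed with the true displacement) is applied
to every model vertex, and `RMSE = √(1/n Σ ‖u_i − g_i‖²)` is the
root-mean-square vertex displacement — a bone-to-bone target
registration error, 0 mm exactly when the registration inverts the true
displacement.

Because a CT-derived femur model cannot be shipped, the package includes
a procedural **synthetic femur** generator (watertight labeled mesh:
cylinder-like shaft, offset head, greater-trochanter and epicondylar
bulges, accessible/inaccessible areas and the three pre-registration
disks) on which the whole pipeline — and the axial-local-minimum regime
the perturbation search exists for — is reproduced.

## Worked example

```python
import numpy as np
from icpps import (
    generate_synthetic_femur, select_gt_ssp, apply_transform,
    random_rigid_transform, add_uple_noise, register_icp_ps, rmse_bone_to_bone,
)

model = generate_synthetic_femur()                      # labeled synthetic femur
rng = np.random.default_rng(7)
gt = select_gt_ssp(model, n_points=25, rng=rng)         # ground-truth sample points
displacement = random_rigid_transform(rng, 10.0, 20.0)  # unknown pose offset
ssp = add_uple_noise(apply_transform(displacement, gt), (0.0, 1.0), rng)

result = register_icp_ps(ssp, model)
for entry in result.trace:
    print(f"{entry.stage:<12} round {entry.round}  PSD {entry.psd:8.4f} mm^2")
print("feedback rounds:", result.n_feedback_rounds)
for step in (2, 3, 4):
    err = rmse_bone_to_bone(displacement, result.transform_after_step(step), model)
    print(f"bone-to-bone RMSE after step {step}: {err:.3f} mm")
```

Output:

```
preregister  round 0  PSD   2.0554 mm^2
icp          round 0  PSD   0.4699 mm^2
perturbation round 1  PSD   0.4296 mm^2
icp          round 1  PSD   0.3803 mm^2
perturbation round 2  PSD   0.3803 mm^2
feedback rounds: 1
bone-to-bone RMSE after step 2: 3.264 mm
bone-to-bone RMSE after step 3: 2.271 mm
bone-to-bone RMSE after step 4: 2.555 mm
```

The trace shows the PSD falling monotonically through the stages: the
perturbation in round 1 escapes the ICP local minimum and the second ICP
pass refines it; the round-2 perturbation finds nothing better, so the
loop stops. The RMSE lines re-score the intermediate transforms with the
bone-to-bone metric: at this noise level ([0–1] mm UPLE) the full
procedure (step 4) ends about 0.7 mm closer to the true pose than plain
ICP (step 2). Note that the PSD — the quantity the search can actually
observe — is monotone by construction, while the RMSE against the hidden
truth may fluctuate between steps 3 and 4. With zero noise the method
typically recovers the pose to well under 0.5 mm, whereas plain ICP is
left ~2 mm off in the axial local minimum.

## Command line

```sh
icpps generate-mesh --seed 1 --out femur.stl            # STL + label sidecar
icpps register --model femur.stl --points points.csv --out result.json
icpps simulate --model femur.stl --points 6:25 --uple 0,0 --uple 0,1 --uple 1,2 \
               --repeats 100 --seed 1 --out results.csv
```

`simulate` sweeps the factorial design (point counts × UPLE intervals ×
repeats; 20 × 3 × 100 = 6000 trials at full scale) and writes a tidy CSV
of per-trial PSD and RMSE per registration step plus an aggregated
mean-RMSE table. All outputs embed the tool version, resolved
configuration and seed.

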