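# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `fluoroguide`, in the order data flows through the chain.

## Geometry and conventions

All 3-D geometry lives in one right-handed world frame in millimetres with
Y along the patient's long axis (positive = superior), X patient
left–right, Z anterior–posterior. The C-arm rotates about Y only; LAO is a
positive rotation, RAO negative, AP zero (the literature does not fix this
sign; it is set in `CArmPose.signed_angle_deg` and used consistently).
Projection is orthographic (parallel-beam): a pose's view frame is
`p_view = R_y(θ_signed) · p_world`, the detector drops the view z, and
pixels map to mm with the detector centre at the world origin
(x = col·spacing relative to centre, mm-y antiparallel to rows). Default
spacing is 0.25 mm/px, i.e. 2 px = 0.5 mm.

Orthographic projection is what makes the two-view relationship a pure
rotation with no perspective scale, and hence the depth equations linear
and row-preserving. Cone-beam divergence of a real C-arm is deliberately
out of scope; at clinical source–detector distances its scale error over
the small spine/catheter region is absorbed by the registration's scale
parameter.

## Synthetic phantom

The phantom stands in for a 3-D-printed heart/spine model imaged under an
interventional X-ray system.

* **Vertebral bodies**: five rounded boxes (axis-aligned box ∩ elliptic
  cylinder with semi-axes 1.2× the half-extents, which rounds the axial
  corners but keeps flat endplates), default 24×18×20 mm with a 4 mm
  intervertebral gap, stacked along +Y and named T4–T8. Transverse
  dimensions grow 5 % per level inferiorly (`size_taper`), matching the
  craniocaudal growth of real vertebral bodies; this also makes the
  silhouette asymmetric under 180° rotation, which a purely periodic stack
  would not be. Optional per-vertebra jitter (default study condition
  0.8 mm) perturbs lateral positions and sizes deterministically from the
  seed. Exact centroids are stored as ground truth.
* **Posterior column**: a narrower solid spanning the whole stack,
  offset posteriorly, standing in for the pedicle/lamina column that makes
  a real projected spine one connected dark object. Without it the
  segmentation's largest-component step would keep a single vertebra.
* **Heart**: an ellipsoid shell rendered almost transparent
  (μ = 0.0008/mm), as the heart appears in clinical fluoroscopy.
* **Catheter**: a natural cubic spline through waypoints, arc-length
  parameterized, rendered as a 4 mm tube (a 12-Fr device) with flat-cut
  ends — the tube's dark band terminates exactly at the tip rather than
  extending a hemispherical cap, as a blunt delivery catheter does.
* **Renderer**: per-pixel analytic ray–solid chord lengths (slab/quadratic
  interval intersections; the tube via a KD-tree on the projected
  centerline, exact for parallel rays), mapped through
  `I = I₀ exp(−Σ μᵢ Lᵢ)` and scaled to 8-bit. Attenuation coefficients
  (bone 0.08/mm, posterior column 0.085/mm, catheter 0.45/mm) are free
  contrast parameters chosen so a vertebral body reads ≈0.2× background
  and the heart ≈0.9×, the qualitative appearance of a metal-coated
  phantom spine. Noise is additive Gaussian (default σ = 2 intensity
  units) plus an optional √I-proportional term and a linear background
  gradient; everything is a pure function of (arguments, seed).

What the phantom does **not** emulate: soft-tissue clutter, scatter, beam
hardening, cardiac/respiratory motion, perspective. Passing tests therefore
demonstrate the correctness and numerical behaviour of the chain, not
segmentation robustness on real patient images — the latter is a known open
problem for spine extraction from clinical fluoroscopy.

## Spine segmentation

Gaussian smoothing (σ = 2 px) → Otsu threshold keeping the dark side →
largest connected component → second Otsu restricted to that component's
bounding box → morphological closing (disk radius 3 px) → removal of
components below 100 px. The σ/radius/area defaults are free parameters
exposed in `SegmentationParams`. The dark-object convention is standard
fluoroscopic polarity; inverted frames must be inverted by the caller
(CLI `--invert`).

The CT-side reference projection is rendered as a noise-free attenuation
image of the spine solids and then binarized **with the same smoothing +
Otsu pipeline**. This matters: a purely geometric any-path>0 silhouette is
systematically wider than an intensity-thresholded mask wherever rays graze
a rotated body, and an unsmoothed threshold cuts a ramped edge a few pixels
outside a smoothed one. Binarizing both sides identically removes a
1–5 % anisotropic shape bias that would otherwise contaminate the
registration's scale estimate at oblique poses.

## Fourier–Mellin registration

Both images are zero-padded to a common power-of-two square, lightly
smoothed (σ = 1 px — the inputs are usually binary masks), windowed with a
raised cosine, and transformed. The centred spectral magnitude gets the
standard radial high-pass emphasis `(1−X)(2−X)`, `X = cos πf_x · cos πf_y`,
then is resampled on (θ, γ = log ρ) axes: 360 angular bins over 180°
(real-image magnitudes are centrally symmetric), 256 log-radial bins over
ρ ∈ [4 px, 0.9 · Nyquist]. Phase correlation of the two log-polar maps
gives (α, log k); peaks are refined by a 3×3 parabolic fit and unwrapped to
signed shifts.

Numerical safeguards, each of which was necessary on the phantom suite:

* **180° ambiguity** — both α and α+180° are tried; each candidate's
  translation is estimated and the winner is the candidate whose fully
  aligned overlay has the higher normalized cross-correlation (NCC), not
  the higher raw peak.
* **Periodicity aliases** — a stack of similar vertebrae produces strong
  correlation peaks one vertebral level apart. The top three translation
  peaks are each verified by overlay NCC.
* **Joint refinement** — with the bulk motion removed, the window weighs
  both images symmetrically, so residual (α, k) from the log-polar stage
  and residual translation become unbiased; up to four refinement passes
  run, and an update is accepted only if the overlay NCC improves
  (monotone refinement cannot drift onto an alias).

The recovered transform is reported in the homogeneous form above, mapping
moving (fluoroscopic) pixels into fixed (CT-projection) pixels. A
translation-peak height below 0.03 sets a `low_confidence` flag rather than
raising. On the packaged 512×512 spine silhouette, 100 random warps with
k ∈ [0.8, 1.25], α ∈ [−45°, 45°], |t| ≤ 64 px are recovered to better than
0.5 % scale, 0.1° and 0.25 px (the suite asserts 1 % / 0.5° / 0.5 px).

## Catheter tracking

The bottom ten rows are Otsu-binarized; among the dark objects the widest
seeds the trace (tie-break: the catheter is the widest dark structure
entering from below), with the direction initialized image-up. Each step
samples a profile 50 px across the current direction, averaged over 10 px
along it (averaging is the noise-robust reading of a single-profile
derivative plot), differentiates it, and takes the global minimum and
maximum of the derivative as the two edges — requiring the entering
(negative) edge before the exiting (positive) one and both above a contrast
floor (8 intensity/px). The midpoint is the centerline sample; the
direction update is clamped to 30°/step and exponentially smoothed
(weight 0.4 on the previous direction); the ROI advances 10 px.

On a contrast loss the tracer re-examines the last samples with a 2-px
averaging window (the wide window sees the band up to half its length past
the tip), trims any that fail, then creeps forward in 1 px steps until the
band vanishes or its width leaves [0.6, 1.5]× the running median — the
plausible-width rule. This places the reported tip within ~0.5 px of the
true band end instead of one ROI step short. Stop reasons (`lost_track`,
`out_of_bounds`, `max_steps`) are recorded, never silently bridged; frames
are traced independently (no temporal model).

## Biplane reconstruction and the precision statistic

Views rotated about Y share every point's detector row, so centerlines are
corresponded by interpolating each trace's x at a common row grid (0.25 mm
step) over the overlap of **all** views — every pair then estimates the
same physical samples. For a pair separated by θ (minimum 5°; row agreement
tolerance 0.5 mm = 2 px):

```
z₂ = (x₁ − x₂ cos θ) / sin θ,    y = (y₁ + y₂)/2,
```

and the view-2 point `(x₂, y, z₂)` is rotated back to the world frame.
This inverts the projection exactly (to machine precision) for noiseless
consistent inputs. With three views the admissible pairs are AP+LAO,
AP+RAO, LAO+RAO; the consensus curve is the per-row mean and the precision
of each sample is

```
MSE = (1/n_pairs) Σ |P_pair − P̄|   (Euclidean norm, mm),
```

deliberately the *mean absolute deviation*, not a squared error — the
statistic is reproduced exactly as printed in the clinical convention it
follows, and documented as a precision (pair-agreement) measure, not an
accuracy measure. With a single pair it is identically zero and the report
carries a `single_pair` caveat. Under detector noise σ the statistic is
linear in σ and matches closed-form linear propagation (Jacobians of the
pair estimates w.r.t. per-view detector noise) within the dispersion of a
finite suite; at σ = 0.25 mm with views (−30°, 0°, +30°) it comes out
around 0.3 mm.

## Per-view registration and the scene

Each view is registered independently — the patient may not lie identically
for CT and fluoroscopy, and a per-view in-plane similarity is exactly what
a 2-D method can correct. The pipeline applies each view's transform to
that view's centerline *before* triangulation; for a rigid patient shift
the corrected detector coordinates equal the true projections, so the
reconstruction lands in the CT model's frame with no residual. The
alternative reading (triangulate first, then average per-view corrected
curves) under-corrects depth components and is not used, but
`lift_transform_to_world` is provided for placing already-triangulated
geometry with a single view's transform; it needs the registered image size
because the transform's translation is expressed about the pixel origin.
Depth along each view axis is uncorrectable by construction; the scene
manifest records every view's transform and peak diagnostics so consumers
can see what was corrected.

The exported scene contains the anatomy meshes, the consensus curve with
ten key points sampled uniformly in arc length (rendered downstream as 4 mm
spheres), optional planned path and target rings, and a tip camera
(position = last point, forward = last segment direction, up = world Y
projected orthogonal). Output is viewer-agnostic STL + versioned JSON; AR
presentation (head-mounted display, voice/gesture control) is out of scope.

## Evaluation protocols

Registration error for one pair is the mean distance (mm) between
row-order-paired vertebra centroids of the fluoroscopic mask (mapped
through the recovered transform) and the CT reference projection. Row-order
pairing is robust for a vertically stacked spine; a mask whose vertebrae
merged is split at plateau-aware local minima of its row-width profile.
Failures of this bookkeeping count as evaluation errors, not method
failures. The packaged benchmark is 5 poses (AP, LAO30, LAO60, RAO30,
RAO60) × 7 warp/noise conditions = 35 pairs, warps k ∈ [0.9, 1.1],
|α| ≤ 10°, |t| ≤ 30 px, noise σ up to 4, all deterministic from one seed.
Success is classified at 5 mm — the radius of the clinically quoted safe
region around a transseptal puncture target — making an operator-judgment
protocol machine-readable. Per-image mean then grand mean is reported;
runtimes are recorded but never used in acceptance. External feature-based
registrars can be plugged in as callables returning a `RigidTransform2D`;
none are reimplemented here.

## Problem sizes and determinism

Default frames are 640×640 px (160 mm field of view; the registration
suites use 512×512), the recovery suite runs 100 warps, the benchmark 35
pairs, and reconstruction precision averages 5 noise realizations — sizes
chosen so the full study re-runs in about a minute on one CPU while keeping
every statistic's dispersion well below its tolerance. Every stochastic
component (phantom jitter, noise fields, warp draws) derives from explicit
seeds; equal seeds give bit-identical images and identical statistics.

## Known limitations

* Parallel-beam geometry; no cone-beam divergence or C-arm cranial/caudal
  angulation (rotation is about Y only).
* Static anatomy: no cardiac or respiratory motion, and no motion
  compensation.
* The segmentation is tuned to high-contrast spines (metal-coated phantom
  or bone against clean background); real patient frames with overlapping
  soft tissue will need stronger models.
* Single catheter per frame, ≥ 4 px wide; guidewires and multi-device
  scenes are out of scope.
* 2-D per-view registration cannot correct out-of-plane (depth) error or
  a patient rotation about Y between CT and fluoroscopy; the latter is not
  an in-plane similarity in any view.
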