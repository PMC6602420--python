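"""Build the synthetic phantom and render its projections.

Creates the five-vertebra spine phantom (T4-T8 with a posterior column and
an ellipsoidal heart shell), a spline catheter, and renders both a noisy
fluoroscopy-like frame and the CT-side reference projection at LAO30.
"""

import numpy as np

from fluoroguide import (
    CArmPose,
    PhantomNoiseSpec,
    default_catheter_curve,
    make_spine_phantom,
    render_fluoroscopy,
    render_reference_projection,
)

model = make_spine_phantom(jitter_mm=0.8, seed=7)
catheter = default_catheter_curve()
pose = CArmPose("LAO", 30)

fluoro = render_fluoroscopy(
    model, catheter, pose, spacing=0.25, size=(640, 640),
    noise=PhantomNoiseSpec(gaussian_sigma=2.0, seed=7),
)
reference = render_reference_projection(model, pose, 0.25, (640, 640))

print(f"vertebra centroids (mm, world frame):\n{model.vertebra_centroids.round(2)}")
print(f"catheter: {len(catheter)} samples, {catheter.length:.1f} mm arc, "
      f"tip at {catheter.tip.round(1)} mm")
print(f"fluoro frame: {fluoro.shape} px at {fluoro.spacing} mm/px, "
      f"intensities {fluoro.pixels.min():.0f}-{fluoro.pixels.max():.0f} "
      f"(dark spine on bright background)")
print(f"reference projection: {int(reference.pixels.sum())} spine pixels")
# The centroids are the ground truth against which registration errors are
# scored; the reference projection is the fixed image of the registration.
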