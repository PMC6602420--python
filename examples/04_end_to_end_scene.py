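"""Full guidance chain with a patient shift, exported as a 3-D scene.

The phantom is displaced by a few millimetres between the "CT" model and
the "fluoroscopy" renders, as a patient would be between acquisitions.
Per-view registration against the CT reference projections recovers the
shift, the catheter is traced and triangulated in the corrected frames, and
the registered scene (meshes, ten catheter key points, tip camera) is
written as STL + JSON for any 3-D viewer.
"""

import tempfile
import warnings
from pathlib import Path

import numpy as np

from fluoroguide import CArmPose, PhantomNoiseSpec, default_catheter_curve, make_spine_phantom
from fluoroguide.phantom import FieldOfViewWarning
from fluoroguide.pipeline import run_guidance
from fluoroguide.scene import write_scene

model = make_spine_phantom(jitter_mm=0.8, seed=7)
catheter = default_catheter_curve()

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FieldOfViewWarning)  # shifted curve clips the frame edge
    result = run_guidance(
        model,
        catheter,
        [CArmPose("AP"), CArmPose("LAO", 30), CArmPose("RAO", 30)],
        noise=PhantomNoiseSpec(gaussian_sigma=2.0, seed=2),
        misalignment_mm=(3.0, -2.0, 1.5),
    )

for view in result.views:
    t = view.registration.transform
    print(f"{view.pose}: registration k={t.k:.4f} alpha={t.alpha_deg:+.2f} deg "
          f"t=({t.tx:+.1f},{t.ty:+.1f}) px, "
          f"vertebra error {view.vertebra_error_mm.mean():.3f} mm")

tip_err = np.linalg.norm(result.tip_mm - catheter.tip)
print(f"\nmean vertebra registration error: {result.mean_vertebra_error_mm:.3f} mm")
print(f"catheter tip error after the corrected reconstruction: {tip_err:.3f} mm")

out = Path(tempfile.mkdtemp()) / "scene"
manifest = write_scene(result.scene, out)
print(f"scene written to {manifest}")
print(f"  key points: {len(result.scene.key_points)} (4 mm spheres downstream)")
print(f"  tip camera at {result.scene.tip_camera.position.round(1)} mm, "
      f"forward {result.scene.tip_camera.forward.round(3)}")
# Sub-millimetre vertebra and tip errors mean the catheter hologram would sit
# correctly inside the heart rendering despite the simulated patient shift.
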