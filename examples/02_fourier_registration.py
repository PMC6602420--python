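"""Fourier-Mellin registration of a warped spine image.

Warps the spine silhouette by a known similarity transform (scale, rotation,
translation), then recovers the transform with register().  The printed
errors show the subpixel/subdegree accuracy of the log-polar phase
correlation on this kind of input.
"""

import numpy as np

from fluoroguide import CArmPose, make_spine_phantom, register
from fluoroguide.projection import render_reference_projection
from fluoroguide.registration import _center_similarity_matrix, _warp_by

model = make_spine_phantom(jitter_mm=0.8, seed=7)
silhouette = np.asarray(
    render_reference_projection(model, CArmPose("AP"), 0.25, (512, 512)).pixels, float
)

k_true, alpha_true, t_true = 1.12, 17.0, (22.0, -35.0)  # px units
center = (255.5, 255.5)
gt = np.array(
    [[1, 0, t_true[0]], [0, 1, t_true[1]], [0, 0, 1.0]]
) @ _center_similarity_matrix(k_true, alpha_true, center)
moving = _warp_by(silhouette, np.linalg.inv(gt))

result = register(silhouette, moving)
t = result.transform
c = np.array([*center, 1.0])
t_center = (t.matrix @ c)[:2] - (_center_similarity_matrix(t.k, t.alpha_deg, center) @ c)[:2]

print(f"true : k={k_true:.4f}  alpha={alpha_true:+.2f} deg  t=({t_true[0]:+.1f},{t_true[1]:+.1f}) px")
print(f"found: k={t.k:.4f}  alpha={t.alpha_deg:+.2f} deg  "
      f"t=({t_center[0]:+.1f},{t_center[1]:+.1f}) px")
print(f"errors: scale {abs(t.k - k_true) / k_true * 100:.3f} %, "
      f"rotation {abs(t.alpha_deg - alpha_true):.3f} deg, "
      f"translation {np.abs(t_center - t_true).max():.3f} px")
print(f"translation correlation peak height: {result.translation_peak.height:.3f} "
      f"(low-confidence flag: {result.low_confidence})")
# Scale error < 1 %, rotation < 0.5 deg and translation < 0.5 px mean the
# registered overlay is aligned to a fraction of a millimetre at 0.25 mm/px.
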