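"""Pupil/glint extraction from a synthetic eye raster.

Renders a cropped eye image (dark elliptical pupil, two bright glints, pixel
noise), then recovers the features at subpixel resolution the way the online
tracking stage does: threshold segmentation, least-squares ellipse fit to the
pupil contour, intensity-weighted glint centroids.
"""

import numpy as np

from stereogaze.image_features import (
    SegmentationConfig,
    extract_glints,
    extract_pupil,
    pupil_glint_vector,
    render_eye_raster,
)

raster = render_eye_raster(
    pupil_center=(100.3, 60.7),
    pupil_axes=(20.0, 15.0),
    pupil_tilt_deg=25.0,
    glint_centers=[(92.5, 82.0), (112.2, 82.0)],
    noise_sd=2.0,
    seed=42,
)
config = SegmentationConfig()
pupil, params = extract_pupil(raster.image, config)
glints = extract_glints(raster.image, config)

print(f"true pupil center  : (100.30, 60.70) px")
print(f"fitted pupil center: ({pupil[0]:.2f}, {pupil[1]:.2f}) px, "
      f"semi-axes ({params['axes'][0]:.1f}, {params['axes'][1]:.1f}) px")
for g, t in zip(glints, raster.glint_centers):
    print(f"glint centroid ({g[0]:.2f}, {g[1]:.2f}) px, true ({t[0]:.1f}, {t[1]:.1f}), "
          f"error {np.hypot(*(g - t)):.3f} px")
print("pupil-glint vector (used for online feedback):",
      np.round(pupil_glint_vector(pupil, glints[0]), 2), "px")
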