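"""Mirror-based system calibration on synthetic observations.

The illuminators and the screen sit behind the cameras and are never imaged
directly; a planar mirror with a marker pattern makes their virtual images
visible. This script simulates the whole procedure and recovers the hidden
geometry.
"""

import numpy as np

import stereogaze as sg
from stereogaze.geometry import Plane, reflect_point
from stereogaze.system_calibration import (
    MarkerObservation,
    fit_mirror_plane,
    fit_screen_pose,
    localize_hidden_point,
)

geometry = sg.reference_rig()
mirror_true = Plane([55.0, 30.0, 400.0], [0.05, -0.08, -1.0])


def observe(point, marker_id, layout=None):
    return MarkerObservation(
        marker_id,
        geometry.camera1.project(point),
        geometry.camera2.project(point),
        layout,
    )


# markers physically attached to the mirror surface
e1 = np.cross(mirror_true.normal, [0.0, 1.0, 0.0])
e1 /= np.linalg.norm(e1)
e2 = np.cross(mirror_true.normal, e1)
markers = [
    observe(mirror_true.point + u * e1 + v * e2, i)
    for i, (u, v) in enumerate((u, v) for u in (-60, 0, 60) for v in (-60, 0, 60))
]
mirror, rms = fit_mirror_plane(markers, geometry)
print(f"mirror plane fitted from {len(markers)} markers, RMS {rms:.2e} mm")

# the cameras see the illuminators' virtual images in the mirror
for name, L in (("illuminator 1", geometry.illuminator1),
                ("illuminator 2", geometry.illuminator2)):
    obs = observe(reflect_point(L, mirror_true), name)
    found = localize_hidden_point(obs.pixel_cam1, obs.pixel_cam2, mirror, geometry)
    print(f"{name}: recovered {np.round(found, 4)} mm, "
          f"error {np.linalg.norm(found - L):.2e} mm")

# screen dots at known layout positions, observed via the mirror
dots = [
    observe(reflect_point(geometry.screen_point(x, y), mirror_true), f"dot{x}{y}", (x, y))
    for x in (-80.0, 0.0, 80.0) for y in (-60.0, 0.0, 60.0)
]
R, T, rms = fit_screen_pose(dots, mirror, geometry)
print(f"screen pose fitted, RMS {rms:.2e} mm; "
      f"rotation error {np.abs(R - geometry.screen_rotation).max():.2e}, "
      f"translation error {np.abs(T - geometry.screen_translation).max():.2e} mm")
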