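"""Fick-style gaze angle parameterization.

A unit gaze direction in the screen frame (x right, y up, +z out of the
screen toward the participant) is decomposed into a horizontal pan angle
theta and a vertical tilt angle phi:

    g = [cos(phi) sin(theta),  sin(phi),  -cos(phi) cos(theta)]

Straight-ahead gaze (into the screen) is (theta, phi) = (0, 0). The same
parameterization is used for the eye's optical axis, the visual axis, and
the simulator's scripted orientations, so that the visual/optical offsets
(alpha, beta) are additive in (theta, phi).
"""

from __future__ import annotations

import numpy as np

__all__ = ["direction_from_angles", "angles_from_direction"]


def direction_from_angles(theta_deg, phi_deg) -> np.ndarray:
    """Unit direction(s) from pan/tilt angles in degrees.

    Scalars give a (3,) vector, arrays an (N, 3) stack.
    """
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    ph = np.deg2rad(np.asarray(phi_deg, dtype=float))
    g = np.stack(
        [np.cos(ph) * np.sin(th), np.sin(ph), -np.cos(ph) * np.cos(th)],
        axis=-1,
    )
    return g


def angles_from_direction(g) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`direction_from_angles`; returns degrees.

    Works on a (3,) vector or an (N, 3) stack; the input need not be exactly
    unit length (it is normalized first).
    """
    v = np.asarray(g, dtype=float)
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    phi = np.arcsin(np.clip(v[..., 1], -1.0, 1.0))
    theta = np.arctan2(v[..., 0], -v[..., 2])
    return np.rad2deg(theta), np.rad2deg(phi)
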