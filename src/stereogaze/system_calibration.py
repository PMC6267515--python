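"""System geometry and its mirror-based calibration.

The two infrared illuminators and the stimulus screen sit behind the camera
pair and are never imaged directly. Their positions are recovered by placing
a planar front-surface mirror (carrying a dot marker pattern) in front of the
rig:

1. the physical markers on the mirror are triangulated from both cameras and
   a plane is fitted through them (total least squares) — this is the mirror
   pose;
2. each hidden point (illuminator, screen dot) is seen by both cameras as a
   virtual image behind the mirror; the virtual image is triangulated and
   reflected back across the mirror plane to give the real position;
3. the screen pose (rigid tracker -> screen transform) is fitted by
   orthogonal Procrustes between the reconstructed screen dots and their
   known layout on the screen surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    CameraModel,
    DegenerateGeometryError,
    Plane,
    _check_rotation,
    _vec3,
    reflect_point,
    triangulate,
    triangulate_many,
)

__all__ = [
    "SystemGeometry",
    "MarkerObservation",
    "CalibrationError",
    "fit_mirror_plane",
    "localize_hidden_point",
    "fit_screen_pose",
    "reference_rig",
]

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised for degenerate calibration input (too few / collinear markers)."""


@dataclass(frozen=True)
class SystemGeometry:
    """Full rig description in the tracker frame.

    ``screen_rotation`` (R) and ``screen_translation`` (T) map tracker-frame
    points into the stimulus (screen) frame: ``P_screen = R p + T``. The
    screen surface is the plane Z = 0 of the screen frame, with the origin at
    the screen center, x horizontal, y vertical and +z toward the participant.
    """

    camera1: CameraModel
    camera2: CameraModel
    illuminator1: np.ndarray
    illuminator2: np.ndarray
    screen_rotation: np.ndarray
    screen_translation: np.ndarray
    screen_resolution: np.ndarray = field(default_factory=lambda: np.array([1920.0, 1200.0]))
    pixel_pitch: float = 0.27

    def __post_init__(self):
        object.__setattr__(self, "illuminator1", _vec3(self.illuminator1, "illuminator1"))
        object.__setattr__(self, "illuminator2", _vec3(self.illuminator2, "illuminator2"))
        object.__setattr__(self, "screen_rotation", _check_rotation(self.screen_rotation))
        object.__setattr__(
            self, "screen_translation", _vec3(self.screen_translation, "screen_translation")
        )
        object.__setattr__(self, "screen_resolution", np.asarray(self.screen_resolution, float))
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def cameras(self) -> tuple[CameraModel, CameraModel]:
        return (self.camera1, self.camera2)

    @property
    def illuminators(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.illuminator1, self.illuminator2)

    # -- screen frame transforms ------------------------------------------

    def to_screen(self, p: np.ndarray) -> np.ndarray:
        """Tracker -> screen frame, for a (3,) point or (N, 3) stack."""
        P = np.asarray(p, dtype=float)
        return P @ self.screen_rotation.T + self.screen_translation

    def to_tracker(self, P: np.ndarray) -> np.ndarray:
        """Screen -> tracker frame (exact inverse of :meth:`to_screen`)."""
        Q = np.asarray(P, dtype=float)
        return (Q - self.screen_translation) @ self.screen_rotation

    def screen_point(self, x_mm: float, y_mm: float) -> np.ndarray:
        """Tracker-frame position of the screen-surface point (x, y, 0)."""
        return self.to_tracker(np.array([x_mm, y_mm, 0.0]))


def reference_rig() -> SystemGeometry:
    """A realistic desk rig used as the standard fixture.

    Two cameras ~12 cm apart, mounted below and slightly in front of the
    screen, both toed in on the expected eye position 65 cm from the screen;
    one illuminator ~6 cm outboard of each camera; a 1920 x 1200 px screen
    with 0.27 mm pixel pitch. The rig is laid out in the screen (stimulus)
    frame and converted into the tracker frame, which by definition has its
    origin at camera 1's nodal point and axes parallel to its image plane.
    These are fixture choices in the spirit of the original hardware, not
    claims about it.
    """
    focal_px = 16.0 / 0.0055  # 16 mm lens, 5.5 um pixels
    pp = np.array([524.0, 240.0])
    eye_region_w = np.array([0.0, 0.0, 650.0])  # screen frame
    # cameras ~10 cm in front of the screen, near the height of its lower edge
    cam1_w = np.array([-60.0, -160.0, 80.0])
    cam2_w = np.array([60.0, -160.0, 80.0])
    illum_w = [np.array([-120.0, -160.0, 80.0]), np.array([120.0, -160.0, 80.0])]

    cam1_world = CameraModel.looking_at(cam1_w, eye_region_w, focal_px, pp)
    cam2_world = CameraModel.looking_at(cam2_w, eye_region_w, focal_px, pp)
    R1 = cam1_world.rotation  # screen/world -> camera-1 frame == tracker frame

    def to_tracker(p_w):
        return R1 @ (p_w - cam1_w)

    cam1 = CameraModel(np.zeros(3), np.eye(3), focal_px, pp)
    cam2 = CameraModel(
        to_tracker(cam2_w), cam2_world.rotation @ R1.T, focal_px, pp
    )
    # tracker -> screen: p_screen = R1.T p_t + cam1_w (the rig was laid out
    # directly in the screen frame)
    return SystemGeometry(
        camera1=cam1,
        camera2=cam2,
        illuminator1=to_tracker(illum_w[0]),
        illuminator2=to_tracker(illum_w[1]),
        screen_rotation=R1.T,
        screen_translation=cam1_w,
    )


@dataclass(frozen=True)
class MarkerObservation:
    """One calibration marker seen by both cameras.

    ``layout_position`` is the marker's known 2-D position (mm) on the
    surface carrying it (mirror or screen); it is optional for mirror-pose
    markers and required for screen dots.
    """

    marker_id: int
    pixel_cam1: np.ndarray
    pixel_cam2: np.ndarray
    layout_position: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "pixel_cam1", np.asarray(self.pixel_cam1, float))
        object.__setattr__(self, "pixel_cam2", np.asarray(self.pixel_cam2, float))
        if self.layout_position is not None:
            object.__setattr__(self, "layout_position", np.asarray(self.layout_position, float))


def _triangulate_markers(markers: list[MarkerObservation], geometry: SystemGeometry) -> np.ndarray:
    px1 = np.array([m.pixel_cam1 for m in markers])
    px2 = np.array([m.pixel_cam2 for m in markers])
    o1, d1 = geometry.camera1.back_project_many(px1)
    o2, d2 = geometry.camera2.back_project_many(px2)
    pts, _resid, ok = triangulate_many(o1, d1, o2, d2)
    if not np.all(ok):
        raise DegenerateGeometryError("degenerate triangulation for one or more markers")
    return pts


def fit_mirror_plane(
    markers: list[MarkerObservation], geometry: SystemGeometry
) -> tuple[Plane, float]:
    """Triangulate mirror markers and fit a total-least-squares plane.

    Returns the plane and the RMS point-to-plane distance of the triangulated
    markers (mm). The plane normal is oriented toward the cameras (negative
    z component in the tracker frame) for reproducibility.
    """
    if len(markers) < 3:
        raise CalibrationError("mirror plane fit needs at least 3 markers")
    pts = _triangulate_markers(markers, geometry)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # smallest right singular vector = normal of the TLS plane
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise CalibrationError("mirror markers are collinear; plane fit is degenerate")
    normal = vt[2]
    if normal[2] > 0:
        normal = -normal
    plane = Plane(centroid, normal)
    rms = float(np.sqrt(np.mean(((centered @ plane.normal) ** 2))))
    log.info("mirror plane fit: %d markers, RMS point-to-plane %.6f mm", len(pts), rms)
    return plane, rms


def localize_hidden_point(
    pixel_cam1,
    pixel_cam2,
    mirror: Plane,
    geometry: SystemGeometry,
) -> np.ndarray:
    """Recover a hidden point from its virtual image in the mirror.

    The two pixels are the images of the *virtual* point behind the mirror;
    it is triangulated and reflected back across the mirror plane.
    """
    virtual, _resid = triangulate(
        geometry.camera1.back_project(pixel_cam1),
        geometry.camera2.back_project(pixel_cam2),
    )
    return reflect_point(virtual, mirror)


def fit_screen_pose(
    dot_observations: list[MarkerObservation],
    mirror: Plane,
    geometry: SystemGeometry,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit the rigid tracker -> screen transform from screen-dot images.

    Each observation must carry its ``layout_position`` (x, y) in mm on the
    screen surface. The dots' virtual images are triangulated, reflected into
    real space, and the rotation/translation minimizing the RMS distance to
    the layout positions (at Z = 0) is found by orthogonal Procrustes
    (Kabsch).

    Returns (screen_rotation, screen_translation, rms_mm).
    """
    if len(dot_observations) < 3:
        raise CalibrationError("screen pose fit needs at least 3 dots")
    if any(m.layout_position is None for m in dot_observations):
        raise CalibrationError("screen dots must have layout positions")
    virtual = _triangulate_markers(dot_observations, geometry)
    from .geometry import reflect_points

    real = reflect_points(virtual, mirror)
    layout = np.array(
        [[*m.layout_position, 0.0] for m in dot_observations], dtype=float
    )

    q_bar = real.mean(axis=0)
    s_bar = layout.mean(axis=0)
    Q = real - q_bar
    S = layout - s_bar
    # collinearity check: a rigid transform is not identifiable from a line
    sv = np.linalg.svd(Q, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise CalibrationError("screen dots are collinear; pose fit is degenerate")
    H = Q.T @ S
    U, _s, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    T = s_bar - R @ q_bar
    rms = float(np.sqrt(np.mean(np.sum((real @ R.T + T - layout) ** 2, axis=1))))
    log.info("screen pose fit: %d dots, RMS %.6f mm", len(dot_observations), rms)
    return R, T, rms
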