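"""3-D primitives for the stereo rig.

Everything downstream — mirror calibration, glint geometry, gaze
reconstruction — is built from four operations defined here: least-squares
"intersection" (triangulation) of two skew lines, reflection of a point in a
plane, and pinhole projection / back-projection.

Conventions
-----------
* All lengths are millimetres; angles at API boundaries are degrees.
* The tracker coordinate frame has its origin at the nodal point of camera 1,
  x/y parallel to that camera's image plane, and +z pointing away from the
  cameras, toward the participant.
* A camera's ``rotation`` maps tracker-frame vectors into the camera frame;
  the camera looks along its own +z axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "ProjectionError",
    "Ray",
    "Plane",
    "CameraModel",
    "triangulate",
    "triangulate_many",
    "reflect_point",
    "reflect_points",
]

# |cos| between two line directions above which triangulation is refused
PARALLEL_COS_LIMIT = 1.0 - 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when a geometric construction has no usable solution
    (parallel rays, collinear calibration markers, ...)."""


class ProjectionError(ValueError):
    """Raised when a point cannot be imaged (at or behind the nodal plane)."""


def _vec3(x, name: str = "vector") -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must have finite components: {v}")
    return v


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize the zero vector")
    return v / n


@dataclass(frozen=True)
class Ray:
    """A half-infinite line: ``origin + lambda * direction`` (direction is unit)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _vec3(self.origin, "origin"))
        object.__setattr__(self, "direction", _unit(_vec3(self.direction, "direction")))

    def point_at(self, lam: float) -> np.ndarray:
        return self.origin + lam * self.direction


@dataclass(frozen=True)
class Plane:
    """A plane given by one point on it and its unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", _vec3(self.point, "point"))
        object.__setattr__(self, "normal", _unit(_vec3(self.normal, "normal")))

    def signed_distance(self, p) -> float:
        return float(np.dot(_vec3(p) - self.point, self.normal))


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation matrix must have det +1 (got a reflection)")
    return R


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera.

    Parameters
    ----------
    nodal_point : (3,) mm, tracker frame
    rotation : (3, 3) orthonormal, tracker -> camera
    focal_length : pixels
    principal_point : (2,) pixels
    sensor_size : (2,) pixels (width, height)
    """

    nodal_point: np.ndarray
    rotation: np.ndarray
    focal_length: float
    principal_point: np.ndarray
    sensor_size: np.ndarray = field(default_factory=lambda: np.array([1048.0, 480.0]))

    def __post_init__(self):
        object.__setattr__(self, "nodal_point", _vec3(self.nodal_point, "nodal_point"))
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        object.__setattr__(self, "focal_length", float(self.focal_length))
        pp = np.asarray(self.principal_point, dtype=float)
        if pp.shape != (2,):
            raise ValueError("principal_point must be a 2-vector")
        object.__setattr__(self, "principal_point", pp)
        object.__setattr__(self, "sensor_size", np.asarray(self.sensor_size, dtype=float))
        if self.focal_length <= 0:
            raise ValueError("focal_length must be positive")

    @classmethod
    def looking_at(
        cls,
        nodal_point,
        target,
        focal_length: float,
        principal_point,
        sensor_size=(1048.0, 480.0),
        up=(0.0, 1.0, 0.0),
    ) -> "CameraModel":
        """Construct a camera at ``nodal_point`` whose optical axis passes
        through ``target``, with its image x axis horizontal w.r.t. ``up``."""
        nodal = _vec3(nodal_point, "nodal_point")
        z = _unit(_vec3(target, "target") - nodal)
        x = _unit(np.cross(_vec3(up, "up"), z))
        y = np.cross(z, x)
        R = np.vstack([x, y, z])  # rows are camera axes in tracker coords
        return cls(nodal, R, focal_length, principal_point, sensor_size)

    # -- projection ---------------------------------------------------------

    def to_camera_frame(self, p) -> np.ndarray:
        return self.rotation @ (_vec3(p) - self.nodal_point)

    def project(self, p) -> np.ndarray:
        """Project a tracker-frame point to pixel coordinates.

        Raises :class:`ProjectionError` for points at or behind the camera.
        """
        q = self.to_camera_frame(p)
        if q[2] <= 0:
            raise ProjectionError(f"point {p} is not in front of the camera (depth {q[2]:.3f} mm)")
        return self.principal_point + self.focal_length * q[:2] / q[2]

    def project_many(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized projection of an (N, 3) array.

        Returns (pixels (N, 2), in_front (N,) bool). Pixels of points that are
        not strictly in front of the camera are NaN.
        """
        P = np.asarray(points, dtype=float).reshape(-1, 3)
        Q = (P - self.nodal_point) @ self.rotation.T
        depth = Q[:, 2]
        in_front = depth > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            px = self.principal_point + self.focal_length * Q[:, :2] / depth[:, None]
        px[~in_front] = np.nan
        return px, in_front

    def on_sensor(self, px: np.ndarray) -> np.ndarray:
        px = np.atleast_2d(np.asarray(px, dtype=float))
        ok = (
            np.isfinite(px).all(axis=1)
            & (px[:, 0] >= 0)
            & (px[:, 0] <= self.sensor_size[0])
            & (px[:, 1] >= 0)
            & (px[:, 1] <= self.sensor_size[1])
        )
        return ok

    def back_project(self, px) -> Ray:
        """Ray from the nodal point through the given pixel."""
        px = np.asarray(px, dtype=float)
        if px.shape != (2,) or not np.all(np.isfinite(px)):
            raise ValueError(f"pixel must be a finite 2-vector, got {px}")
        d_cam = np.array(
            [
                (px[0] - self.principal_point[0]) / self.focal_length,
                (px[1] - self.principal_point[1]) / self.focal_length,
                1.0,
            ]
        )
        d = self.rotation.T @ d_cam
        return Ray(self.nodal_point, d)

    def back_project_many(self, pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized back-projection: (N, 2) pixels -> (origins (N,3), unit dirs (N,3))."""
        px = np.asarray(pixels, dtype=float).reshape(-1, 2)
        d_cam = np.column_stack(
            [
                (px[:, 0] - self.principal_point[0]) / self.focal_length,
                (px[:, 1] - self.principal_point[1]) / self.focal_length,
                np.ones(len(px)),
            ]
        )
        d = d_cam @ self.rotation  # == (R.T @ d_cam.T).T
        with np.errstate(invalid="ignore"):
            d = d / np.linalg.norm(d, axis=1, keepdims=True)
        origins = np.broadcast_to(self.nodal_point, d.shape).copy()
        return origins, d


# -- two-line least squares --------------------------------------------------


def triangulate_many(
    o1: np.ndarray,
    d1: np.ndarray,
    o2: np.ndarray,
    d2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form midpoint triangulation, vectorized over (N, 3) arrays.

    For each pair of lines ``o + lambda*d`` the 2x2 normal equations of the
    line parameters are solved exactly; the midpoint of the shortest
    connecting segment and its length (residual) are returned, together with
    an ``ok`` mask that is False for (near-)parallel pairs.
    """
    o1 = np.atleast_2d(np.asarray(o1, float))
    d1 = np.atleast_2d(np.asarray(d1, float))
    o2 = np.atleast_2d(np.asarray(o2, float))
    d2 = np.atleast_2d(np.asarray(d2, float))
    d1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
    d2 = d2 / np.linalg.norm(d2, axis=1, keepdims=True)

    b = o2 - o1
    d12 = np.einsum("ij,ij->i", d1, d2)
    d1b = np.einsum("ij,ij->i", d1, b)
    d2b = np.einsum("ij,ij->i", d2, b)
    denom = 1.0 - d12**2
    ok = np.abs(d12) < PARALLEL_COS_LIMIT
    ok &= np.isfinite(denom) & np.isfinite(d1b) & np.isfinite(d2b)
    safe = np.where(ok, denom, 1.0)
    lam1 = (d1b - d12 * d2b) / safe
    lam2 = (d12 * d1b - d2b) / safe
    p1 = o1 + lam1[:, None] * d1
    p2 = o2 + lam2[:, None] * d2
    mid = 0.5 * (p1 + p2)
    resid = np.linalg.norm(p1 - p2, axis=1)
    mid[~ok] = np.nan
    resid[~ok] = np.nan
    return mid, resid, ok


def triangulate(ray_a: Ray, ray_b: Ray) -> tuple[np.ndarray, float]:
    """Least-squares "intersection" of two 3-D lines.

    Returns the midpoint of the unique shortest segment between the lines and
    the segment length (0 for truly intersecting rays).

    Raises
    ------
    DegenerateGeometryError
        If the rays are parallel or nearly so (|cos| >= 1 - 1e-9): such
        geometry never occurs in a sane rig and signals corrupt input.
    """
    mid, resid, ok = triangulate_many(
        ray_a.origin, ray_a.direction, ray_b.origin, ray_b.direction
    )
    if not ok[0]:
        raise DegenerateGeometryError(
            "rays are (near-)parallel; two-line intersection is degenerate"
        )
    return mid[0], float(resid[0])


# -- mirror reflection --------------------------------------------------------


def reflect_points(points: np.ndarray, mirror: Plane) -> np.ndarray:
    """Mirror-image of each row of an (N, 3) array across a plane."""
    P = np.atleast_2d(np.asarray(points, float))
    d = (P - mirror.point) @ mirror.normal
    return P - 2.0 * d[:, None] * mirror.normal


def reflect_point(p, mirror: Plane) -> np.ndarray:
    """Mirror-image of a single point across a plane (an involution)."""
    return reflect_points(_vec3(p), mirror)[0]
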