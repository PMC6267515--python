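"""Forward ray-tracing simulator of the eye + stereo rig.

Generates the two cameras' feature streams (pupil and glint pixel
coordinates) together with ground truth, with the statistical structure the
gaze reconstruction assumes:

* a spherical anterior cornea that forms glints as a convex mirror
  (specular points solved exactly in the plane containing illuminator,
  camera and corneal center);
* a pupil imaged either directly (``no_refraction`` — makes the inverse
  problem exact for round-trip tests) or through Snell refraction at the
  corneal surface (``snell`` — reproduces the systematic variation of the
  apparent corneal-center-to-pupil distance that the gain correction
  targets);
* a visual axis offset from the optical axis by (alpha, beta);
* an eye that rotates about a fixed rotation center behind the cornea, so
  head position and gaze both move the corneal center;
* two asynchronously, jittered-rate sampling cameras and isotropic Gaussian
  pixel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .angles import angles_from_direction, direction_from_angles
from .geometry import CameraModel, Plane, _unit, _vec3
from .system_calibration import SystemGeometry

__all__ = [
    "EyeParameters",
    "EyePose",
    "TargetEvent",
    "TrialScript",
    "NoGlintError",
    "specular_point",
    "glint_pixel",
    "pupil_pixel",
    "render_features",
    "simulate_fixation",
    "simulate_trial",
    "target_grid",
    "pose_for_target",
    "peak_velocity_main_sequence",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "timestamp_s",
    "cam",
    "eye",
    "pupil_x",
    "pupil_y",
    "glint1_x",
    "glint1_y",
    "glint2_x",
    "glint2_y",
    "valid",
]


class NoGlintError(RuntimeError):
    """No specular path exists on the camera-facing corneal hemisphere."""


@dataclass(frozen=True)
class EyeParameters:
    """Schematic-eye anatomy (standard values; fixture choices).

    ``K_true`` is the distance from the corneal curvature center to the pupil
    center along the optical axis; ``rotation_center_distance`` the distance
    from the eye's rotation center forward to the corneal curvature center.
    ``alpha``/``beta`` are the horizontal/vertical angles from the optical to
    the visual axis, additive in the Fick parameterization.
    """

    corneal_radius: float = 7.8  # mm
    K_true: float = 4.2  # mm
    alpha: float = 5.0  # deg
    beta: float = 1.5  # deg
    pupil_radius: float = 2.0  # mm
    refractive_index: float = 1.3375
    rotation_center_distance: float = 5.7  # mm
    # the cornea is a spherical cap, not a full sphere: surface points farther
    # than this from the optical axis cannot form glints or refract the pupil
    corneal_cap_deg: float = 50.0
    # beyond this viewing obliquity the iris occludes the pupil
    pupil_visibility_deg: float = 70.0

    def __post_init__(self):
        if self.corneal_radius <= 0 or self.K_true <= 0:
            raise ValueError("corneal_radius and K_true must be positive")


@dataclass(frozen=True)
class EyePose:
    """Instantaneous eye state in the tracker frame."""

    corneal_center: np.ndarray  # mm
    optical_axis: np.ndarray  # unit vector, pointing from the eye toward the screen

    def __post_init__(self):
        object.__setattr__(self, "corneal_center", _vec3(self.corneal_center))
        object.__setattr__(self, "optical_axis", _unit(_vec3(self.optical_axis)))

    def pupil_center(self, eye: EyeParameters) -> np.ndarray:
        return self.corneal_center + eye.K_true * self.optical_axis


# ---------------------------------------------------------------------------
# planar root solvers on the corneal sphere
# ---------------------------------------------------------------------------


def _bisect(f, lo: np.ndarray, hi: np.ndarray, iters: int = 70) -> np.ndarray:
    """Vectorized bisection for a sign change bracketed by (lo, hi)."""
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        take_lo = np.sign(fm) == np.sign(flo)
        lo = np.where(take_lo, mid, lo)
        flo = np.where(take_lo, fm, flo)
        hi = np.where(take_lo, hi, mid)
    return 0.5 * (lo + hi)


def _plane_basis(centers: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Orthonormal in-plane basis (e1 toward ``a``) for spheres at ``centers``.

    Returns e1, e2, delta (angle between the directions of a and b seen from
    the center) and a mask of degenerate (collinear) rows.
    """
    u = a - centers
    v = b - centers
    nu = np.linalg.norm(u, axis=1, keepdims=True)
    nv = np.linalg.norm(v, axis=1, keepdims=True)
    e1 = u / nu
    w = v - (np.einsum("ij,ij->i", v, e1))[:, None] * e1
    nw = np.linalg.norm(w, axis=1)
    degenerate = nw < 1e-12 * nv[:, 0]
    e2 = np.where(degenerate[:, None], 0.0, w / np.where(degenerate, 1.0, nw)[:, None])
    cosd = np.clip(np.einsum("ij,ij->i", u / nu, v / nv), -1.0, 1.0)
    delta = np.arccos(cosd)
    return e1, e2, delta, degenerate


def _specular_points_many(
    centers: np.ndarray, radius: float, illuminator: np.ndarray, camera_point: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Specular reflection points on spheres (convex mirror).

    For each sphere center, finds the surface point s where the path
    illuminator -> s -> camera satisfies the reflection law, by locating the
    stationary point of the path length (Fermat) in the plane spanned by the
    three points. Returns (points (N, 3), ok (N,)).
    """
    C = np.atleast_2d(np.asarray(centers, float))
    a = np.asarray(illuminator, float)
    b = np.asarray(camera_point, float)
    n = len(C)
    e1, e2, delta, degen = _plane_basis(C, np.broadcast_to(a, C.shape), np.broadcast_to(b, C.shape))

    # outside-sphere requirement
    ok = (np.linalg.norm(a - C, axis=1) > radius) & (np.linalg.norm(b - C, axis=1) > radius)

    def surface(psi):
        return C + radius * (np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2)

    def dpath(psi):
        s = surface(psi)
        t = radius * (-np.sin(psi)[:, None] * e1 + np.cos(psi)[:, None] * e2)
        ra = a - s
        rb = b - s
        return -(
            np.einsum("ij,ij->i", ra, t) / np.linalg.norm(ra, axis=1)
            + np.einsum("ij,ij->i", rb, t) / np.linalg.norm(rb, axis=1)
        )

    lo = np.zeros(n)
    hi = np.where(degen, 1e-12, delta)
    psi = _bisect(dpath, lo, hi)
    # retro-reflective / collinear case: surface point on the line toward both
    psi = np.where(degen, 0.0, psi)
    s = surface(psi)
    # the specular point must face the camera
    normal = (s - C) / radius
    ok &= np.einsum("ij,ij->i", b - s, normal) > 0
    return s, ok


def _snell_entry_points_many(
    centers: np.ndarray,
    pupils: np.ndarray,
    radius: float,
    n_index: float,
    camera_point: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Corneal entry point of the chief ray camera -> pupil center.

    Finds the surface point s such that the ray from the camera nodal point,
    refracted into the eye at s per Snell's law (outside index 1, inside
    ``n_index``), passes through the pupil center. By symmetry of refraction
    the problem is planar (plane of camera, corneal center, pupil center).
    """
    C = np.atleast_2d(np.asarray(centers, float))
    P = np.atleast_2d(np.asarray(pupils, float))
    o = np.asarray(camera_point, float)
    n = len(C)
    mu = 1.0 / n_index

    e1, e2, _delta, degen = _plane_basis(C, np.broadcast_to(o, C.shape), P)
    ok = np.linalg.norm(o - C, axis=1) > radius

    def miss(psi):
        """Signed in-plane miss distance of the refracted ray w.r.t. the pupil."""
        cp, sp = np.cos(psi), np.sin(psi)
        s = C + radius * (cp[:, None] * e1 + sp[:, None] * e2)
        i = s - o
        i = i / np.linalg.norm(i, axis=1, keepdims=True)
        nrm = (s - C) / radius
        c1 = -np.einsum("ij,ij->i", i, nrm)
        c1c = np.clip(c1, 1e-9, 1.0)
        c2 = np.sqrt(np.maximum(1.0 - mu**2 * (1.0 - c1c**2), 0.0))
        t = mu * i + (mu * c1c - c2)[:, None] * nrm
        d = P - s
        # z-component of the in-plane cross product t x d
        t1 = np.einsum("ij,ij->i", t, e1)
        t2 = np.einsum("ij,ij->i", t, e2)
        d1 = np.einsum("ij,ij->i", d, e1)
        d2 = np.einsum("ij,ij->i", d, e2)
        out = t1 * d2 - t2 * d1
        # mark grazing/invalid incidence so the scan skips it
        out[c1 <= 1e-9] = np.nan
        return out

    # coarse scan for a sign-change bracket, then bisection
    grid = np.linspace(0.0, 1.2, 121)
    vals = np.empty((len(grid), n))
    for k, g in enumerate(grid):
        vals[k] = miss(np.full(n, g))
    sign = np.sign(vals)
    flips = (sign[:-1] * sign[1:]) < 0
    has = flips.any(axis=0)
    first = np.argmax(flips, axis=0)
    lo = grid[np.where(has, first, 0)]
    hi = grid[np.where(has, first + 1, 1)]
    psi = _bisect(lambda p: np.nan_to_num(miss(p), nan=1.0), lo, hi)
    psi = np.where(degen, 0.0, psi)
    ok &= has | degen
    s = C + radius * (np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2)
    # validate the root: refraction must be physical and the refracted ray
    # must reach the pupil forward, not on its backward extension
    i = s - o
    i = i / np.linalg.norm(i, axis=1, keepdims=True)
    nrm = (s - C) / radius
    c1 = -np.einsum("ij,ij->i", i, nrm)
    c2 = np.sqrt(np.maximum(1.0 - mu**2 * (1.0 - np.clip(c1, 0, 1) ** 2), 0.0))
    t = mu * i + (mu * np.clip(c1, 0, 1) - c2)[:, None] * nrm
    d = P - s
    dist = np.linalg.norm(d, axis=1)
    along = np.einsum("ij,ij->i", t, d)
    perp = np.sqrt(np.maximum(dist**2 - along**2, 0.0))
    ok &= (c1 > 1e-9) & (along > 0) & (perp < 1e-6 * np.maximum(dist, 1.0))
    return s, ok


# ---------------------------------------------------------------------------
# single-frame feature formation
# ---------------------------------------------------------------------------


def specular_point(
    pose: EyePose, eye: EyeParameters, camera: CameraModel, illuminator
) -> np.ndarray:
    """Surface point on the cornea satisfying the reflection law for the
    illuminator -> cornea -> camera-nodal-point path."""
    s, ok = _specular_points_many(
        pose.corneal_center[None, :], eye.corneal_radius, _vec3(illuminator), camera.nodal_point
    )
    if not ok[0]:
        raise NoGlintError("no specular path on the camera-facing hemisphere")
    return s[0]


def glint_pixel(pose: EyePose, eye: EyeParameters, camera: CameraModel, illuminator) -> np.ndarray:
    """Pixel coordinates of the glint caused by one illuminator."""
    return camera.project(specular_point(pose, eye, camera, illuminator))


def pupil_pixel(
    pose: EyePose, eye: EyeParameters, camera: CameraModel, mode: str = "no_refraction"
) -> np.ndarray:
    """Pixel coordinates of the (virtual) pupil center.

    ``no_refraction`` projects the true pupil center directly; ``snell``
    projects the corneal entry point of the refracted chief ray, i.e. what a
    pinhole camera actually images.
    """
    if mode == "no_refraction":
        return camera.project(pose.pupil_center(eye))
    if mode == "snell":
        s, ok = _snell_entry_points_many(
            pose.corneal_center[None, :],
            pose.pupil_center(eye)[None, :],
            eye.corneal_radius,
            eye.refractive_index,
            camera.nodal_point,
        )
        if not ok[0]:
            raise NoGlintError("no refracted chief ray reaches the pupil center")
        return camera.project(s[0])
    raise ValueError(f"unknown pupil imaging mode {mode!r}")


def _render_camera_features(
    centers: np.ndarray,
    pupils: np.ndarray,
    eye: EyeParameters,
    camera: CameraModel,
    geometry: SystemGeometry,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free feature pixels for one camera over N poses.

    Returns (features (N, 6): pupil, glint1, glint2 pixels; valid (N,)).
    """
    n = len(centers)
    axes = (pupils - centers) / eye.K_true
    cap_cos = np.cos(np.deg2rad(eye.corneal_cap_deg))

    def within_cap(surface_pts):
        u = (surface_pts - centers) / eye.corneal_radius
        return np.einsum("ij,ij->i", u, axes) > cap_cos

    if mode == "no_refraction":
        ppx, p_ok = camera.project_many(pupils)
        view = camera.nodal_point - centers
        view = view / np.linalg.norm(view, axis=1, keepdims=True)
        p_ok &= np.einsum("ij,ij->i", view, axes) > np.cos(
            np.deg2rad(eye.pupil_visibility_deg)
        )
    else:
        s, ok_s = _snell_entry_points_many(
            centers, pupils, eye.corneal_radius, eye.refractive_index, camera.nodal_point
        )
        ppx, p_ok = camera.project_many(s)
        p_ok &= ok_s & within_cap(s)
    feats = np.full((n, 6), np.nan)
    feats[:, 0:2] = ppx
    valid = p_ok & camera.on_sensor(ppx)
    for j, illum in enumerate(geometry.illuminators):
        s, ok_g = _specular_points_many(centers, eye.corneal_radius, illum, camera.nodal_point)
        gpx, g_ok = camera.project_many(s)
        feats[:, 2 + 2 * j : 4 + 2 * j] = gpx
        valid &= ok_g & g_ok & camera.on_sensor(gpx) & within_cap(s)
    return feats, valid


def render_features(
    pose: EyePose,
    eye: EyeParameters,
    geometry: SystemGeometry,
    mode: str = "no_refraction",
    pixel_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    timestamp: float = 0.0,
    eye_label: str = "right",
) -> pd.DataFrame:
    """One feature frame per camera for a single eye pose.

    Features that fall off the sensor, or for which no specular/refracted
    path exists, make the frame invalid rather than raising.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for cam_id, camera in enumerate(geometry.cameras, start=1):
        feats, valid = _render_camera_features(
            pose.corneal_center[None, :], pose.pupil_center(eye)[None, :], eye, camera, geometry, mode
        )
        f = feats[0]
        if pixel_noise_sd > 0:
            f = f + rng.normal(0.0, pixel_noise_sd, size=6)
        rows.append([timestamp, cam_id, eye_label, *f, bool(valid[0])])
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


# ---------------------------------------------------------------------------
# scripted poses
# ---------------------------------------------------------------------------


def _poses_from_visual_angles(
    geometry: SystemGeometry,
    eye: EyeParameters,
    theta_v: np.ndarray,
    phi_v: np.ndarray,
    rotation_center_screen: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Eye state for given visual-axis angles (screen frame).

    Returns tracker-frame corneal centers and pupil centers, plus the true
    POG (mm, screen) and the screen-frame corneal centers.
    """
    theta_e = np.asarray(theta_v, float) - eye.alpha
    phi_e = np.asarray(phi_v, float) - eye.beta
    axis_s = direction_from_angles(theta_e, phi_e)  # optical axis, screen frame
    E = np.asarray(rotation_center_screen, float)
    c_s = E + eye.rotation_center_distance * axis_s
    g = direction_from_angles(theta_v, phi_v)  # visual axis, screen frame
    lam = c_s[..., 2] / -g[..., 2]
    pog = c_s[..., :2] + lam[..., None] * g[..., :2]
    c_t = geometry.to_tracker(c_s)
    pupil_t = geometry.to_tracker(c_s + eye.K_true * axis_s)
    return c_t, pupil_t, pog, c_s


def _visual_angles_for_target(
    eye: EyeParameters, target_xy, rotation_center_screen
) -> tuple[float, float]:
    """Visual-axis angles that put the POG on the target (screen frame).

    The corneal center depends on the optical axis, which depends on the
    angles being solved for; a short fixed-point iteration converges because
    the rotation-center-to-cornea distance is tiny compared with the viewing
    distance.
    """
    E = np.asarray(rotation_center_screen, float)
    target = np.array([target_xy[0], target_xy[1], 0.0])
    c = E.copy()
    theta_v = phi_v = 0.0
    for _ in range(50):
        g = _unit(target - c)
        theta_v, phi_v = angles_from_direction(g)
        axis = direction_from_angles(theta_v - eye.alpha, phi_v - eye.beta)
        c_new = E + eye.rotation_center_distance * axis
        if np.linalg.norm(c_new - c) < 1e-13:
            c = c_new
            break
        c = c_new
    return float(theta_v), float(phi_v)


def pose_for_target(
    geometry: SystemGeometry,
    eye: EyeParameters,
    target_xy,
    rotation_center_screen=(0.0, 0.0, 650.0),
) -> EyePose:
    """Eye pose (tracker frame) fixating a screen target (mm)."""
    th, ph = _visual_angles_for_target(eye, target_xy, rotation_center_screen)
    c_t, pupil_t, _pog, _cs = _poses_from_visual_angles(
        geometry, eye, np.array([th]), np.array([ph]), np.asarray(rotation_center_screen, float)
    )
    axis = _unit(pupil_t[0] - c_t[0])
    return EyePose(c_t[0], axis)


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetEvent:
    """One stimulus step: target shown at (x, y) mm from ``onset_s``."""

    x_mm: float
    y_mm: float
    onset_s: float


@dataclass(frozen=True)
class TrialScript:
    """Scripted stimulus/eye behaviour for one simulated recording.

    Defaults mirror the validation-study conditions: two cameras near 330 and
    300 Hz with +/-10 % frame-interval jitter, saccades whose peak velocity
    follows the main-sequence law with v0 = 500 deg/s and Amp0 = 5 deg, and a
    saccade latency of 180 ms.
    """

    targets: tuple[TargetEvent, ...]
    duration_s: float
    head_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))  # mm, screen frame
    v0: float = 500.0  # deg/s
    amp0: float = 5.0  # deg
    latency_s: float = 0.18
    camera_rates: tuple[float, float] = (330.0, 300.0)
    pixel_noise_sd: float = 0.1  # px
    mode: str = "no_refraction"
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "head_offset", np.asarray(self.head_offset, float))
        if any(r <= 0 for r in self.camera_rates):
            raise ValueError("camera rates must be positive")
        onsets = [t.onset_s for t in self.targets]
        if sorted(onsets) != onsets:
            raise ValueError("target onsets must be increasing")


def peak_velocity_main_sequence(amplitude_deg, v0: float, amp0: float):
    """Saturating-exponential main sequence: v_peak = v0 (1 - exp(-Amp/Amp0))."""
    return v0 * (1.0 - np.exp(-np.asarray(amplitude_deg, float) / amp0))


def _raised_cosine_progress(t: np.ndarray, duration: float) -> np.ndarray:
    """Normalized position profile of a raised-cosine-velocity movement."""
    x = np.clip(t / duration, 0.0, 1.0)
    return x - np.sin(2.0 * np.pi * x) / (2.0 * np.pi)


def _angle_timeline(
    script: TrialScript, eye: EyeParameters, rotation_center_screen: np.ndarray
) -> tuple[list[tuple[float, float, float, np.ndarray, np.ndarray]], np.ndarray]:
    """Piecewise saccade plan: (start, duration, amplitude, from_angles, to_angles)."""
    angles = [
        np.array(_visual_angles_for_target(eye, (ev.x_mm, ev.y_mm), rotation_center_screen))
        for ev in script.targets
    ]
    plan = []
    for k in range(1, len(script.targets)):
        a_from, a_to = angles[k - 1], angles[k]
        amp = float(np.hypot(*(a_to - a_from)))
        if amp == 0.0:
            continue
        v_peak = float(peak_velocity_main_sequence(amp, script.v0, script.amp0))
        duration = 2.0 * amp / v_peak
        start = script.targets[k].onset_s + script.latency_s
        plan.append((start, duration, amp, a_from, a_to))
    return plan, angles[0]


def _angles_at(
    t: np.ndarray, plan, first_angles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    theta = np.full(t.shape, first_angles[0])
    phi = np.full(t.shape, first_angles[1])
    for start, duration, _amp, a_from, a_to in plan:
        prog = _raised_cosine_progress(t - start, duration)
        active = t >= start
        theta = np.where(active, a_from[0] + prog * (a_to[0] - a_from[0]), theta)
        phi = np.where(active, a_from[1] + prog * (a_to[1] - a_from[1]), phi)
    return theta, phi


def _jittered_timestamps(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    n = int(np.ceil(duration * rate * 1.3)) + 2
    dt = (1.0 / rate) * (1.0 + rng.uniform(-0.1, 0.1, size=n))
    t = np.cumsum(dt) - dt[0] + rng.uniform(0.0, 1.0 / rate)
    return t[t <= duration]


def simulate_trial(
    script: TrialScript,
    geometry: SystemGeometry,
    eye: EyeParameters,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one recording.

    Returns (frames_cam1, frames_cam2, truth). The feature frames follow the
    FeatureFrame CSV schema; ``truth`` holds, at the union of both cameras'
    timestamps, the true visual-axis angles, the true POG on the screen (mm)
    and the screen-frame corneal center.
    """
    rng = np.random.default_rng(script.seed)
    center = np.array([0.0, 0.0, 650.0]) + script.head_offset
    plan, first_angles = _angle_timeline(script, eye, center)

    frames = []
    all_t = []
    for cam_idx, (camera, rate) in enumerate(zip(geometry.cameras, script.camera_rates)):
        t = _jittered_timestamps(rate, script.duration_s, rng)
        all_t.append(t)
        theta_v, phi_v = _angles_at(t, plan, first_angles)
        c_t, pupil_t, _pog, _cs = _poses_from_visual_angles(geometry, eye, theta_v, phi_v, center)
        feats, valid = _render_camera_features(
            c_t, pupil_t, eye, camera, geometry, script.mode
        )
        if script.pixel_noise_sd > 0:
            feats = feats + rng.normal(0.0, script.pixel_noise_sd, size=feats.shape)
        df = pd.DataFrame(feats, columns=FEATURE_COLUMNS[3:9])
        df.insert(0, "timestamp_s", t)
        df.insert(1, "cam", cam_idx + 1)
        df.insert(2, "eye", "right")
        df["valid"] = valid
        frames.append(df)

    t_union = np.sort(np.concatenate(all_t))
    theta_v, phi_v = _angles_at(t_union, plan, first_angles)
    _c_t, _pupil_t, pog, c_s = _poses_from_visual_angles(geometry, eye, theta_v, phi_v, center)
    truth = pd.DataFrame(
        {
            "timestamp_s": t_union,
            "theta_true": theta_v,
            "phi_true": phi_v,
            "pog_x_mm": pog[:, 0],
            "pog_y_mm": pog[:, 1],
            "Cx": c_s[:, 0],
            "Cy": c_s[:, 1],
            "Cz": c_s[:, 2],
        }
    )
    return frames[0], frames[1], truth


def simulate_fixation(
    geometry: SystemGeometry,
    eye: EyeParameters,
    target_xy,
    n_frames: int = 30,
    rotation_center_screen=(0.0, 0.0, 650.0),
    camera_rates: tuple[float, float] = (330.0, 300.0),
    mode: str = "no_refraction",
    pixel_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    t0: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Steady fixation of one target: n_frames per camera, no saccade.

    A lightweight generator for calibration and grid round-trip fixtures.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    pose = pose_for_target(geometry, eye, target_xy, rotation_center_screen)
    out = []
    for cam_idx, (camera, rate) in enumerate(zip(geometry.cameras, camera_rates)):
        t = t0 + np.arange(n_frames) / rate + (0.5 * cam_idx) / rate
        centers = np.tile(pose.corneal_center, (n_frames, 1))
        pupils = np.tile(pose.pupil_center(eye), (n_frames, 1))
        feats, valid = _render_camera_features(centers, pupils, eye, camera, geometry, mode)
        if pixel_noise_sd > 0:
            feats = feats + rng.normal(0.0, pixel_noise_sd, size=feats.shape)
        df = pd.DataFrame(feats, columns=FEATURE_COLUMNS[3:9])
        df.insert(0, "timestamp_s", t)
        df.insert(1, "cam", cam_idx + 1)
        df.insert(2, "eye", "right")
        df["valid"] = valid
        out.append(df)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# stimulus design
# ---------------------------------------------------------------------------


def target_grid(viewing_distance_mm: float = 650.0) -> np.ndarray:
    """The 54-target stimulus grid (mm on screen).

    Eccentricities 3, 6, 9 and 12 deg in 12 directions (0:30:330) and 15 deg
    in 6 directions (0, 45, 135, 180, 225, 315); visual angles are converted
    to screen millimetres for an imaginary eye on the screen z-axis at the
    viewing distance.
    """
    rows = []
    for ecc in (3.0, 6.0, 9.0, 12.0):
        for direction in np.arange(0.0, 360.0, 30.0):
            rows.append((ecc, direction))
    for direction in (0.0, 45.0, 135.0, 180.0, 225.0, 315.0):
        rows.append((15.0, direction))
    out = np.empty((len(rows), 2))
    for i, (ecc, direction) in enumerate(rows):
        r = viewing_distance_mm * np.tan(np.deg2rad(ecc))
        out[i] = (r * np.cos(np.deg2rad(direction)), r * np.sin(np.deg2rad(direction)))
    return out
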