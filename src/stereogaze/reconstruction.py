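"""Offline stereo gaze reconstruction.

Pipeline (per synchronized feature pair):

1. triangulate the virtual pupil center ``p_v`` from the two cameras' pupil
   images;
2. triangulate each illuminator's virtual image from its two glints and
   intersect the illuminator -> virtual-image lines to get the corneal
   curvature center ``c`` (convex-mirror property: both cameras see the
   virtual image of an illuminator at the same location);
3. re-impose the participant-specific corneal-center-to-pupil distance K by
   adjusting only the z coordinate of ``p_v`` (image noise acts mainly along
   the camera viewing direction);
4. map ``c`` and ``p_v`` into the screen frame, median-filter their
   coordinates and the raw ``|c - p_v|`` track;
5. convert the optical axis into pan/tilt angles, add the per-participant
   visual-axis offsets (alpha, beta), intersect the visual axis with the
   screen to get the point of gaze (POG);
6. apply the empirical gain K/K_actual to the full POG vector and recompute
   the corrected gaze angles.

The one-point calibration estimates (alpha, beta, K) from steady fixation of
a single central target: K as the median measured ``|c - p_v|``, alpha/beta
as medians of the per-sample differences between the line-of-sight angles and
the optical-axis angles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import angles_from_direction, direction_from_angles
from .system_calibration import SystemGeometry
from .geometry import triangulate_many

__all__ = [
    "CalibrationResult",
    "InvalidSampleError",
    "synchronize",
    "estimate_virtual_pupil",
    "estimate_corneal_center",
    "apply_K_constraint",
    "to_screen_frame",
    "optical_axis_angles",
    "calibrate_one_point",
    "point_of_gaze",
    "correct_pog",
    "median_filter_track",
    "reconstruct",
    "GAZE_COLUMNS",
]

log = logging.getLogger(__name__)

GAZE_COLUMNS = [
    "timestamp_s",
    "eye",
    "Cx",
    "Cy",
    "Cz",
    "theta",
    "phi",
    "theta_corr",
    "phi_corr",
    "pog_x_mm",
    "pog_y_mm",
    "pogc_x_mm",
    "pogc_y_mm",
    "K_actual",
    "valid",
]

_FEATURES = ["pupil_x", "pupil_y", "glint1_x", "glint1_y", "glint2_x", "glint2_y"]


class InvalidSampleError(ValueError):
    """A per-sample reconstruction step has no valid solution."""


@dataclass(frozen=True)
class CalibrationResult:
    """One-point calibration: visual/optical axis offsets and the K distance."""

    alpha: float  # deg
    beta: float  # deg
    K: float  # mm
    n_samples_used: int = 0

    def __post_init__(self):
        if not self.K > 0:
            raise ValueError("K must be positive")
        if abs(self.alpha) >= 15 or abs(self.beta) >= 15:
            raise ValueError("implausible visual-axis offsets (|alpha|,|beta| must be < 15 deg)")


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------


def _interp_stream(
    t_query: np.ndarray, t_src: np.ndarray, values: np.ndarray, valid_src: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of feature columns at query times.

    A query coinciding with a source timestamp returns that raw frame; an
    interpolated record is valid only if both bracketing frames are valid.
    """
    hi = np.searchsorted(t_src, t_query, side="left")
    exact = (hi < len(t_src)) & (t_src[np.minimum(hi, len(t_src) - 1)] == t_query)
    lo = np.where(exact, hi, hi - 1)
    hi = np.where(exact, hi, hi)
    inside = (lo >= 0) & (hi < len(t_src))
    lo_c = np.clip(lo, 0, len(t_src) - 1)
    hi_c = np.clip(hi, 0, len(t_src) - 1)
    dt = t_src[hi_c] - t_src[lo_c]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(dt > 0, (t_query - t_src[lo_c]) / np.where(dt > 0, dt, 1.0), 0.0)
    out = values[lo_c] + frac[:, None] * (values[hi_c] - values[lo_c])
    ok = inside & valid_src[lo_c] & valid_src[hi_c] & np.isfinite(out).all(axis=1)
    return out, ok


def synchronize(frames_cam1: pd.DataFrame, frames_cam2: pd.DataFrame) -> pd.DataFrame:
    """Pair the two asynchronous feature streams.

    Each camera's features are linearly interpolated at the timestamps of the
    other camera; the output has one paired record per input timestamp of
    either camera inside the temporal overlap. Records whose interpolation is
    bracketed by an invalid frame are flagged invalid.
    """
    streams = []
    for df in (frames_cam1, frames_cam2):
        d = df.sort_values("timestamp_s")
        streams.append(
            (
                d["timestamp_s"].to_numpy(float),
                d[_FEATURES].to_numpy(float),
                d["valid"].to_numpy(bool) & np.isfinite(d[_FEATURES].to_numpy(float)).all(axis=1),
            )
        )
    (t1, v1, ok1), (t2, v2, ok2) = streams
    if len(t1) == 0 or len(t2) == 0 or max(t1[0], t2[0]) > min(t1[-1], t2[-1]):
        warnings.warn("feature streams have no temporal overlap; empty pairing")
        return pd.DataFrame(
            columns=["timestamp_s"]
            + [f"{c}_c1" for c in _FEATURES]
            + [f"{c}_c2" for c in _FEATURES]
            + ["valid"]
        )
    lo = max(t1[0], t2[0])
    hi = min(t1[-1], t2[-1])
    t = np.unique(np.concatenate([t1, t2]))
    t = t[(t >= lo) & (t <= hi)]
    a, ok_a = _interp_stream(t, t1, v1, ok1)
    b, ok_b = _interp_stream(t, t2, v2, ok2)
    out = pd.DataFrame({"timestamp_s": t})
    for j, c in enumerate(_FEATURES):
        out[f"{c}_c1"] = a[:, j]
    for j, c in enumerate(_FEATURES):
        out[f"{c}_c2"] = b[:, j]
    out["valid"] = ok_a & ok_b
    return out


# ---------------------------------------------------------------------------
# per-sample geometry (vectorized internals + scalar spec operations)
# ---------------------------------------------------------------------------


def _triangulate_pixel_pairs(
    px1: np.ndarray, px2: np.ndarray, geometry: SystemGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    o1, d1 = geometry.camera1.back_project_many(px1)
    o2, d2 = geometry.camera2.back_project_many(px2)
    return triangulate_many(o1, d1, o2, d2)


def _paired_arrays(paired: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "v1": paired[["pupil_x_c1", "pupil_y_c1"]].to_numpy(float),
        "v2": paired[["pupil_x_c2", "pupil_y_c2"]].to_numpy(float),
        "u11": paired[["glint1_x_c1", "glint1_y_c1"]].to_numpy(float),
        "u21": paired[["glint1_x_c2", "glint1_y_c2"]].to_numpy(float),
        "u12": paired[["glint2_x_c1", "glint2_y_c1"]].to_numpy(float),
        "u22": paired[["glint2_x_c2", "glint2_y_c2"]].to_numpy(float),
    }


def _virtual_pupils(arr: dict, geometry: SystemGeometry):
    return _triangulate_pixel_pairs(arr["v1"], arr["v2"], geometry)


def _corneal_centers(arr: dict, geometry: SystemGeometry):
    """Corneal curvature centers from the four glints (vectorized).

    For each illuminator j, the virtual image L'_j is triangulated from the
    glints u_1j, u_2j; c is the least-squares intersection of the lines
    L_j -> L'_j.
    """
    L1, L2 = geometry.illuminators
    Lp1, _r1, ok1 = _triangulate_pixel_pairs(arr["u11"], arr["u21"], geometry)
    Lp2, _r2, ok2 = _triangulate_pixel_pairs(arr["u12"], arr["u22"], geometry)
    n = len(Lp1)
    o1 = np.broadcast_to(L1, (n, 3))
    o2 = np.broadcast_to(L2, (n, 3))
    with np.errstate(invalid="ignore"):
        c, _res, ok = triangulate_many(o1, Lp1 - L1, o2, Lp2 - L2)
    return c, ok & ok1 & ok2


def estimate_virtual_pupil(pair, geometry: SystemGeometry) -> np.ndarray:
    """Triangulated virtual pupil center for one paired record (tracker mm)."""
    arr = {k: v[None, :] for k, v in _row_features(pair).items()}
    p, _r, ok = _virtual_pupils(arr, geometry)
    if not ok[0]:
        raise InvalidSampleError("degenerate pupil triangulation")
    return p[0]


def estimate_corneal_center(pair, geometry: SystemGeometry) -> tuple[np.ndarray, float]:
    """Corneal center and raw K for one paired record.

    Returns (c, K_actual_raw) where K_actual_raw = |c - p_v| of the same pair.
    """
    arr = {k: v[None, :] for k, v in _row_features(pair).items()}
    c, ok = _corneal_centers(arr, geometry)
    if not ok[0]:
        raise InvalidSampleError("degenerate corneal-center triangulation")
    p_v = estimate_virtual_pupil(pair, geometry)
    return c[0], float(np.linalg.norm(c[0] - p_v))


def _row_features(pair) -> dict[str, np.ndarray]:
    get = pair.__getitem__
    return {
        "v1": np.array([get("pupil_x_c1"), get("pupil_y_c1")], float),
        "v2": np.array([get("pupil_x_c2"), get("pupil_y_c2")], float),
        "u11": np.array([get("glint1_x_c1"), get("glint1_y_c1")], float),
        "u21": np.array([get("glint1_x_c2"), get("glint1_y_c2")], float),
        "u12": np.array([get("glint2_x_c1"), get("glint2_y_c1")], float),
        "u22": np.array([get("glint2_x_c2"), get("glint2_y_c2")], float),
    }


def apply_K_constraint(c, p_v, K: float) -> np.ndarray:
    """Move the virtual pupil along z so that |p_v' - c| = K exactly.

    x and y are kept; the z coordinate becomes
    ``z_c - sqrt(K^2 - (x_c - x_pv)^2 - (y_c - y_pv)^2)`` (the pupil is nearer
    the cameras than the corneal center in tracker coordinates).
    """
    c = np.asarray(c, float)
    p_v = np.asarray(p_v, float)
    planar2 = (c[0] - p_v[0]) ** 2 + (c[1] - p_v[1]) ** 2
    if planar2 > K**2:
        raise InvalidSampleError(
            f"planar distance {np.sqrt(planar2):.3f} mm exceeds K = {K:.3f} mm"
        )
    return np.array([p_v[0], p_v[1], c[2] - np.sqrt(K**2 - planar2)])


def _apply_K_constraint_many(c: np.ndarray, p_v: np.ndarray, K: float):
    planar2 = (c[:, 0] - p_v[:, 0]) ** 2 + (c[:, 1] - p_v[:, 1]) ** 2
    ok = planar2 <= K**2
    z = c[:, 2] - np.sqrt(np.where(ok, K**2 - planar2, np.nan))
    out = np.column_stack([p_v[:, 0], p_v[:, 1], z])
    return out, ok


def to_screen_frame(p, geometry: SystemGeometry) -> np.ndarray:
    """Tracker -> stimulus (screen) frame: rotation then translation."""
    return geometry.to_screen(np.asarray(p, float))


def optical_axis_angles(C, P_v_prime) -> tuple[float, float]:
    """Pan/tilt angles (deg) of the optical axis from screen-frame C and P'_v."""
    C = np.asarray(C, float)
    P = np.asarray(P_v_prime, float)
    d = P - C
    if np.linalg.norm(d) == 0:
        raise InvalidSampleError("zero-length optical axis")
    th, ph = angles_from_direction(d)
    return float(th), float(ph)


# ---------------------------------------------------------------------------
# median filtering
# ---------------------------------------------------------------------------


def median_filter_track(series, width: int = 20) -> np.ndarray:
    """Running median with a window of ``width`` samples.

    Even widths center the window as closely as parity allows (width//2
    samples before, width//2 - 1 after) and average the two middle order
    statistics; windows are truncated at the edges, so the output has the
    input's length and a constant series is returned unchanged.
    """
    x = np.asarray(series, float)
    if width < 1:
        raise ValueError("width must be >= 1")
    n = len(x)
    if n == 0:
        return x.copy()
    w = min(width, n)
    lo = w // 2
    hi = w - lo - 1
    out = np.empty(n)
    if n >= w:
        windows = np.lib.stride_tricks.sliding_window_view(x, w)
        out[lo : n - hi] = np.median(windows, axis=1)
    for i in range(min(lo, n)):
        out[i] = np.median(x[: i + hi + 1])
    for i in range(max(n - hi, 0), n):
        out[i] = np.median(x[i - lo :])
    return out


def _filter_valid_runs(x: np.ndarray, valid: np.ndarray, width: int) -> np.ndarray:
    """Median-filter each contiguous valid run independently; invalid samples
    are never interpolated through."""
    out = x.copy()
    n = len(x)
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        out[i:j] = median_filter_track(x[i:j], width)
        i = j
    return out


# ---------------------------------------------------------------------------
# gaze from angles
# ---------------------------------------------------------------------------


def point_of_gaze(C, theta: float, phi: float, calib: CalibrationResult):
    """POG on the screen plane (Z = 0) from screen-frame C and the optical-axis
    angles, via the visual axis g(theta + alpha, phi + beta).

    Returns (pog (2,) mm, lambda_g mm).
    """
    C = np.asarray(C, float)
    th = np.deg2rad(theta + calib.alpha)
    ph = np.deg2rad(phi + calib.beta)
    denom = np.cos(ph) * np.cos(th)
    if denom <= 0 or C[2] <= 0:
        raise InvalidSampleError("gaze does not intersect the screen in front of the eye")
    g = direction_from_angles(theta + calib.alpha, phi + calib.beta)
    lam = C[2] / denom
    p = C + lam * g
    return p[:2], float(lam)


def correct_pog(
    C,
    lambda_g: float,
    gaze: np.ndarray,
    K: float,
    K_actual_filtered: float,
) -> tuple[np.ndarray, float, float]:
    """Empirical gain correction of the POG.

    The full screen-frame POG vector C + lambda_g * g is scaled by
    K / K_actual; the corrected gaze direction is taken from the scaled POG
    back to the *unscaled* C, and the corrected pan/tilt angles are read off
    that direction. With K_actual = K this is the identity.
    """
    if not K_actual_filtered > 0:
        raise InvalidSampleError("K_actual must be positive")
    C = np.asarray(C, float)
    pog3 = C + lambda_g * np.asarray(gaze, float)
    pog_corr3 = (K / K_actual_filtered) * pog3
    d = pog_corr3 - C
    th, ph = angles_from_direction(d)
    return pog_corr3[:2], float(th), float(ph)


# ---------------------------------------------------------------------------
# one-point calibration
# ---------------------------------------------------------------------------


def calibrate_one_point(
    frames_cam1: pd.DataFrame,
    frames_cam2: pd.DataFrame,
    geometry: SystemGeometry,
    target_screen=(0.0, 0.0, 0.0),
    min_samples: int = 20,
) -> CalibrationResult:
    """Estimate (alpha, beta, K) from fixation of a single known target.

    K is the median measured |c - p_v|; alpha/beta are the medians of the
    per-sample differences between the line-of-sight angles (from C to the
    target, same Fick parameterization as the optical axis) and the
    optical-axis angles. Medians are used throughout for robustness.
    """
    paired = synchronize(frames_cam1, frames_cam2)
    arr = _paired_arrays(paired)
    p_v, _r, ok_p = _virtual_pupils(arr, geometry)
    c, ok_c = _corneal_centers(arr, geometry)
    valid = paired["valid"].to_numpy(bool) & ok_p & ok_c
    if valid.sum() < min_samples:
        raise ValueError(
            f"one-point calibration needs >= {min_samples} valid samples, got {int(valid.sum())}"
        )
    p_v, c = p_v[valid], c[valid]
    K = float(np.median(np.linalg.norm(c - p_v, axis=1)))
    p_prime, ok_k = _apply_K_constraint_many(c, p_v, K)
    c, p_prime = c[ok_k], p_prime[ok_k]
    C = geometry.to_screen(c)
    P = geometry.to_screen(p_prime)
    th_eye, ph_eye = angles_from_direction(P - C)
    target = np.asarray(target_screen, float)
    th_sight, ph_sight = angles_from_direction(target - C)
    alpha = float(np.median(th_sight - th_eye))
    beta = float(np.median(ph_sight - ph_eye))
    result = CalibrationResult(alpha=alpha, beta=beta, K=K, n_samples_used=int(ok_k.sum()))
    log.info(
        "one-point calibration: alpha=%.3f deg beta=%.3f deg K=%.4f mm (n=%d)",
        alpha,
        beta,
        K,
        result.n_samples_used,
    )
    return result


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _reconstruct_single_eye(
    frames_cam1: pd.DataFrame,
    frames_cam2: pd.DataFrame,
    geometry: SystemGeometry,
    calib: CalibrationResult,
    eye_label: str,
    filter_width: int = 20,
    use_k_constraint: bool = True,
    use_correction: bool = True,
) -> pd.DataFrame:
    paired = synchronize(frames_cam1, frames_cam2)
    n = len(paired)
    out = pd.DataFrame({c: np.full(n, np.nan) for c in GAZE_COLUMNS if c not in ("eye", "valid")})
    out["timestamp_s"] = paired["timestamp_s"].to_numpy(float) if n else np.array([])
    out["eye"] = eye_label
    out["valid"] = False
    if n == 0:
        return out[GAZE_COLUMNS]

    arr = _paired_arrays(paired)
    p_v, _res, ok_p = _virtual_pupils(arr, geometry)
    c, ok_c = _corneal_centers(arr, geometry)
    valid = paired["valid"].to_numpy(bool) & ok_p & ok_c
    k_raw = np.linalg.norm(c - p_v, axis=1)

    if use_k_constraint:
        with np.errstate(invalid="ignore"):
            p_used, ok_k = _apply_K_constraint_many(c, p_v, calib.K)
        valid &= ok_k
    else:
        p_used = p_v

    C = geometry.to_screen(np.nan_to_num(c, nan=0.0))
    P = geometry.to_screen(np.nan_to_num(p_used, nan=0.0))
    C[~valid] = np.nan
    P[~valid] = np.nan
    k_track = np.where(valid, k_raw, np.nan)

    if filter_width > 1:
        for col in range(3):
            C[:, col] = _filter_valid_runs(C[:, col], valid, filter_width)
            P[:, col] = _filter_valid_runs(P[:, col], valid, filter_width)
        k_track = _filter_valid_runs(k_track, valid, filter_width)

    d = P - C
    nrm = np.linalg.norm(d, axis=1)
    valid &= np.isfinite(nrm) & (nrm > 0) & (C[:, 2] > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta, phi = angles_from_direction(np.where(valid[:, None], d, [[0, 0, -1.0]]))
        th_g = np.deg2rad(theta + calib.alpha)
        ph_g = np.deg2rad(phi + calib.beta)
        denom = np.cos(ph_g) * np.cos(th_g)
        valid &= denom > 1e-12
        g = direction_from_angles(theta + calib.alpha, phi + calib.beta)
        lam = C[:, 2] / np.where(denom > 1e-12, denom, np.nan)
        pog3 = C + lam[:, None] * g
        if use_correction:
            valid &= k_track > 0
            gain = calib.K / np.where(k_track > 0, k_track, np.nan)
            pogc3 = gain[:, None] * pog3
            dc = pogc3 - C
            theta_corr, phi_corr = angles_from_direction(
                np.where(valid[:, None], dc, [[0, 0, -1.0]])
            )
        else:
            pogc3 = pog3
            theta_corr, phi_corr = theta, phi

    out["Cx"], out["Cy"], out["Cz"] = C.T
    out["theta"], out["phi"] = theta, phi
    out["theta_corr"], out["phi_corr"] = theta_corr, phi_corr
    out["pog_x_mm"], out["pog_y_mm"] = pog3[:, 0], pog3[:, 1]
    out["pogc_x_mm"], out["pogc_y_mm"] = pogc3[:, 0], pogc3[:, 1]
    out["K_actual"] = k_track
    out["valid"] = valid
    mask = ~valid
    for col in GAZE_COLUMNS:
        if col not in ("timestamp_s", "eye", "valid"):
            out.loc[mask, col] = np.nan
    log.info(
        "reconstructed %d samples (%d valid) for eye=%s", n, int(valid.sum()), eye_label
    )
    return out[GAZE_COLUMNS]


def reconstruct(
    frames_cam1: pd.DataFrame,
    frames_cam2: pd.DataFrame,
    geometry: SystemGeometry,
    calib: CalibrationResult | dict,
    filter_width: int = 20,
    use_k_constraint: bool = True,
    use_correction: bool = True,
) -> pd.DataFrame:
    """Synchronize two feature streams and reconstruct the gaze sample stream.

    ``calib`` may be a single :class:`CalibrationResult` or a mapping
    eye-label -> result when the frames contain several eyes. Invalid frames
    propagate as invalid gaze samples (all-NaN rows), never interpolated
    through.
    """
    eyes = sorted(set(frames_cam1.get("eye", pd.Series(["right"]))) | set(
        frames_cam2.get("eye", pd.Series(["right"]))
    ))
    pieces = []
    for eye_label in eyes:
        f1 = frames_cam1[frames_cam1["eye"] == eye_label] if "eye" in frames_cam1 else frames_cam1
        f2 = frames_cam2[frames_cam2["eye"] == eye_label] if "eye" in frames_cam2 else frames_cam2
        cal = calib[eye_label] if isinstance(calib, dict) else calib
        pieces.append(
            _reconstruct_single_eye(
                f1,
                f2,
                geometry,
                cal,
                eye_label,
                filter_width=filter_width,
                use_k_constraint=use_k_constraint,
                use_correction=use_correction,
            )
        )
    return pd.concat(pieces, ignore_index=True).sort_values(
        ["timestamp_s", "eye"], ignore_index=True
    )
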