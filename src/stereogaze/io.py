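"""File formats: geometry/calibration JSON, feature/gaze/target CSVs.

All lengths are millimetres, matrices are stored row-major, floats are
written with 9 significant digits so every CSV round-trips losslessly at the
precision the pipeline uses.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CameraModel
from .reconstruction import CalibrationResult, GAZE_COLUMNS
from .simulator import FEATURE_COLUMNS
from .system_calibration import SystemGeometry

__all__ = [
    "ConfigError",
    "geometry_to_dict",
    "geometry_from_dict",
    "save_geometry",
    "load_geometry",
    "save_calibration",
    "load_calibration",
    "write_features_csv",
    "read_features_csv",
    "write_gaze_csv",
    "read_gaze_csv",
    "read_targets_csv",
    "write_targets_csv",
]

FLOAT_FMT = "%.9g"


class ConfigError(ValueError):
    """A configuration file violates its schema."""


def _camera_to_dict(cam: CameraModel) -> dict:
    return {
        "nodal_point_mm": cam.nodal_point.tolist(),
        "rotation": cam.rotation.tolist(),
        "focal_length_px": cam.focal_length,
        "principal_point_px": cam.principal_point.tolist(),
        "sensor_size_px": cam.sensor_size.tolist(),
    }


def _camera_from_dict(d: dict, name: str) -> CameraModel:
    try:
        return CameraModel(
            nodal_point=np.array(d["nodal_point_mm"], float),
            rotation=np.array(d["rotation"], float),
            focal_length=float(d["focal_length_px"]),
            principal_point=np.array(d["principal_point_px"], float),
            sensor_size=np.array(d.get("sensor_size_px", [1048.0, 480.0]), float),
        )
    except KeyError as exc:
        raise ConfigError(f"geometry field {name}.{exc.args[0]} is missing") from exc
    except ValueError as exc:
        raise ConfigError(f"geometry field {name} is invalid: {exc}") from exc


def geometry_to_dict(geo: SystemGeometry) -> dict:
    return {
        "camera1": _camera_to_dict(geo.camera1),
        "camera2": _camera_to_dict(geo.camera2),
        "illuminator1_mm": geo.illuminator1.tolist(),
        "illuminator2_mm": geo.illuminator2.tolist(),
        "screen_rotation": geo.screen_rotation.tolist(),
        "screen_translation_mm": geo.screen_translation.tolist(),
        "screen_resolution_px": geo.screen_resolution.tolist(),
        "pixel_pitch_mm": geo.pixel_pitch,
    }


def geometry_from_dict(d: dict) -> SystemGeometry:
    for key in (
        "camera1",
        "camera2",
        "illuminator1_mm",
        "illuminator2_mm",
        "screen_rotation",
        "screen_translation_mm",
    ):
        if key not in d:
            raise ConfigError(f"geometry field {key} is missing")
    try:
        return SystemGeometry(
            camera1=_camera_from_dict(d["camera1"], "camera1"),
            camera2=_camera_from_dict(d["camera2"], "camera2"),
            illuminator1=np.array(d["illuminator1_mm"], float),
            illuminator2=np.array(d["illuminator2_mm"], float),
            screen_rotation=np.array(d["screen_rotation"], float),
            screen_translation=np.array(d["screen_translation_mm"], float),
            screen_resolution=np.array(d.get("screen_resolution_px", [1920.0, 1200.0]), float),
            pixel_pitch=float(d.get("pixel_pitch_mm", 0.27)),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid geometry: {exc}") from exc


def save_geometry(geo: SystemGeometry, path) -> None:
    Path(path).write_text(json.dumps(geometry_to_dict(geo), indent=2))


def load_geometry(path) -> SystemGeometry:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"geometry file not found: {p}")
    return geometry_from_dict(json.loads(p.read_text()))


def save_calibration(calib: CalibrationResult | dict, path) -> None:
    if isinstance(calib, CalibrationResult):
        calib = {"default": calib}
    payload = {
        eye: {
            "alpha_deg": c.alpha,
            "beta_deg": c.beta,
            "K_mm": c.K,
            "n_samples_used": c.n_samples_used,
        }
        for eye, c in calib.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_calibration(path) -> CalibrationResult | dict:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"calibration file not found: {p}")
    raw = json.loads(p.read_text())
    out = {}
    for eye, d in raw.items():
        try:
            out[eye] = CalibrationResult(
                alpha=float(d["alpha_deg"]),
                beta=float(d["beta_deg"]),
                K=float(d["K_mm"]),
                n_samples_used=int(d.get("n_samples_used", 0)),
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"invalid calibration entry {eye!r}: {exc}") from exc
    return out["default"] if set(out) == {"default"} else out


def write_features_csv(frames: pd.DataFrame, path) -> None:
    frames.to_csv(path, index=False, float_format=FLOAT_FMT, columns=FEATURE_COLUMNS)


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"feature CSV {path} is missing columns {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    return df


def write_gaze_csv(gaze: pd.DataFrame, path) -> None:
    gaze.to_csv(path, index=False, float_format=FLOAT_FMT, columns=GAZE_COLUMNS)


def read_gaze_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(GAZE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"gaze CSV {path} is missing columns {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    return df


def write_targets_csv(targets: pd.DataFrame, path) -> None:
    targets.to_csv(
        path, index=False, float_format=FLOAT_FMT, columns=["trial", "onset_s", "x_mm", "y_mm"]
    )


def read_targets_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"trial", "onset_s", "x_mm", "y_mm"} - set(df.columns)
    if missing:
        raise ConfigError(f"targets CSV {path} is missing columns {sorted(missing)}")
    return df
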