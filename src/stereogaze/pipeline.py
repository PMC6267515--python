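"""Top-level reproducible runs tying simulate -> reconstruct -> analyze.

The demo replays the full synthetic validation study: a one-point calibration
at the central head position, then 54 saccade trials at each of nine head
positions (+/- 50 mm horizontal, +/- 30 mm vertical and their combinations),
reconstruction, and fixation/saccade analytics per position.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, io
from .reconstruction import CalibrationResult, calibrate_one_point, reconstruct
from .simulator import (
    EyeParameters,
    TargetEvent,
    TrialScript,
    simulate_fixation,
    simulate_trial,
    target_grid,
)
from .system_calibration import SystemGeometry, reference_rig

__all__ = ["HEAD_POSITIONS", "simulate_session", "run_demo"]

log = logging.getLogger(__name__)

# central position, +/- 50 mm horizontal, +/- 30 mm vertical, and combinations
HEAD_POSITIONS = tuple(
    (dx, dy) for dy in (30.0, 0.0, -30.0) for dx in (-50.0, 0.0, 50.0)
)


def simulate_session(
    geometry: SystemGeometry,
    eye: EyeParameters,
    head_offset: tuple[float, float],
    seed: int,
    mode: str = "snell",
    pixel_noise_sd: float = 0.1,
    targets: np.ndarray | None = None,
    fixation_s: tuple[float, float] = (1.0, 1.6),
    target_s: float = 1.0,
    camera_rates: tuple[float, float] = (330.0, 300.0),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One block of saccade trials at a fixed head position.

    Each trial starts with fixation of the screen center for a random
    1.0-1.6 s, after which the peripheral target appears for ``target_s``.
    Returns (frames_cam1, frames_cam2, truth, targets_table) with trial
    streams concatenated on a common time axis.
    """
    rng = np.random.default_rng(seed)
    if targets is None:
        targets = target_grid()
        rng.shuffle(targets)
    f1_all, f2_all, truth_all, rows = [], [], [], []
    t0 = 0.0
    for k, (tx, ty) in enumerate(targets):
        fix = float(rng.uniform(*fixation_s))
        script = TrialScript(
            targets=(TargetEvent(0.0, 0.0, 0.0), TargetEvent(tx, ty, fix)),
            duration_s=fix + target_s,
            head_offset=np.array([head_offset[0], head_offset[1], 0.0]),
            camera_rates=camera_rates,
            pixel_noise_sd=pixel_noise_sd,
            mode=mode,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        f1, f2, truth = simulate_trial(script, geometry, eye)
        for df in (f1, f2, truth):
            df["timestamp_s"] += t0
        rows.append({"trial": k, "onset_s": t0 + fix, "x_mm": tx, "y_mm": ty})
        f1_all.append(f1)
        f2_all.append(f2)
        truth_all.append(truth)
        t0 += script.duration_s + 0.05
    return (
        pd.concat(f1_all, ignore_index=True),
        pd.concat(f2_all, ignore_index=True),
        pd.concat(truth_all, ignore_index=True),
        pd.DataFrame(rows),
    )


def _stats_block(result: dict) -> dict:
    block: dict = {"n_trials_excluded": result.get("n_trials_excluded", 0)}
    fx = result.get("fixation")
    if fx is not None:
        block["fixation"] = dataclasses.asdict(fx)
    ms = result.get("main_sequence")
    if ms is not None:
        block["main_sequence"] = dataclasses.asdict(ms)
    return block


def _truth_as_gaze(truth: pd.DataFrame) -> pd.DataFrame:
    g = pd.DataFrame(
        {
            "timestamp_s": truth["timestamp_s"],
            "pog_x_mm": truth["pog_x_mm"],
            "pog_y_mm": truth["pog_y_mm"],
            "pogc_x_mm": truth["pog_x_mm"],
            "pogc_y_mm": truth["pog_y_mm"],
            "valid": True,
        }
    )
    return g


def run_demo(
    seed: int,
    out_dir,
    mode: str = "snell",
    pixel_noise_sd: float = 0.1,
    positions=HEAD_POSITIONS,
    calibration: CalibrationResult | None = None,
    write_streams: bool = False,
    n_targets: int | None = None,
) -> dict:
    """Synthetic replica of the validation study; writes report.json.

    All randomness derives from ``seed``; identical seeds give identical
    report files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = reference_rig()
    eye = EyeParameters()
    io.save_geometry(geometry, out / "geometry.json")

    if calibration is None:
        rng = np.random.default_rng(seed)
        c1, c2 = simulate_fixation(
            geometry, eye, (0.0, 0.0), n_frames=200, mode=mode,
            pixel_noise_sd=pixel_noise_sd, rng=rng,
        )
        calibration = calibrate_one_point(c1, c2, geometry)
    io.save_calibration(calibration, out / "calibration.json")

    report: dict = {
        "seed": seed,
        "mode": mode,
        "calibration": dataclasses.asdict(calibration),
        "head_positions": {},
    }
    for k, (dx, dy) in enumerate(positions):
        f1, f2, truth, targets = simulate_session(
            geometry, eye, (dx, dy), seed=seed * 1000 + k, mode=mode,
            pixel_noise_sd=pixel_noise_sd,
            targets=None if n_targets is None else target_grid()[:n_targets],
        )
        gaze = reconstruct(f1, f2, geometry, calibration)
        result = analysis.analyze_trials(gaze, targets)
        key = f"dx{dx:+.0f}_dy{dy:+.0f}"
        report["head_positions"][key] = _stats_block(result)
        log.info("head position %s analyzed (%d trials)", key, len(targets))
        if write_streams:
            io.write_features_csv(f1, out / f"{key}_cam1.csv")
            io.write_features_csv(f2, out / f"{key}_cam2.csv")
            io.write_gaze_csv(gaze, out / f"{key}_gaze.csv")
            io.write_targets_csv(targets, out / f"{key}_targets.csv")
        if (dx, dy) == (0.0, 0.0):
            # agreement with ground truth at the central position, in the
            # style of a between-system comparison
            truth_result = analysis.analyze_trials(_truth_as_gaze(truth), targets)
            a = result.get("first_saccades", [])
            b = truth_result.get("first_saccades", [])
            n = min(len(a), len(b))
            if n > 2:
                ba_amp = analysis.bland_altman(
                    [s.amplitude for s in a[:n]], [s.amplitude for s in b[:n]]
                )
                ba_vp = analysis.bland_altman(
                    [s.peak_velocity for s in a[:n]], [s.peak_velocity for s in b[:n]]
                )
                report["bland_altman_vs_truth"] = {
                    "amplitude": dataclasses.asdict(ba_amp),
                    "peak_velocity": dataclasses.asdict(ba_vp),
                }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
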