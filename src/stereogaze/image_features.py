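"""Raster-level pupil/glint feature extraction, with a synthetic renderer.

Mirrors the online image-processing stage of a video eye tracker at desk
scale: a cropped eye image is segmented by intensity thresholds, the pupil
center is found at subpixel resolution by a least-squares ellipse fit to the
contour of the dark pupil component, and glint centers are intensity-weighted
centroids of small bright components. The renderer draws the matching
synthetic rasters (anti-aliased dark ellipse on a mid-gray iris background,
Gaussian glint spots, additive pixel noise) so every extractor is testable
against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

__all__ = [
    "EyeRaster",
    "SegmentationConfig",
    "FeatureNotFoundError",
    "render_eye_raster",
    "extract_pupil",
    "extract_glints",
    "pupil_glint_vector",
]


class FeatureNotFoundError(RuntimeError):
    """No image component qualifies for the requested feature."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds and size gates for the pupil/glint segmentation.

    Defaults are tuned for the synthetic renderer below (background ~120,
    pupil ~20, glints saturating), not taken from any particular hardware.
    Areas are in px^2.
    """

    pupil_threshold: float = 70.0
    glint_threshold: float = 200.0
    pupil_size_bounds: tuple[float, float] = (80.0, 20000.0)
    glint_size_bounds: tuple[float, float] = (2.0, 300.0)

    def __post_init__(self):
        for th in (self.pupil_threshold, self.glint_threshold):
            if not 0 <= th <= 255:
                raise ValueError("thresholds must be in [0, 255]")
        for lo, hi in (self.pupil_size_bounds, self.glint_size_bounds):
            if not (0 < lo < hi):
                raise ValueError("size bounds must be positive with min < max")


@dataclass(frozen=True)
class EyeRaster:
    """8-bit grayscale eye image with its generating ground truth."""

    image: np.ndarray  # (rows, cols) uint8
    pupil_center: np.ndarray  # (x, y) px
    pupil_axes: np.ndarray  # (a, b) semi-axes px
    pupil_tilt: float  # deg
    glint_centers: np.ndarray  # (k, 2) px

    def __post_init__(self):
        img = np.asarray(self.image)
        if img.ndim != 2 or img.dtype != np.uint8:
            raise ValueError("image must be a 2-D uint8 array")


def render_eye_raster(
    pupil_center,
    pupil_axes,
    pupil_tilt_deg: float = 0.0,
    glint_centers=(),
    shape: tuple[int, int] = (160, 200),
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 120.0,
    pupil_intensity: float = 20.0,
    glint_amplitude: float = 220.0,
    glint_sigma_px: float = 1.6,
    supersample: int = 4,
) -> EyeRaster:
    """Draw a synthetic eye image (deterministic for a given seed).

    The pupil is an anti-aliased dark ellipse (area coverage computed on a
    ``supersample`` x ``supersample`` subgrid); glints are Gaussian bright
    spots added on top and clipped at 255.
    """
    rows, cols = shape
    cx, cy = (float(v) for v in pupil_center)
    a, b = (float(v) for v in pupil_axes)
    if not (0 <= cx < cols and 0 <= cy < rows):
        raise ValueError("pupil center must lie inside the frame")

    # pixel (r, c) is centered on (x, y) = (c, r), matching skimage conventions
    s = supersample
    ys = (np.arange(rows * s) + 0.5) / s - 0.5
    xs = (np.arange(cols * s) + 0.5) / s - 0.5
    X, Y = np.meshgrid(xs, ys)
    tilt = np.deg2rad(pupil_tilt_deg)
    dx, dy = X - cx, Y - cy
    u = dx * np.cos(tilt) + dy * np.sin(tilt)
    v = -dx * np.sin(tilt) + dy * np.cos(tilt)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    coverage = inside.reshape(rows, s, cols, s).mean(axis=(1, 3))
    img = background + (pupil_intensity - background) * coverage

    yy, xx = np.mgrid[0:rows, 0:cols]
    for gx, gy in glint_centers:
        img = img + glint_amplitude * np.exp(
            -((xx - gx) ** 2 + (yy - gy) ** 2) / (2.0 * glint_sigma_px**2)
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return EyeRaster(
        image=img,
        pupil_center=np.array([cx, cy]),
        pupil_axes=np.array([a, b]),
        pupil_tilt=float(pupil_tilt_deg),
        glint_centers=np.asarray(list(glint_centers), float).reshape(-1, 2),
    )


def _components(mask: np.ndarray):
    labels = measure.label(mask, connectivity=2)  # 8-connectivity
    return labels, measure.regionprops(labels)


def extract_pupil(image: np.ndarray, config: SegmentationConfig = SegmentationConfig()):
    """Subpixel pupil center from the largest in-bounds dark component.

    The component's contour is traced at the threshold level (subpixel
    marching squares) and fitted with a direct least-squares ellipse.
    Returns (center (x, y) px, ellipse params dict).
    """
    img = np.asarray(image, float)
    mask = img < config.pupil_threshold
    labels, props = _components(mask)
    lo, hi = config.pupil_size_bounds
    candidates = [p for p in props if lo <= p.area <= hi]
    if not candidates:
        raise FeatureNotFoundError("no pupil component within size bounds")
    blob = max(candidates, key=lambda p: p.area)

    # subpixel contour of this component only: mask everything else bright
    work = np.where(labels == blob.label, img, 255.0)
    contours = measure.find_contours(work, level=config.pupil_threshold)
    if not contours:
        raise FeatureNotFoundError("pupil component has no traceable contour")
    contour = max(contours, key=len)  # (row, col) pairs
    xy = contour[:, ::-1]
    try:
        model = measure.EllipseModel.from_estimate(xy)
        if not model:
            raise FeatureNotFoundError("ellipse fit to the pupil contour failed")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    except AttributeError:  # scikit-image < 0.26
        model = measure.EllipseModel()
        if not model.estimate(xy) or model.params is None:
            raise FeatureNotFoundError("ellipse fit to the pupil contour failed")
        xc, yc, a, b, theta = model.params
    return np.array([xc, yc]), {
        "center": np.array([xc, yc]),
        "axes": np.array([a, b]),
        "tilt_deg": float(np.rad2deg(theta)),
        "area_px": float(blob.area),
    }


def extract_glints(
    image: np.ndarray, config: SegmentationConfig = SegmentationConfig()
) -> list[np.ndarray]:
    """Subpixel glint centers (intensity-weighted centroids), left to right.

    Components above the glint threshold and inside the size bounds qualify;
    an empty list means no glint was found.
    """
    img = np.asarray(image, float)
    mask = img > config.glint_threshold
    labels, props = _components(mask)
    lo, hi = config.glint_size_bounds
    centers = []
    for p in props:
        if not (lo <= p.area <= hi):
            continue
        rr, cc = np.nonzero(labels == p.label)
        # weighting by intensity above threshold reduces the discretization
        # bias of the component's jagged outline
        w = img[rr, cc] - config.glint_threshold
        centers.append(np.array([np.average(cc, weights=w), np.average(rr, weights=w)]))
    centers.sort(key=lambda c: c[0])
    return centers


def pupil_glint_vector(pupil_center, glint_center) -> np.ndarray:
    """Componentwise pupil-minus-glint vector (px); translation invariant."""
    return np.asarray(pupil_center, float) - np.asarray(glint_center, float)
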