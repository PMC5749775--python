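"""Optical-density maps and instrument qualification.

Transmitted-light Feulgen densitometry measures, at every pixel, the optical
density OD = log10(I0 / I) where I0 is the clear-background intensity.
Under stoichiometric staining, OD integrated over a chromosome is
proportional to its DNA content, which is what the downstream proportional
allocation relies on.

This module also implements the three qualification tests run before any
measurement session: linearity (regression of measured band OD on the
nominal ODs of a stepped density filter), field uniformity (tile-wise CV of
a blank field) and signal stability (time to a stable mean-OD signal after
lamp warm-up).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

from .errors import CalibrationError, ValidationError

#: OD assigned to pixels at or below zero counts (cap instead of infinity).
_FLOOR_COUNTS = 0.5


@dataclass
class ODMap:
    """Per-pixel optical densities with calibration metadata.

    ``saturation`` marks pixels whose intensity hit the zero floor; their OD
    is capped and measurements over them should be flagged.
    """

    od: np.ndarray
    pixel_size_um: float
    background: float
    saturation: np.ndarray = None

    def __post_init__(self):
        if self.saturation is None:
            self.saturation = np.zeros(self.od.shape, dtype=bool)

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2


@dataclass
class CalibrationReport:
    """Results of the qualification tests plus the spatial calibration."""

    linearity_r2: float
    uniformity_cv_pct: float
    stability_trace: list = field(default_factory=list)
    stabilized: bool = False
    stabilization_time_min: float | None = None
    um_per_px: float = 1.0
    background: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationReport":
        with open(path) as fh:
            d = json.load(fh)
        d["stability_trace"] = [tuple(t) for t in d.get("stability_trace", [])]
        return cls(**d)


def read_image(path) -> np.ndarray:
    """Read an 8/12/16-bit grayscale TIFF or PNG as a 2-D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:  # collapse trivial colour axes
        if img.shape[-1] in (3, 4):
            img = img[..., 0]
        else:
            img = img.squeeze()
    if img.ndim != 2:
        raise ValidationError(f"expected a 2-D grayscale image, got shape {img.shape}")
    return img


def estimate_background(image, object_mask=None) -> float:
    """Estimate the clear-field intensity I0 as the mode of non-object pixels.

    Chromosomes absorb, so object pixels are dark; without an explicit
    ``object_mask`` the image is split at the Otsu threshold and the bright
    side is taken as background.  The mode is computed on unit-count bins,
    which is robust to the dark tail that would bias a mean.
    """
    img = np.asarray(image, dtype=float)
    if object_mask is not None:
        non_object = ~np.asarray(object_mask, dtype=bool)
    else:
        vals = img[np.isfinite(img)]
        if np.ptp(vals) > 0:
            thr = threshold_otsu(img)
            non_object = img >= thr
        else:
            non_object = np.ones(img.shape, dtype=bool)
    if not non_object.any():
        raise ValidationError("no non-object pixels available for background")
    counts = np.rint(img[non_object]).astype(np.int64)
    counts = counts[counts >= 0]
    if counts.size == 0:
        raise ValidationError("background pixels are all negative")
    return float(np.bincount(counts).argmax())


def to_od(image, background: float, pixel_size_um: float = 1.0) -> ODMap:
    """Beer-Lambert inverse: OD(p) = log10(I0 / I(p)).

    Negative ODs (pixels brighter than I0, i.e. noise) are clipped to 0;
    zero-count pixels are capped at the OD of 0.5 counts and flagged in the
    saturation mask.
    """
    if background <= 0:
        raise ValidationError("background I0 must be positive")
    img = np.asarray(image, dtype=float)
    saturation = img <= 0
    od = np.log10(background / np.clip(img, _FLOOR_COUNTS, None))
    od = np.clip(od, 0.0, None)
    return ODMap(od, pixel_size_um, float(background), saturation)


def linearity_test(nominal_ods, band_masks, od_map) -> float:
    """R-squared of measured mean band OD regressed on nominal band OD."""
    nominal = np.asarray(nominal_ods, dtype=float)
    if len(nominal) < 3:
        raise ValidationError("linearity test needs at least 3 bands")
    if np.ptp(nominal) == 0:
        raise CalibrationError("nominal ODs are identical; fit is singular")
    od = od_map.od if isinstance(od_map, ODMap) else np.asarray(od_map, dtype=float)
    measured = np.array([od[np.asarray(m, dtype=bool)].mean() for m in band_masks])
    fit = stats.linregress(nominal, measured)
    return float(fit.rvalue ** 2)


def uniformity_test(image, grid: int = 8) -> float:
    """Field-uniformity CV (%): 100*sd/mean of per-tile means on a grid.

    Operates on a blank-field intensity image (or OD map); tiling suppresses
    pixel-level shot noise so the statistic tracks illumination structure.
    """
    img = np.asarray(image.od if isinstance(image, ODMap) else image, dtype=float)
    if img.size == 0:
        raise ValidationError("empty image")
    h = (img.shape[0] // grid) * grid
    w = (img.shape[1] // grid) * grid
    if h == 0 or w == 0:
        raise ValidationError(f"image too small for a {grid}x{grid} tile grid")
    tiles = img[:h, :w].reshape(grid, h // grid, grid, w // grid)
    means = tiles.mean(axis=(1, 3))
    mu = means.mean()
    if mu == 0:
        raise CalibrationError("zero mean intensity; CV undefined")
    return float(100.0 * means.std() / mu)


def stability_test(trace, window: int = 3, tol: float = 0.03):
    """First time from which the rolling mean-OD range stays within ``tol``.

    ``trace`` is a sequence of (minutes, mean OD).  The signal counts as
    stabilized at the first timestamp such that every subsequent window of
    ``window`` consecutive samples has max-min <= tol; returns
    (stabilized, time) with time None when the signal never settles.
    """
    pts = sorted((float(t), float(v)) for t, v in trace)
    if len(pts) < 3:
        raise ValidationError("stability test needs at least 3 time points")
    if window < 2 or window > len(pts):
        raise ValidationError("window must be between 2 and the trace length")
    times = [t for t, _ in pts]
    vals = np.array([v for _, v in pts])
    n = len(vals)
    ranges = np.array(
        [vals[k : k + window].max() - vals[k : k + window].min() for k in range(n - window + 1)]
    )
    ok = ranges <= tol
    # first start index from which all later windows are within tolerance
    for i in range(len(ok)):
        if ok[i:].all():
            return True, times[i]
    return False, None
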