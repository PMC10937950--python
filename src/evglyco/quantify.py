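"""Fluorescence quantification: spot readout, calibration curves, colocalization.

Turns the raw measurements of the thermophoretic assay into the scalar
intensities the signature pipeline consumes: the mean fluorescence over the
central accumulation spot (a 100-um-diameter disk by default), a linear
intensity-vs-EV-count calibration with a blank-based limit of detection, and
colocalization fractions with exact binomial confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "FluorescenceImage",
    "CalibrationFit",
    "central_spot_intensity",
    "fit_calibration",
    "colocalization_fraction",
    "read_image",
]


@dataclass
class FluorescenceImage:
    """A 2-D non-negative intensity grid with a physical pixel size [um]."""

    intensity: np.ndarray
    pixel_size: float  # um per pixel

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D grid")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class CalibrationFit:
    slope: float
    intercept: float
    r_squared: float
    lod: float  # EV count at blank mean + 3 sd; 0 flags a degenerate blank set

    def predict(self, counts):
        return self.intercept + self.slope * np.asarray(counts, dtype=float)


def read_image(path) -> FluorescenceImage:
    """Load a grayscale TIFF/PNG or a CSV grid as a FluorescenceImage."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        arr = np.loadtxt(path, delimiter=",")
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path), dtype=float)
        if arr.ndim == 3:  # collapse RGB(A) to luminance
            arr = arr[..., :3].mean(axis=-1)
    return FluorescenceImage(intensity=arr, pixel_size=1.0)


def central_spot_intensity(img: FluorescenceImage, diameter: float = 100.0) -> float:
    """Mean intensity over a disk of ``diameter`` [um] centered in the image."""
    ny, nx = img.intensity.shape
    radius_px = diameter / 2.0 / img.pixel_size
    if 2 * radius_px > min(nx, ny):
        raise ValueError(
            f"{diameter} um disk does not fit in a {ny}x{nx} image at "
            f"{img.pixel_size} um/px")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.ogrid[:ny, :nx]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
    return float(img.intensity[mask].mean())


def fit_calibration(counts, intensities, blanks) -> CalibrationFit:
    """Least-squares line intensity = slope * count + intercept, with the
    limit of detection taken where the line crosses blank mean + 3 sd."""
    counts = np.asarray(counts, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    blanks = np.asarray(blanks, dtype=float)
    if counts.size < 3 or counts.size != intensities.size:
        raise ValueError("need >= 3 aligned (count, intensity) pairs")
    if blanks.size < 3:
        raise ValueError("need >= 3 blank replicates")
    if np.ptp(counts) == 0:
        raise ValueError("calibration counts are all equal")
    res = stats.linregress(counts, intensities)
    if res.slope <= 0:
        lod = np.inf
    else:
        crit = blanks.mean() + 3.0 * blanks.std(ddof=1)
        lod = max((crit - res.intercept) / res.slope, 0.0)
    return CalibrationFit(slope=float(res.slope), intercept=float(res.intercept),
                          r_squared=float(res.rvalue**2), lod=float(lod))


def colocalization_fraction(k: int, n: int, confidence: float = 0.95):
    """Fraction of colocalized events with a Clopper-Pearson CI.

    Returns ``(fraction, (lo, hi), display)`` where ``display`` is the
    percentage rounded to one decimal, e.g. (90, 349) -> '25.8%'.
    """
    if n <= 0 or k < 0 or k > n:
        raise ValueError("require 0 <= k <= n with n > 0")
    frac = k / n
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    display = f"{round(100.0 * frac, 1):.1f}%"
    return frac, (lo, hi), display
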