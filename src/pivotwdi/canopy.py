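"""Fractional canopy cover: NDVI calibration and Otsu percent canopy cover.

Two independent routes to the cover fraction Fc used by the trapezoid:

* a linear NDVI -> Fc calibration, fitted by ordinary least squares against
  reference cover measurements and applied with clamping to [0, 1];
* image thresholding of a single-band reflectance raster with Otsu's
  between-class-variance criterion, returning the fraction of pixels above
  the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

OTSU_BINS = 256


@dataclass(frozen=True)
class FcCalibration:
    """Linear NDVI -> Fc map with fit diagnostics."""

    slope: float
    intercept: float
    ndvi_range: tuple[float, float] = (float("-inf"), float("inf"))
    n_points: int = 0
    r_squared: float = float("nan")


#: Field-derived calibration for a pivot-mounted NDVI sensor over cotton
#: against aerial cover measurements (Fc = 0.9449*NDVI + 0.1539).
COTTON_PIVOT_PRESET = FcCalibration(slope=0.9449, intercept=0.1539,
                                    ndvi_range=(0.0, 0.9))


def fit_fc_calibration(pairs) -> FcCalibration:
    """Ordinary least squares fit of Fc on NDVI.

    ``pairs`` is an iterable of (ndvi, fc) tuples or an (n, 2) array; at
    least three points with non-degenerate NDVI variance are required.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError("need at least 3 (ndvi, fc) pairs")
    ndvi, fc = arr[:, 0], arr[:, 1]
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite calibration pairs")
    if np.ptp(ndvi) == 0.0:
        raise ValidationError("degenerate calibration: NDVI values are all equal")
    res = stats.linregress(ndvi, fc)
    return FcCalibration(slope=float(res.slope), intercept=float(res.intercept),
                         ndvi_range=(float(ndvi.min()), float(ndvi.max())),
                         n_points=int(arr.shape[0]),
                         r_squared=float(res.rvalue ** 2))


def ndvi_to_fc(ndvi, calib: FcCalibration):
    """Apply a calibration: Fc = clamp(slope*ndvi + intercept, 0, 1).

    Returns ``(fc, clamped)``; arrays in, arrays out. Records whose raw
    linear prediction fell outside [0, 1] are flagged.
    """
    arr = np.asarray(ndvi, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite NDVI input")
    raw = calib.slope * arr + calib.intercept
    clamped = (raw < 0.0) | (raw > 1.0)
    fc = np.clip(raw, 0.0, 1.0)
    if np.isscalar(ndvi) or arr.ndim == 0:
        return float(fc), bool(clamped)
    return fc, clamped


def otsu_canopy_cover(raster) -> tuple[float, float]:
    """Otsu threshold and canopy fraction for a reflectance raster.

    The threshold maximizes the between-class variance over a histogram of
    ``OTSU_BINS`` equal-width bins spanning the finite pixel range, with
    ties broken toward the lower threshold; the returned cover fraction is
    the share of finite pixels strictly above the threshold. NaN encodes
    nodata.
    """
    arr = np.asarray(raster, dtype=float)
    vals = arr[np.isfinite(arr)]
    if vals.size == 0:
        raise ValidationError("raster has no finite pixels")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        raise ValidationError("constant raster: no separable classes")
    counts, edges = np.histogram(vals, bins=OTSU_BINS, range=(lo, hi))

    # The between-class variance w0*w1*(mu0-mu1)^2 is invariant to affine
    # maps of the bin values, so evaluate it on integer bin indices with
    # exact integer arithmetic: ties across empty-bin plateaus then resolve
    # deterministically toward the lower threshold.
    c = [int(v) for v in counts]
    total = sum(c)
    mass_total = sum(i * c[i] for i in range(OTSU_BINS))
    best_num, best_den, best_t = -1, 1, 0
    w0 = m0 = 0
    for t in range(OTSU_BINS - 1):
        w0 += c[t]
        m0 += t * c[t]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        num = (m0 * w1 - (mass_total - m0) * w0) ** 2
        den = w0 * w1
        if num * best_den > best_num * den:  # strict: keep the lower threshold on ties
            best_num, best_den, best_t = num, den, t
    threshold = float(edges[best_t + 1])
    fc = float(np.count_nonzero(vals > threshold) / vals.size)
    return threshold, fc
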