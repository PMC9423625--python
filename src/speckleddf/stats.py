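"""Axial circular statistics, ROI reports and the precision-scaling fit.

Orientations are axial (defined modulo 180 degrees): statistics are computed
on doubled angles and halved back, so adding 180 degrees to any subset of a
sample changes nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ROISpec",
    "AxialSample",
    "PowerLawFit",
    "InsufficientDataError",
    "axial_mean_and_std",
    "independent_measurements",
    "fit_power_law",
    "tube_angle_from_points",
    "roi_report",
    "polar_histogram",
    "wrap_axial",
]


def wrap_axial(angle_deg):
    """Wrap axial angles (mod 180) into (-90, 90]."""
    a = np.mod(np.asarray(angle_deg, float) + 90.0, 180.0) - 90.0
    a = np.where(a == -90.0, 90.0, a)
    return float(a) if a.ndim == 0 else a


class InsufficientDataError(ValueError):
    """Too few points survive the exclusion threshold."""


@dataclass(frozen=True)
class ROISpec:
    """Square region of interest, given by centre (row, col) and side length."""

    centre: tuple[int, int]
    size: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("ROI size must be >= 1")

    def slices(self) -> tuple[slice, slice]:
        h = self.size // 2
        r, c = self.centre
        return slice(r - h, r - h + self.size), slice(c - h, c - h + self.size)


@dataclass(frozen=True)
class AxialSample:
    """A sample of axial angles in degrees (interpreted modulo 180)."""

    angles: np.ndarray

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.angles, float)).ravel()
        a = a[np.isfinite(a)]
        if a.size == 0:
            raise ValueError("empty axial sample")
        object.__setattr__(self, "angles", a)


@dataclass(frozen=True)
class PowerLawFit:
    """Weighted log-log fit of sigma_theta = A * P**B."""

    amplitude: float
    exponent: float
    amplitude_err: float
    exponent_err: float
    chi2_reduced: float
    exclude_below: float
    n_points: int


def axial_mean_and_std(sample: AxialSample) -> tuple[float, float]:
    """Circular mean and standard deviation of axial angles, in degrees.

    Double-angle method: the angles are doubled, the circular mean/std of the
    doubled sample is taken and halved.  The mean is reported in (-90, 90].
    For a wrapped-normal sample the std estimator is consistent with the
    generating sigma.
    """
    d = np.radians(2.0 * sample.angles)
    c, s = np.cos(d).mean(), np.sin(d).mean()
    r = math.hypot(c, s)
    mean = wrap_axial(0.5 * math.degrees(math.atan2(s, c)))
    if r <= 0.0:
        return mean, float("inf")
    std = 0.5 * math.degrees(math.sqrt(max(-2.0 * math.log(r), 0.0)))
    return mean, std


def independent_measurements(window_size: int, n_positions: int) -> int:
    """P = window pixels times diffuser positions."""
    if window_size < 1 or n_positions < 1:
        raise ValueError("window_size and n_positions must be positive")
    return int(window_size) ** 2 * int(n_positions)


def fit_power_law(points, exclude_below: float = 50.0) -> PowerLawFit:
    """Fit sigma_theta = A * P**B by (weighted) linear regression in log-log.

    ``points`` is a sequence of ``(P, sigma_theta)`` or
    ``(P, sigma_theta, err)`` tuples; when errors are supplied the fit is
    weighted by the log-transformed standard errors.  Points with
    ``P < exclude_below`` are dropped before fitting.
    """
    arr = np.asarray([tuple(p) for p in points], float)
    if arr.ndim != 2 or arr.shape[1] not in (2, 3):
        raise ValueError("points must be (P, sigma) or (P, sigma, err) tuples")
    keep = arr[:, 0] >= exclude_below
    arr = arr[keep]
    n = arr.shape[0]
    if n < 3:
        raise InsufficientDataError(
            f"only {n} points with P >= {exclude_below}; need at least 3"
        )
    x = np.log(arr[:, 0])
    y = np.log(arr[:, 1])
    if arr.shape[1] == 3 and np.all(arr[:, 2] > 0):
        s = arr[:, 2] / arr[:, 1]  # propagate to log space
        weighted = True
    else:
        s = np.ones(n)
        weighted = False
    w = 1.0 / s**2
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    delta = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / delta
    intercept = (sxx * sy - sx * sxy) / delta
    resid = y - (intercept + slope * x)
    chi2 = float((w * resid**2).sum())
    dof = n - 2
    chi2_red = chi2 / dof if dof > 0 else float("nan")
    var_slope = sw / delta
    var_intercept = sxx / delta
    if not weighted and dof > 0:
        # unweighted: scale parameter errors by the residual variance
        var_slope *= chi2_red
        var_intercept *= chi2_red
    amplitude = math.exp(intercept)
    return PowerLawFit(
        amplitude=amplitude,
        exponent=float(slope),
        amplitude_err=amplitude * math.sqrt(max(var_intercept, 0.0)),
        exponent_err=math.sqrt(max(var_slope, 0.0)),
        chi2_reduced=chi2_red,
        exclude_below=float(exclude_below),
        n_points=n,
    )


def tube_angle_from_points(
    p1: tuple[float, float],
    p2: tuple[float, float],
    position_error: float = 2.0,
) -> tuple[float, float]:
    """Angle of the line p1-p2 to the horizontal, with propagated error.

    Points are (x, y) pixel positions; the returned angle is axial, in
    degrees.  ``position_error`` is the 1-sigma uncertainty of each coordinate
    of both points; to first order the angle error is
    ``sqrt(2) * position_error / |p2 - p1|`` radians.
    """
    dx = float(p2[0]) - float(p1[0])
    dy = float(p2[1]) - float(p1[1])
    length = math.hypot(dx, dy)
    if length == 0.0:
        raise ValueError("points must not coincide")
    angle = wrap_axial(math.degrees(math.atan2(dy, dx)))
    err = math.degrees(math.sqrt(2.0) * float(position_error) / length)
    return angle, err


def polar_histogram(sample: AxialSample, bins: int = 36):
    """Histogram of axial angles over (-90, 90]; counts sum to the sample size."""
    edges = np.linspace(-90.0, 90.0, bins + 1)
    wrapped = wrap_axial(sample.angles)
    counts, _ = np.histogram(np.clip(wrapped, -90.0 + 1e-12, 90.0), bins=edges)
    return counts, edges


def roi_report(
    theta_map: np.ndarray,
    rois: list[ROISpec],
    reference_angles,
    reference_errors=None,
    valid: np.ndarray | None = None,
    allow_partial: bool = False,
) -> pd.DataFrame:
    """Per-ROI axial mean/std of theta and deviation from orthogonality.

    ``reference_angles`` are the tube angles phi (degrees); the deviation
    column is ``<theta> - phi - 90`` wrapped to the axial interval.  ROIs
    containing masked or non-finite pixels raise unless ``allow_partial``.
    """
    theta = np.asarray(theta_map, float)
    if len(rois) != len(list(reference_angles)):
        raise ValueError("need one reference angle per ROI")
    if reference_errors is None:
        reference_errors = [np.nan] * len(rois)
    rows = []
    for i, (roi, phi, phi_err) in enumerate(
        zip(rois, reference_angles, reference_errors)
    ):
        sl = roi.slices()
        if (
            sl[0].start < 0
            or sl[1].start < 0
            or sl[0].stop > theta.shape[0]
            or sl[1].stop > theta.shape[1]
        ):
            raise ValueError(f"ROI {i} extends outside the map")
        patch = theta[sl]
        ok = np.isfinite(patch)
        if valid is not None:
            ok &= valid[sl]
        if not ok.all() and not allow_partial:
            raise ValueError(f"ROI {i} overlaps masked or unsolved pixels")
        if not ok.any():
            raise ValueError(f"ROI {i} contains no valid pixels")
        mean, std = axial_mean_and_std(AxialSample(patch[ok]))
        rows.append(
            {
                "roi": i,
                "phi_deg": float(phi),
                "phi_err_deg": float(phi_err),
                "theta_mean_deg": mean,
                "theta_std_deg": std,
                "deviation_deg": wrap_axial(mean - float(phi) - 90.0),
                "n_pixels": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)
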