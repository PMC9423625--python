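"""Derived dark-field quantities: mean width, directionality, orientation.

Per-pixel summaries of the fitted blur kernel::

    sigma^2 = (alpha1 + alpha3) / (2 * (alpha1*alpha3 - alpha2^2))
    epsilon = (sigma_M^2 - sigma_m^2) / (sigma_M^2 + sigma_m^2)
            = sqrt((alpha3 - alpha1)^2 + 4*alpha2^2) / (alpha1 + alpha3)
    theta   = axial orientation of the wide axis (see model module docstring)

plus refraction-angle conversion and the HSV composite display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .model import BlurKernelParams, GeometrySpec, alpha_to_axes

__all__ = [
    "ISOTROPY_EPS",
    "DarkFieldSummary",
    "RefractionMaps",
    "darkfield_summary",
    "summary_maps",
    "refraction_maps",
    "hsv_composite",
]

#: Below this directionality the orientation is numerically undefined; theta is
#: reported as 0 and flagged.
ISOTROPY_EPS = 0.02


@dataclass(frozen=True)
class DarkFieldSummary:
    """Mean kernel width (px), directionality in [0, 1), axial angle (deg)."""

    sigma: float
    eccentricity: float
    theta: float
    isotropic: bool = False

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")
        if not (0.0 <= self.eccentricity < 1.0):
            raise ValueError("eccentricity must lie in [0, 1)")


@dataclass(frozen=True)
class RefractionMaps:
    """Refraction angles u * pixel_size / d, in microradians."""

    angle_x: np.ndarray
    angle_y: np.ndarray


def darkfield_summary(params: BlurKernelParams) -> DarkFieldSummary:
    """Summarise a kernel as (sigma, eccentricity, theta).

    Identical to recomputing through :func:`~speckleddf.model.alpha_to_axes`:
    ``sigma^2 = (sigma_M^2 + sigma_m^2)/2`` and
    ``eccentricity = (sigma_M^2 - sigma_m^2)/(sigma_M^2 + sigma_m^2)``.
    """
    a1, a2, a3 = params.astuple()
    det = params.determinant
    sigma = math.sqrt(0.5 * (a1 + a3) / det)
    ecc = math.sqrt((a3 - a1) ** 2 + 4.0 * a2 * a2) / (a1 + a3)
    iso = ecc < ISOTROPY_EPS
    theta = 0.0 if iso else alpha_to_axes(params).theta
    return DarkFieldSummary(sigma=sigma, eccentricity=ecc, theta=theta, isotropic=iso)


def summary_maps(
    alpha1: np.ndarray, alpha2: np.ndarray, alpha3: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorised :func:`darkfield_summary` over whole alpha maps.

    Returns a dict with keys ``sigma``, ``eccentricity``, ``theta_deg`` and the
    boolean ``isotropic`` companion mask.  Pixels with non-positive-definite
    alphas yield NaN.
    """
    a1 = np.asarray(alpha1, float)
    a2 = np.asarray(alpha2, float)
    a3 = np.asarray(alpha3, float)
    det = a1 * a3 - a2 * a2
    with np.errstate(invalid="ignore", divide="ignore"):
        valid = (a1 > 0) & (a3 > 0) & (det > 0)
        sigma = np.where(valid, np.sqrt(0.5 * (a1 + a3) / np.where(det > 0, det, 1.0)), np.nan)
        ecc = np.where(valid, np.hypot(a3 - a1, 2.0 * a2) / (a1 + a3), np.nan)
        theta = 0.5 * np.degrees(np.arctan2(-2.0 * a2, a3 - a1))
    theta = np.where(theta <= -90.0, theta + 180.0, theta)
    iso = ecc < ISOTROPY_EPS
    theta = np.where(iso, 0.0, theta)
    theta = np.where(valid, theta, np.nan)
    return {
        "sigma": sigma,
        "eccentricity": ecc,
        "theta_deg": theta,
        "isotropic": iso & valid,
    }


def refraction_maps(
    u_x: np.ndarray, u_y: np.ndarray, geometry: GeometrySpec
) -> RefractionMaps:
    """Convert shift maps (pixels) to refraction angles in microradians."""
    scale = 1e6 * geometry.pixel_size / geometry.distance_d
    return RefractionMaps(
        angle_x=np.asarray(u_x, float) * scale,
        angle_y=np.asarray(u_y, float) * scale,
    )


def hsv_composite(
    theta_deg: np.ndarray,
    eccentricity: np.ndarray,
    sigma: np.ndarray,
    value_clip: float = 99.0,
) -> np.ndarray:
    """Compose orientation/directionality/width into an RGB image.

    Hue encodes the axial orientation, ``H = (theta + 90)/180`` (so -90 and
    +90 degrees map to the same hue); saturation is the directionality clipped
    to [0, 1]; value is the mean width normalised by its ``value_clip``-th
    percentile.  Non-finite inputs render black.
    """
    theta = np.asarray(theta_deg, float)
    ecc = np.asarray(eccentricity, float)
    sig = np.asarray(sigma, float)
    if not (theta.shape == ecc.shape == sig.shape):
        raise ValueError("maps must share shape")
    bad = ~(np.isfinite(theta) & np.isfinite(ecc) & np.isfinite(sig))
    h = np.mod(theta + 90.0, 180.0) / 180.0
    s = np.clip(ecc, 0.0, 1.0)
    finite_sig = sig[np.isfinite(sig)]
    vmax = np.percentile(finite_sig, value_clip) if finite_sig.size else 1.0
    v = np.clip(sig / vmax, 0.0, 1.0) if vmax > 0 else np.zeros_like(sig)
    h[bad] = 0.0
    s[bad] = 0.0
    v[bad] = 0.0
    return hsv_to_rgb(np.stack([h, s, v], axis=-1))
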