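"""Forward image-formation model for speckle-based directional dark-field imaging.

A sample frame is modelled as the reference speckle pattern, locally scaled by
a transmittance ``T``, convolved with an anisotropic Gaussian blurring kernel
``K_alpha`` and sampled at a sub-pixel lateral shift ``u``::

    model(r) = T * (I0 * K_alpha)(r + u)

Coordinate conventions (used consistently across the package)
-------------------------------------------------------------
* Arrays are indexed ``[row, col]``; ``x`` is the column offset and ``y`` the
  row offset.
* The kernel orientation ``theta`` is the axial angle of the *wide* principal
  axis, measured from the +x axis towards the +y axis, in degrees, wrapped to
  ``(-90, 90]``.  When an array is displayed with ``origin='lower'`` this is
  the usual counter-clockwise angle from horizontal.
* Shifts are passed as ``u = (u_x, u_y)`` in pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "InvalidKernelError",
    "BlurKernelParams",
    "KernelImage",
    "PrincipalAxes",
    "GeometrySpec",
    "SpeckleFrameSet",
    "PixelSolution",
    "WIDTH_DELTA_FLOOR",
    "evaluate_kernel",
    "alpha_to_axes",
    "axes_to_alpha",
    "model_intensity",
]

#: Kernel widths (in pixels) below this value are numerically indistinguishable
#: from a discrete delta once rasterised on the pixel grid.
WIDTH_DELTA_FLOOR = 0.05


class InvalidKernelError(ValueError):
    """Raised when kernel parameters do not define a normalisable Gaussian."""


@dataclass(frozen=True)
class BlurKernelParams:
    """Inverse-covariance parameters ``(alpha1, alpha2, alpha3)`` of the kernel.

    The kernel is ``K(x, y) ∝ exp(-(alpha1*x² + 2*alpha2*x*y + alpha3*y²)/2)``,
    so ``[[alpha1, alpha2], [alpha2, alpha3]]`` must be positive definite.
    Units are inverse square pixels.
    """

    alpha1: float
    alpha2: float
    alpha3: float

    def __post_init__(self) -> None:
        if not (self.alpha1 > 0):
            raise InvalidKernelError(f"alpha1 > 0 violated (alpha1={self.alpha1})")
        if not (self.alpha3 > 0):
            raise InvalidKernelError(f"alpha3 > 0 violated (alpha3={self.alpha3})")
        det = self.alpha1 * self.alpha3 - self.alpha2**2
        if not (det > 0):
            raise InvalidKernelError(
                "alpha1*alpha3 - alpha2**2 > 0 violated "
                f"(det={det}; alpha={self.astuple()})"
            )

    def astuple(self) -> tuple[float, float, float]:
        return (self.alpha1, self.alpha2, self.alpha3)

    @property
    def matrix(self) -> np.ndarray:
        """The symmetric 2x2 inverse-covariance matrix (x, y ordering)."""
        return np.array(
            [[self.alpha1, self.alpha2], [self.alpha2, self.alpha3]], float
        )

    @property
    def determinant(self) -> float:
        return self.alpha1 * self.alpha3 - self.alpha2**2


@dataclass(frozen=True)
class KernelImage:
    """A rasterised kernel on an odd pixel grid centred at the origin."""

    weights: np.ndarray
    support_radius: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] % 2 == 0:
            raise ValueError("kernel weights must be a square odd-sized array")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class PrincipalAxes:
    """Principal widths (pixels) and axial orientation (degrees) of a kernel."""

    sigma_major: float
    sigma_minor: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.sigma_minor > 0):
            raise ValueError(f"sigma_minor must be > 0 (got {self.sigma_minor})")
        if self.sigma_major < self.sigma_minor:
            raise ValueError(
                f"sigma_major ({self.sigma_major}) < sigma_minor ({self.sigma_minor})"
            )


@dataclass(frozen=True)
class GeometrySpec:
    """Imaging geometry: pixel size (m) in the sample plane, propagation distance (m)."""

    pixel_size: float
    distance_d: float

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0 and self.distance_d > 0):
            raise ValueError("pixel_size and distance_d must be strictly positive")


@dataclass
class SpeckleFrameSet:
    """Paired sample / reference stacks over N diffuser positions."""

    sample: np.ndarray
    reference: np.ndarray
    geometry: GeometrySpec = field(
        default_factory=lambda: GeometrySpec(pixel_size=21.5e-6, distance_d=6.65)
    )

    def __post_init__(self) -> None:
        self.sample = np.ascontiguousarray(self.sample, dtype=np.float64)
        self.reference = np.ascontiguousarray(self.reference, dtype=np.float64)
        if self.sample.ndim != 3 or self.reference.ndim != 3:
            raise ValueError("sample and reference must be (N, H, W) stacks")
        if self.sample.shape != self.reference.shape:
            raise ValueError(
                f"sample shape {self.sample.shape} != reference shape "
                f"{self.reference.shape}"
            )
        if self.sample.shape[0] < 1:
            raise ValueError("need at least one frame pair")
        if not (np.isfinite(self.sample).all() and np.isfinite(self.reference).all()):
            raise ValueError("intensities must be finite")
        if np.any(self.sample < 0) or np.any(self.reference < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_positions(self) -> int:
        return self.sample.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.sample.shape[1:]


@dataclass
class PixelSolution:
    """Model parameters fitted at one pixel."""

    T: float
    u: tuple[float, float]
    kernel: BlurKernelParams
    residual: float
    converged: bool = False

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValueError("residual must be >= 0")


# ---------------------------------------------------------------------------
# Kernel rasterisation and axis conversions
# ---------------------------------------------------------------------------


def _eigvals_2x2(a1: float, a2: float, a3: float) -> tuple[float, float]:
    """Eigenvalues (min, max) of [[a1, a2], [a2, a3]] in closed form."""
    half_tr = 0.5 * (a1 + a3)
    disc = math.hypot(0.5 * (a1 - a3), a2)
    return half_tr - disc, half_tr + disc


def alpha_to_axes(params: BlurKernelParams) -> PrincipalAxes:
    """Principal widths and orientation of the kernel.

    The kernel covariance is the inverse of the alpha matrix, so the wide
    (major) axis corresponds to the *smallest* eigenvalue of the alpha matrix:
    ``sigma_major = 1/sqrt(lambda_min)``.  ``theta`` follows the package-wide
    axial convention (see module docstring); for an isotropic kernel it is
    reported as 0.
    """
    a1, a2, a3 = params.astuple()
    lam_min, lam_max = _eigvals_2x2(a1, a2, a3)
    # det > 0 and trace > 0 guarantee lam_min > 0
    theta = 0.5 * math.degrees(math.atan2(-2.0 * a2, a3 - a1))
    if theta <= -90.0:
        theta += 180.0
    return PrincipalAxes(
        sigma_major=1.0 / math.sqrt(lam_min),
        sigma_minor=1.0 / math.sqrt(lam_max),
        theta=theta,
    )


def _alpha_from_widths(
    sigma_a: float, sigma_b: float, theta_deg: float
) -> tuple[float, float, float]:
    """Alpha triple for widths ``sigma_a`` along ``theta`` and ``sigma_b`` across.

    No ordering is imposed; used both by :func:`axes_to_alpha` and by the
    solver's unconstrained width parameterisation.
    """
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    ia, ib = 1.0 / sigma_a**2, 1.0 / sigma_b**2
    a1 = c * c * ia + s * s * ib
    a2 = s * c * (ia - ib)
    a3 = s * s * ia + c * c * ib
    return a1, a2, a3


def axes_to_alpha(axes: PrincipalAxes) -> BlurKernelParams:
    """Inverse of :func:`alpha_to_axes` (positive definite by construction)."""
    a1, a2, a3 = _alpha_from_widths(axes.sigma_major, axes.sigma_minor, axes.theta)
    return BlurKernelParams(a1, a2, a3)


def evaluate_kernel(
    params: BlurKernelParams, support_radius: int | None = None
) -> KernelImage:
    """Rasterise the kernel on an odd pixel grid, normalised to unit sum.

    The automatic support radius is ``ceil(4 * sigma_major)`` (at least 1),
    which truncates less than 0.1% of the Gaussian mass.  Widths below
    :data:`WIDTH_DELTA_FLOOR` degenerate to a discrete delta on the grid.
    """
    axes = alpha_to_axes(params)
    if support_radius is None:
        support_radius = max(1, math.ceil(4.0 * axes.sigma_major))
    elif support_radius < 1:
        raise ValueError("support_radius must be >= 1")
    weights = _raster_kernel(*params.astuple(), support_radius)
    return KernelImage(weights=weights, support_radius=int(support_radius))


def _raster_kernel(a1: float, a2: float, a3: float, radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    q = a1 * x * x + 2.0 * a2 * x * y + a3 * y * y
    w = np.exp(-0.5 * np.clip(q, 0.0, 1400.0))
    # centre weight is exp(0)=1, so the sum can never vanish
    return w / w.sum()


# ---------------------------------------------------------------------------
# Sub-pixel sampling and the forward model
# ---------------------------------------------------------------------------


def _cr_weights(f: float) -> np.ndarray:
    """Catmull-Rom cubic interpolation taps for fractional offset f in [0, 1)."""
    f2, f3 = f * f, f * f * f
    return np.array(
        [
            -0.5 * f3 + f2 - 0.5 * f,
            1.5 * f3 - 2.5 * f2 + 1.0,
            -1.5 * f3 + 2.0 * f2 + 0.5 * f,
            0.5 * f3 - 0.5 * f2,
        ]
    )


def sample_shifted(image: np.ndarray, u: tuple[float, float]) -> np.ndarray:
    """Sample ``image`` at ``r + u`` with Catmull-Rom interpolation.

    ``u = (u_x, u_y)`` in pixels; mirror boundary handling.  At integer ``u``
    this reduces to an exact translated copy.
    """
    ux, uy = float(u[0]), float(u[1])
    mx, my = math.floor(ux), math.floor(uy)
    wx, wy = _cr_weights(ux - mx), _cr_weights(uy - my)
    pad = max(abs(mx), abs(my)) + 2
    padded = np.pad(np.asarray(image, float), pad, mode="reflect")
    h, w = image.shape
    out = np.zeros((h, w))
    for ty in range(4):
        if wy[ty] == 0.0:
            continue
        oy = pad + my + ty - 1
        row_block = padded[oy : oy + h]
        acc = np.zeros((h, w))
        for tx in range(4):
            if wx[tx] == 0.0:
                continue
            ox = pad + mx + tx - 1
            acc += wx[tx] * row_block[:, ox : ox + w]
        out += wy[ty] * acc
    return out


def model_intensity(
    reference_frame: np.ndarray,
    T: float,
    u: tuple[float, float],
    params: BlurKernelParams,
    max_shift: float | None = None,
) -> np.ndarray:
    """Forward model: ``T * (reference * K_alpha)(r + u)``.

    The reference is convolved with the unit-sum rasterised kernel (mirror
    boundaries) and resampled at ``r + u`` with Catmull-Rom interpolation;
    interpolation undershoot is clipped at zero.
    """
    ref = np.asarray(reference_frame, float)
    if ref.ndim != 2:
        raise ValueError("reference_frame must be 2-D")
    limit = (
        float(max_shift)
        if max_shift is not None
        else min(ref.shape) / 2.0 - 2.0
    )
    if max(abs(u[0]), abs(u[1])) > limit:
        raise ValueError(f"shift {u} exceeds maximum allowed |u| = {limit}")
    kernel = evaluate_kernel(params)
    # the kernel is point symmetric, so correlation equals convolution
    blurred = ndimage.correlate(ref, kernel.weights, mode="mirror")
    out = sample_shifted(blurred, u)
    return float(T) * np.clip(out, 0.0, None)
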