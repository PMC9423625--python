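"""Independent brute-force oracles used by the test suite.

Everything here is written from the model definition directly (explicit
loops, no package internals) so it can serve as an independent check of the
package's vectorised/compiled implementations.
"""

from __future__ import annotations

import math

import numpy as np


def gaussian_kernel_bruteforce(a1: float, a2: float, a3: float, radius: int) -> np.ndarray:
    """Pixel-centre rasterisation of the anisotropic Gaussian, unit sum."""
    size = 2 * radius + 1
    out = np.empty((size, size))
    for iy in range(size):
        for ix in range(size):
            x, y = ix - radius, iy - radius
            out[iy, ix] = math.exp(-0.5 * (a1 * x * x + 2 * a2 * x * y + a3 * y * y))
    return out / out.sum()


def kernel_moments_integral(a1: float, a2: float, a3: float, extent: float = 12.0,
                            step: float = 0.02) -> np.ndarray:
    """Covariance of the continuous kernel by dense numerical integration."""
    g = np.arange(-extent, extent + step / 2, step)
    x, y = np.meshgrid(g, g)
    w = np.exp(-0.5 * (a1 * x * x + 2 * a2 * x * y + a3 * y * y))
    w /= w.sum()
    return np.array(
        [
            [(w * x * x).sum(), (w * x * y).sum()],
            [(w * x * y).sum(), (w * y * y).sum()],
        ]
    )


def raster_moment_axes(weights: np.ndarray) -> tuple[float, float, float]:
    """(sigma_major, sigma_minor, theta_deg) from discrete kernel moments."""
    r = weights.shape[0] // 2
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    cxx = (weights * x * x).sum()
    cyy = (weights * y * y).sum()
    cxy = (weights * x * y).sum()
    theta = 0.5 * math.degrees(math.atan2(2 * cxy, cxx - cyy))
    if theta <= -90.0:
        theta += 180.0
    half = 0.5 * (cxx + cyy)
    disc = math.hypot(0.5 * (cxx - cyy), cxy)
    return math.sqrt(half + disc), math.sqrt(half - disc), theta


def _cr_value(v0: float, v1: float, v2: float, v3: float, f: float) -> float:
    """Catmull-Rom interpolation between v1 and v2 at fraction f."""
    return (
        v1
        + 0.5 * f * (v2 - v0 + f * (2 * v0 - 5 * v1 + 4 * v2 - v3
                                    + f * (3 * (v1 - v2) + v3 - v0)))
    )


def straight_loop_cost(
    sample: np.ndarray,
    reference: np.ndarray,
    gamma: np.ndarray,
    r0: tuple[int, int],
    T: float,
    u: tuple[float, float],
    alpha: tuple[float, float, float],
) -> float:
    """Direct double-sum evaluation of the windowed least-squares cost.

    Kernel rasterised at pixel centres with support ceil(4*sigma_major);
    mirror boundaries; Catmull-Rom sampling of the blurred reference at the
    shifted positions.  Pure python loops throughout.
    """
    a1, a2, a3 = alpha
    half_tr = 0.5 * (a1 + a3)
    lam_min = half_tr - math.hypot(0.5 * (a1 - a3), a2)
    radius = max(1, math.ceil(4.0 / math.sqrt(lam_min)))
    kern = gaussian_kernel_bruteforce(a1, a2, a3, radius)
    h, w = reference.shape[1:]

    def mirror(i: int, n: int) -> int:
        period = 2 * n - 2
        i = abs(i) % period
        return period - i if i >= n else i

    def blurred(j: int, yy: int, xx: int) -> float:
        acc = 0.0
        for a in range(-radius, radius + 1):
            for b in range(-radius, radius + 1):
                acc += kern[a + radius, b + radius] * reference[
                    j, mirror(yy + a, h), mirror(xx + b, w)
                ]
        return acc

    ux, uy = u
    mx, my = math.floor(ux), math.floor(uy)
    fx, fy = ux - mx, uy - my
    wh = gamma.shape[0] // 2
    cost = 0.0
    for j in range(sample.shape[0]):
        for dy in range(-wh, wh + 1):
            for dx in range(-wh, wh + 1):
                yy, xx = r0[0] + dy, r0[1] + dx
                rows = []
                for t in range(4):
                    vals = [
                        blurred(j, yy + my + t - 1, xx + mx + s - 1)
                        for s in range(4)
                    ]
                    rows.append(_cr_value(*vals, fx))
                model = T * _cr_value(*rows, fy)
                diff = sample[j, yy, xx] - model
                cost += gamma[dy + wh, dx + wh] * diff * diff
    return cost


def autocorrelation_fwhm(image: np.ndarray) -> float:
    """FWHM (pixels) of the azimuthally-averaged FFT autocorrelation."""
    f = image - image.mean()
    power = np.abs(np.fft.rfft2(f)) ** 2
    ac = np.fft.irfft2(power, s=f.shape)
    ac /= ac[0, 0]
    # half-max crossing along both axes, linear interpolation
    results = []
    for profile in (ac[0, : image.shape[1] // 2], ac[: image.shape[0] // 2, 0]):
        below = np.nonzero(profile < 0.5)[0]
        if below.size == 0:
            return float("nan")
        i = below[0]
        frac = (profile[i - 1] - 0.5) / (profile[i - 1] - profile[i])
        results.append(2.0 * (i - 1 + frac))
    return float(np.mean(results))
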