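"""Per-pixel retrieval of (T, u, alpha) by windowed nonlinear least squares.

The cost at pixel r0 is::

    L(r0; T, u, alpha) = sum_r sum_j Gamma(r - r0) * |I_j(r) - T*(I0_j * K_alpha)(r + u)|^2

summed over an odd tapered window and all N frame pairs.  T is eliminated in
closed form (the cost is quadratic in T), the remaining five parameters
(u_x, u_y, log-widths, angle) are minimised with a derivative-free local
method, and a coarse-to-fine multi-resolution cascade provides robust
initialisation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize

from . import _fast
from .model import (
    WIDTH_DELTA_FLOOR,
    BlurKernelParams,
    PixelSolution,
    SpeckleFrameSet,
    _alpha_from_widths,
    _cr_weights,
    _raster_kernel,
    alpha_to_axes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "SolverConfig",
    "SignalMaps",
    "DegenerateWindowError",
    "cost_function",
    "optimal_transmission",
    "solve_pixel",
    "solve_level",
    "multires_solve",
]


class DegenerateWindowError(ZeroDivisionError):
    """The model term vanishes identically inside the window."""


@dataclass(frozen=True)
class WindowSpec:
    """Odd analysis window with a tapered weight array (max weight 1)."""

    size: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError("window size must be odd and >= 3")
        w = np.asarray(self.weights, float)
        if w.shape != (self.size, self.size):
            raise ValueError("weights shape must match window size")
        if w[self.size // 2, self.size // 2] <= 0:
            raise ValueError("window weight at centre must be positive")
        object.__setattr__(self, "weights", np.ascontiguousarray(w / w.max()))

    @classmethod
    def hamming(cls, size: int) -> "WindowSpec":
        """Separable 2-D Hamming taper (the default analysis window)."""
        taper = np.hamming(size)
        return cls(size=size, weights=np.outer(taper, taper))

    @classmethod
    def flat(cls, size: int) -> "WindowSpec":
        return cls(size=size, weights=np.ones((size, size)))

    @property
    def half(self) -> int:
        return self.size // 2


@dataclass(frozen=True)
class SolverConfig:
    """Configuration of the per-pixel solver and multi-resolution cascade."""

    window: WindowSpec = field(default_factory=lambda: WindowSpec.hamming(7))
    levels: tuple[int, ...] = (4, 2, 1)
    max_shift: float = 5.0
    width_bounds: tuple[float, float] = (0.02, 3.0)
    grid_widths: tuple[float, ...] = (WIDTH_DELTA_FLOOR, 0.5, 1.0, 2.0)
    cost_tol: float = 1e-8
    param_tol: float = 1e-3
    max_evals: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        lv = tuple(int(f) for f in self.levels)
        if not lv or lv[-1] != 1 or any(a <= b for a, b in zip(lv, lv[1:])):
            raise ValueError("levels must be strictly decreasing and end at 1")
        for a, b in zip(lv, lv[1:]):
            if a % b != 0:
                raise ValueError("each level factor must be divisible by the next")
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        lo, hi = self.width_bounds
        if not (0 < lo < hi):
            raise ValueError("width_bounds must satisfy 0 < lo < hi")
        object.__setattr__(self, "levels", lv)

    @property
    def support_max(self) -> int:
        return max(1, math.ceil(4.0 * self.width_bounds[1]))

    @property
    def patch_margin(self) -> int:
        return self.support_max + math.ceil(self.max_shift) + 2

    @property
    def margin(self) -> int:
        """Excluded border width: window half + shift + kernel support + taps."""
        return self.window.half + self.patch_margin


@dataclass
class SignalMaps:
    """Whole-image retrieval output; NaN outside the validity mask."""

    T: np.ndarray
    u_x: np.ndarray
    u_y: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    alpha3: np.ndarray
    residual: np.ndarray
    valid: np.ndarray
    margin: int = 0

    _FIELDS = ("T", "u_x", "u_y", "alpha1", "alpha2", "alpha3", "residual")

    @classmethod
    def empty(cls, shape: tuple[int, int], margin: int = 0) -> "SignalMaps":
        nan = lambda: np.full(shape, np.nan)
        return cls(
            T=nan(), u_x=nan(), u_y=nan(),
            alpha1=nan(), alpha2=nan(), alpha3=nan(),
            residual=nan(), valid=np.zeros(shape, bool), margin=margin,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.T.shape

    def as_dict(self) -> dict[str, np.ndarray]:
        out = {name: getattr(self, name) for name in self._FIELDS}
        out["valid"] = self.valid
        return out


# ---------------------------------------------------------------------------
# Cost evaluation
# ---------------------------------------------------------------------------


def _sums_at(
    frames: SpeckleFrameSet,
    window: WindowSpec,
    r0: tuple[int, int],
    u: tuple[float, float],
    kernel: np.ndarray,
) -> tuple[float, float, float]:
    ux, uy = float(u[0]), float(u[1])
    mx, my = math.floor(ux), math.floor(uy)
    crx = np.ascontiguousarray(_cr_weights(ux - mx))
    cry = np.ascontiguousarray(_cr_weights(uy - my))
    ks = kernel.shape[0]
    sh = ks // 2
    r0y, r0x = int(r0[0]), int(r0[1])
    wh = window.half
    sy, sx = r0y - wh, r0x - wh
    by, bx = sy - sh + my - 1, sx - sh + mx - 1
    p = window.size + ks - 1
    h, w = frames.frame_shape
    if sy < 0 or sx < 0 or sy + window.size > h or sx + window.size > w:
        raise ValueError(f"window at r0={r0} exceeds frame bounds")
    if by < 0 or bx < 0 or by + p + 3 > h or bx + p + 3 > w:
        raise ValueError(
            f"r0={r0} is inside the margin for shift {u} and kernel support {sh}"
        )
    return _fast.weighted_sums(
        frames.sample,
        frames.reference,
        window.weights,
        np.ascontiguousarray(kernel),
        cry,
        crx,
        sy,
        sx,
        by,
        bx,
        p,
    )


def cost_function(
    r0: tuple[int, int],
    T: float,
    u: tuple[float, float],
    params: BlurKernelParams,
    frames: SpeckleFrameSet,
    window: WindowSpec,
) -> float:
    """Evaluate the windowed least-squares cost at fixed (T, u, alpha).

    ``r0`` is (row, col).  Exactly the double sum over window pixels and all
    N frame pairs; no model clipping is applied.
    """
    kernel = _raster_kernel(*params.astuple(), _auto_support(params))
    s_ii, s_im, s_mm = _sums_at(frames, window, r0, u, kernel)
    return s_ii - 2.0 * T * s_im + T * T * s_mm


def optimal_transmission(
    u: tuple[float, float],
    params: BlurKernelParams,
    r0: tuple[int, int],
    frames: SpeckleFrameSet,
    window: WindowSpec,
) -> float:
    """Closed-form T minimising the cost at fixed (u, alpha)."""
    kernel = _raster_kernel(*params.astuple(), _auto_support(params))
    _, s_im, s_mm = _sums_at(frames, window, r0, u, kernel)
    if s_mm <= 0.0:
        raise DegenerateWindowError("model term vanishes inside the window")
    return s_im / s_mm


def _auto_support(params: BlurKernelParams) -> int:
    return max(1, math.ceil(4.0 * alpha_to_axes(params).sigma_major))


# ---------------------------------------------------------------------------
# Per-pixel solve
# ---------------------------------------------------------------------------


def _pvec_to_widths(p: np.ndarray, cfg: SolverConfig):
    lo, hi = cfg.width_bounds
    sa = min(max(math.exp(p[2]), lo), hi)
    sb = min(max(math.exp(p[3]), lo), hi)
    return sa, sb


def _pvec_kernel(p: np.ndarray, cfg: SolverConfig) -> np.ndarray:
    sa, sb = _pvec_to_widths(p, cfg)
    a1, a2, a3 = _alpha_from_widths(sa, sb, math.degrees(p[4]))
    radius = min(max(1, math.ceil(4.0 * max(sa, sb))), cfg.support_max)
    return _raster_kernel(a1, a2, a3, radius)


def _pvec_cost(
    p: np.ndarray,
    frames: SpeckleFrameSet,
    window: WindowSpec,
    cfg: SolverConfig,
    r0: tuple[int, int],
    scale: float,
) -> float:
    ms = cfg.max_shift
    ux = min(max(p[0], -ms), ms)
    uy = min(max(p[1], -ms), ms)
    kernel = _pvec_kernel(p, cfg)
    s_ii, s_im, s_mm = _sums_at(frames, window, r0, (ux, uy), kernel)
    if s_mm <= 0.0:
        return s_ii
    cost = s_ii - s_im * s_im / s_mm
    # smooth barrier keeps the optimiser near the feasible box
    over = max(0.0, abs(p[0]) - ms) + max(0.0, abs(p[1]) - ms)
    return cost + scale * over * over


def _solution_from_pvec(
    p: np.ndarray,
    frames: SpeckleFrameSet,
    window: WindowSpec,
    cfg: SolverConfig,
    r0: tuple[int, int],
    converged: bool,
) -> PixelSolution:
    ms = cfg.max_shift
    ux = min(max(p[0], -ms), ms)
    uy = min(max(p[1], -ms), ms)
    sa, sb = _pvec_to_widths(p, cfg)
    a1, a2, a3 = _alpha_from_widths(sa, sb, math.degrees(p[4]))
    kernel = _raster_kernel(a1, a2, a3, min(max(1, math.ceil(4.0 * max(sa, sb))), cfg.support_max))
    s_ii, s_im, s_mm = _sums_at(frames, window, r0, (ux, uy), kernel)
    if s_mm > 0.0:
        t_star = s_im / s_mm
        cost = s_ii - s_im * s_im / s_mm
    else:
        t_star, cost = 0.0, s_ii
    return PixelSolution(
        T=t_star,
        u=(ux, uy),
        kernel=BlurKernelParams(a1, a2, a3),
        residual=max(cost, 0.0),
        converged=converged,
    )


def _solution_to_pvec(sol: PixelSolution, cfg: SolverConfig) -> np.ndarray:
    axes = alpha_to_axes(sol.kernel)
    lo, hi = cfg.width_bounds
    sa = min(max(axes.sigma_major, lo), hi)
    sb = min(max(axes.sigma_minor, lo), hi)
    return np.array(
        [sol.u[0], sol.u[1], math.log(sa), math.log(sb), math.radians(axes.theta)]
    )


def grid_init(
    r0: tuple[int, int],
    frames: SpeckleFrameSet,
    window: WindowSpec,
    cfg: SolverConfig,
) -> PixelSolution:
    """Exhaustive integer-shift / isotropic-width search for initialisation."""
    ms = int(math.floor(cfg.max_shift))
    best = None
    lo, hi = cfg.width_bounds
    widths = sorted({min(max(s, lo), hi) for s in cfg.grid_widths})
    for sigma in widths:
        radius = min(max(1, math.ceil(4.0 * sigma)), cfg.support_max)
        a = 1.0 / sigma**2
        kernel = _raster_kernel(a, 0.0, a, radius)
        for iy in range(-ms, ms + 1):
            for ix in range(-ms, ms + 1):
                s_ii, s_im, s_mm = _sums_at(frames, window, r0, (ix, iy), kernel)
                cost = s_ii - s_im * s_im / s_mm if s_mm > 0 else s_ii
                if best is None or cost < best[0]:
                    best = (cost, ix, iy, sigma)
    cost, ix, iy, sigma = best
    a = 1.0 / sigma**2
    return PixelSolution(
        T=1.0, u=(float(ix), float(iy)),
        kernel=BlurKernelParams(a, 0.0, a), residual=max(cost, 0.0),
    )


_SIMPLEX_STEPS = np.array([0.4, 0.4, 0.35, 0.35, 0.35])


def solve_pixel(
    r0: tuple[int, int],
    frames: SpeckleFrameSet,
    window: WindowSpec,
    config: SolverConfig,
    init: PixelSolution | None = None,
) -> PixelSolution:
    """Minimise the cost at one pixel starting from ``init`` (or a grid search).

    The kernel is parameterised by two unconstrained log-widths and an angle,
    so positive definiteness holds by construction; T is eliminated in closed
    form at every evaluation.  The returned cost never exceeds the cost at the
    initial point.
    """
    if init is None:
        init = grid_init(r0, frames, window, config)
    x0 = _solution_to_pvec(init, config)
    cost0 = _pvec_cost(x0, frames, window, config, r0, 0.0)
    scale = max(cost0, 1e-12)
    args = (frames, window, config, r0, scale)
    simplex = np.vstack([x0] + [x0 + np.eye(5)[i] * _SIMPLEX_STEPS[i] for i in range(5)])
    res = optimize.minimize(
        _pvec_cost,
        x0,
        args=args,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "xatol": config.param_tol,
            "fatol": max(config.cost_tol * scale, 1e-300),
            "maxfev": config.max_evals,
            "adaptive": False,
        },
    )
    p = res.x if res.fun <= cost0 else x0
    return _solution_from_pvec(
        p, frames, window, config, r0, converged=bool(res.success)
    )


# ---------------------------------------------------------------------------
# Map assembly and the multi-resolution cascade
# ---------------------------------------------------------------------------


def _store(maps: SignalMaps, row: int, col: int, sol: PixelSolution) -> None:
    maps.T[row, col] = sol.T
    maps.u_x[row, col] = sol.u[0]
    maps.u_y[row, col] = sol.u[1]
    maps.alpha1[row, col] = sol.kernel.alpha1
    maps.alpha2[row, col] = sol.kernel.alpha2
    maps.alpha3[row, col] = sol.kernel.alpha3
    maps.residual[row, col] = sol.residual
    maps.valid[row, col] = True


def _init_from_maps(
    maps: SignalMaps, row: int, col: int, cfg: SolverConfig
) -> PixelSolution | None:
    if not np.isfinite(maps.alpha1[row, col]):
        return None
    try:
        kernel = BlurKernelParams(
            maps.alpha1[row, col], maps.alpha2[row, col], maps.alpha3[row, col]
        )
    except ValueError:
        return None
    ms = cfg.max_shift
    return PixelSolution(
        T=float(maps.T[row, col]),
        u=(
            float(np.clip(maps.u_x[row, col], -ms, ms)),
            float(np.clip(maps.u_y[row, col], -ms, ms)),
        ),
        kernel=kernel,
        residual=float(max(maps.residual[row, col], 0.0))
        if np.isfinite(maps.residual[row, col])
        else 0.0,
    )


def solve_level(
    frames: SpeckleFrameSet,
    window: WindowSpec,
    config: SolverConfig,
    init_maps: SignalMaps | None = None,
    *,
    stride: int = 1,
    select: np.ndarray | None = None,
) -> SignalMaps:
    """Solve every selected pixel independently and assemble SignalMaps.

    ``stride`` solves a regular sub-grid; ``select`` restricts to a boolean
    mask.  Pixels inside the margin are always masked out.  Each pixel's
    initialisation depends only on ``init_maps`` (or its own grid search), so
    the result is deterministic and invariant under processing order.
    """
    h, w = frames.frame_shape
    margin = config.margin
    if 2 * margin >= min(h, w):
        raise ValueError(
            f"window/margin ({margin}) too large for frame shape {(h, w)}"
        )
    if select is not None and select.shape != (h, w):
        raise ValueError("select mask shape must match frames")
    maps = SignalMaps.empty((h, w), margin=margin)
    rows = range(margin, h - margin, stride)
    cols = range(margin, w - margin, stride)
    for row in rows:
        for col in cols:
            if select is not None and not select[row, col]:
                continue
            init = None
            if init_maps is not None:
                init = _init_from_maps(init_maps, row, col, config)
            if init is None:
                init = grid_init((row, col), frames, window, config)
            sol = solve_pixel((row, col), frames, window, config, init=init)
            _store(maps, row, col, sol)
    return maps


def bin_stack(stack: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a (N, H, W) stack; trailing rows/cols are cropped."""
    if factor == 1:
        return stack
    n, h, w = stack.shape
    hb, wb = h // factor, w // factor
    cropped = stack[:, : hb * factor, : wb * factor]
    return cropped.reshape(n, hb, factor, wb, factor).mean(axis=(2, 4))


def _fill_nearest(arr: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid pixels with the nearest valid value (init plumbing only)."""
    if valid.all() or not valid.any():
        return arr
    idx = ndimage.distance_transform_edt(
        ~valid, return_distances=False, return_indices=True
    )
    return arr[tuple(idx)]


def _upsample_maps(
    maps: SignalMaps, ratio: int, shape: tuple[int, int], cfg: SolverConfig
) -> SignalMaps:
    """Nearest-neighbour upsample with u scaled by ratio and alpha by 1/ratio^2."""
    out = SignalMaps.empty(shape, margin=cfg.margin)
    any_valid = bool(maps.valid.any())
    for name in SignalMaps._FIELDS:
        src = getattr(maps, name)
        if any_valid:
            src = _fill_nearest(src, maps.valid)
        up = np.repeat(np.repeat(src, ratio, axis=0), ratio, axis=1)
        buf = np.full(shape, np.nan)
        r = min(shape[0], up.shape[0])
        c = min(shape[1], up.shape[1])
        buf[:r, :c] = up[:r, :c]
        if r < shape[0]:
            buf[r:, :] = buf[r - 1 : r, :]
        if c < shape[1]:
            buf[:, c:] = buf[:, c - 1 : c]
        setattr(out, name, buf)
    out.u_x *= ratio
    out.u_y *= ratio
    out.alpha1 /= ratio * ratio
    out.alpha2 /= ratio * ratio
    out.alpha3 /= ratio * ratio
    out.valid = np.isfinite(out.alpha1)
    return out


def _level_config(cfg: SolverConfig, factor: int) -> SolverConfig:
    if factor == 1:
        return cfg
    lo, hi = cfg.width_bounds
    return replace(
        cfg,
        levels=(1,),
        max_shift=max(cfg.max_shift / factor, 1.0),
        width_bounds=(lo, max(hi / factor, 4.0 * lo)),
    )


def multires_solve(
    frames: SpeckleFrameSet,
    config: SolverConfig,
    *,
    stride: int = 1,
    select: np.ndarray | None = None,
) -> SignalMaps:
    """Coarse-to-fine cascade over ``config.levels``.

    Each binned level is solved with the previous (upsampled, rescaled)
    solution as initialisation; the coarsest level uses the exhaustive grid
    search.  Levels whose margin does not fit the binned frames are skipped
    with a log message.
    """
    init: SignalMaps | None = None
    prev_factor: int | None = None
    maps: SignalMaps | None = None
    for factor in config.levels:
        cfg_l = _level_config(config, factor)
        sample_b = bin_stack(frames.sample, factor)
        reference_b = bin_stack(frames.reference, factor)
        frames_b = SpeckleFrameSet(sample_b, reference_b, frames.geometry)
        if init is not None and prev_factor is not None:
            init = _upsample_maps(init, prev_factor // factor, frames_b.frame_shape, cfg_l)
        stride_l = max(1, round(stride / factor)) if factor > 1 else stride
        select_l = None
        if select is not None:
            h, w = frames_b.frame_shape
            sel = select[: h * factor, : w * factor]
            select_l = (
                sel.reshape(h, factor, w, factor).any(axis=(1, 3))
                if factor > 1
                else select
            )
            if factor > 1:
                # pad so that the fine-level pixels have initialisation nearby
                select_l = ndimage.binary_dilation(select_l, iterations=2)
        try:
            maps = solve_level(
                frames_b, config.window, cfg_l, init_maps=init,
                stride=stride_l, select=select_l,
            )
        except ValueError as exc:
            logger.info("skipping level %d: %s", factor, exc)
            maps = None
            continue
        if not maps.valid.any():
            logger.info("level %d produced no valid pixels; dropping", factor)
            maps = None
            continue
        init = maps
        prev_factor = factor
    if maps is None:
        raise ValueError("no resolution level produced valid pixels")
    return maps
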