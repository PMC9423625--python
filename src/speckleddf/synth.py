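"""Synthetic speckle test bed: patterns, diffuser stepping, phantoms, noise.

Stands in for beamline data: near-field speckle is emulated statistically
(Gaussian-band-limited counting noise with controllable speckle size and
visibility), the diffuser is stepped along a spiral with no repeated x or y
component, and phantoms apply known (T, u, alpha) fields region by region
through the same forward model the solver fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model import (
    GeometrySpec,
    PrincipalAxes,
    SpeckleFrameSet,
    axes_to_alpha,
    model_intensity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PatternSpec",
    "PhantomSpec",
    "AcquisitionSpec",
    "generate_speckle_pattern",
    "spiral_positions",
    "synthesize_dataset",
    "simulate",
    "wrap_axial",
]

#: Gaussian FWHM in units of sigma, times sqrt(2) for the autocorrelation.
_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0)) * math.sqrt(2.0)


def wrap_axial(angle_deg: float) -> float:
    """Wrap an axial angle (mod 180) into (-90, 90]."""
    a = (float(angle_deg) + 90.0) % 180.0 - 90.0
    return 90.0 if a == -90.0 else a


@dataclass(frozen=True)
class PatternSpec:
    """Statistical description of a synthetic speckle pattern."""

    shape: tuple[int, int]
    speckle_size: float = 3.0
    visibility: float = 0.3
    mean_counts: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speckle_size < 1:
            raise ValueError("speckle_size must be >= 1 pixel")
        if not (0 < self.visibility < 1):
            raise ValueError("visibility must lie in (0, 1)")
        if self.mean_counts <= 0:
            raise ValueError("mean_counts must be > 0")


@dataclass
class PhantomSpec:
    """Region-labelled ground-truth fields (T, u, principal axes)."""

    labels: np.ndarray
    transmittance: dict[int, float]
    shift: dict[int, tuple[float, float]]
    axes: dict[int, PrincipalAxes]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D map")
        for lab in self.region_labels:
            for table, name in (
                (self.transmittance, "transmittance"),
                (self.shift, "shift"),
                (self.axes, "axes"),
            ):
                if lab not in table:
                    raise ValueError(f"region {lab} missing a {name} entry")
            if self.transmittance[lab] < 0:
                raise ValueError(f"region {lab}: transmittance must be >= 0")

    @property
    def region_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.labels)]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def truth_maps(self) -> dict[str, np.ndarray]:
        """Per-pixel ground-truth maps co-registered with the frames."""
        shape = self.shape
        maps = {
            name: np.zeros(shape)
            for name in ("T", "u_x", "u_y", "alpha1", "alpha2", "alpha3", "theta_deg")
        }
        maps["labels"] = self.labels.astype(np.int32)
        for lab in self.region_labels:
            mask = self.labels == lab
            alpha = axes_to_alpha(self.axes[lab])
            maps["T"][mask] = self.transmittance[lab]
            maps["u_x"][mask] = self.shift[lab][0]
            maps["u_y"][mask] = self.shift[lab][1]
            maps["alpha1"][mask] = alpha.alpha1
            maps["alpha2"][mask] = alpha.alpha2
            maps["alpha3"][mask] = alpha.alpha3
            maps["theta_deg"][mask] = self.axes[lab].theta
        return maps

    @classmethod
    def uniform(
        cls,
        shape: tuple[int, int],
        T: float = 0.8,
        shift: tuple[float, float] = (0.0, 0.0),
        axes: PrincipalAxes = PrincipalAxes(2.0, 1.0, 30.0),
    ) -> "PhantomSpec":
        return cls(
            labels=np.zeros(shape, np.int32),
            transmittance={0: T},
            shift={0: shift},
            axes={0: axes},
        )

    @classmethod
    def four_tube(
        cls,
        shape: tuple[int, int],
        T: float = 0.8,
        shift: tuple[float, float] = (0.6, -0.4),
        sigma_major: float = 2.0,
        sigma_minor: float = 1.0,
        fibre_angles: tuple[float, ...] = (0.0, 90.0, 45.0, -45.0),
    ) -> "PhantomSpec":
        """Quadrant phantom mimicking four unidirectional-fibre tubes.

        Each quadrant carries a fibre direction ``phi``; scattering is
        orthogonal to the fibres, so the kernel's wide axis sits at
        ``phi + 90`` (axially wrapped).  Fibre angles are stored in
        ``meta['fibre_angles']``.
        """
        if len(fibre_angles) != 4:
            raise ValueError("four_tube needs exactly four fibre angles")
        h, w = shape
        labels = np.zeros(shape, np.int32)
        labels[: h // 2, w // 2 :] = 1
        labels[h // 2 :, : w // 2] = 2
        labels[h // 2 :, w // 2 :] = 3
        axes = {
            i: PrincipalAxes(sigma_major, sigma_minor, wrap_axial(phi + 90.0))
            for i, phi in enumerate(fibre_angles)
        }
        return cls(
            labels=labels,
            transmittance={i: T for i in range(4)},
            shift={i: shift for i in range(4)},
            axes=axes,
            meta={"fibre_angles": {i: float(phi) for i, phi in enumerate(fibre_angles)}},
        )


@dataclass(frozen=True)
class AcquisitionSpec:
    """Diffuser stepping and noise protocol."""

    n_positions: int = 25
    step: float = 8.0
    n_reference_averages: int = 50
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.n_reference_averages < 1:
            raise ValueError("n_reference_averages must be >= 1")


def generate_speckle_pattern(spec: PatternSpec) -> np.ndarray:
    """Band-limited pseudo-speckle with prescribed statistics.

    Gaussian-filtered white noise rescaled so the mean is ``mean_counts``, the
    contrast (std/mean) is ``visibility`` and the autocorrelation FWHM matches
    ``speckle_size``.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(spec.shape)
    sigma_g = spec.speckle_size / _FWHM_FACTOR
    smooth = ndimage.gaussian_filter(white, sigma_g, mode="wrap")
    smooth = (smooth - smooth.mean()) / smooth.std()
    return np.clip(spec.mean_counts * (1.0 + spec.visibility * smooth), 0.0, None)


_GOLDEN_DEG = 180.0 * (3.0 - math.sqrt(5.0))  # ~137.5, irrational turn


def spiral_positions(n: int, step: float) -> np.ndarray:
    """Integer diffuser offsets along a Fermat spiral.

    Pairwise Euclidean distances are at least ``step`` and no two offsets
    share an x or a y component (the stepping protocol of the acquisition).
    Returns an (n, 2) int array of (x, y) offsets.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if step <= 0:
        raise ValueError("step must be > 0")
    if n == 1:
        return np.zeros((1, 2), np.int64)
    k = np.arange(1, n + 1, dtype=float)
    ang = np.radians(k * _GOLDEN_DEG)
    r = np.sqrt(k)
    pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    dmin = _min_pairwise(pts)
    pts *= (step + 4.0) / dmin
    xy = np.round(pts).astype(np.int64)
    for axis in (0, 1):
        xy[:, axis] = _make_distinct(xy[:, axis])
    if _min_pairwise(xy.astype(float)) < step:
        raise RuntimeError("spiral construction failed to honour the step size")
    return xy


def _min_pairwise(pts: np.ndarray) -> float:
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    np.fill_diagonal(dist, np.inf)
    return float(dist.min())


def _make_distinct(values: np.ndarray) -> np.ndarray:
    """Nudge duplicate integers upward (+1) until all values are distinct."""
    out = values.copy()
    for _ in range(10 * len(out)):
        order = np.argsort(out, kind="stable")
        shifted = out[order]
        dup = np.nonzero(np.diff(shifted) == 0)[0]
        if dup.size == 0:
            return out
        out[order[dup[0] + 1]] += 1
    raise RuntimeError("could not make offsets distinct")


def _extension_margin(phantom: PhantomSpec) -> int:
    sup = max(
        math.ceil(4.0 * ax.sigma_major) for ax in phantom.axes.values()
    )
    umax = max(
        max(abs(u[0]), abs(u[1])) for u in phantom.shift.values()
    )
    return sup + math.ceil(umax) + 3


def synthesize_dataset(
    pattern_master: np.ndarray,
    phantom: PhantomSpec,
    acq: AcquisitionSpec,
    geometry: GeometrySpec | None = None,
) -> tuple[SpeckleFrameSet, dict[str, np.ndarray]]:
    """Build a SpeckleFrameSet and ground-truth maps from one master pattern.

    Reference j is a crop of the master at spiral offset j (averaged over
    ``n_reference_averages`` independent Poisson draws when noise is on);
    sample j applies the phantom's per-region forward model to the same crop
    and receives a single Poisson draw.
    """
    master = np.asarray(pattern_master, float)
    h, w = phantom.shape
    m = _extension_margin(phantom)
    offsets = spiral_positions(acq.n_positions, acq.step)
    offsets = offsets - offsets.min(axis=0)
    need_h = h + 2 * m + int(offsets[:, 1].max())
    need_w = w + 2 * m + int(offsets[:, 0].max())
    if master.shape[0] < need_h or master.shape[1] < need_w:
        raise ValueError(
            f"master pattern {master.shape} too small: need at least "
            f"({need_h}, {need_w}) for phantom {phantom.shape}, margin {m} "
            f"and offsets up to {offsets.max(axis=0)}"
        )
    labels_ext = np.pad(phantom.labels, m, mode="edge")
    rng = np.random.default_rng(acq.seed)
    n = acq.n_positions
    sample = np.empty((n, h, w))
    reference = np.empty((n, h, w))
    for j in range(n):
        ox, oy = int(offsets[j, 0]), int(offsets[j, 1])
        crop = master[oy : oy + h + 2 * m, ox : ox + w + 2 * m]
        sample_ext = np.zeros_like(crop)
        for lab in phantom.region_labels:
            modelled = model_intensity(
                crop,
                phantom.transmittance[lab],
                phantom.shift[lab],
                axes_to_alpha(phantom.axes[lab]),
            )
            region = labels_ext == lab
            sample_ext[region] = modelled[region]
        clean_ref = crop[m : m + h, m : m + w]
        clean_sample = sample_ext[m : m + h, m : m + w]
        if acq.noise:
            navg = acq.n_reference_averages
            # sum of navg independent Poisson draws == one draw at navg * rate
            reference[j] = rng.poisson(navg * clean_ref) / navg
            sample[j] = rng.poisson(clean_sample)
        else:
            reference[j] = clean_ref
            sample[j] = clean_sample
    frames = SpeckleFrameSet(
        sample, reference, geometry or GeometrySpec(21.5e-6, 6.65)
    )
    return frames, phantom.truth_maps()


def simulate(
    pattern: PatternSpec,
    phantom: PhantomSpec,
    acq: AcquisitionSpec,
    geometry: GeometrySpec | None = None,
) -> tuple[SpeckleFrameSet, dict[str, np.ndarray]]:
    """Generate a master pattern of the required size and synthesise a dataset.

    ``pattern.shape`` is treated as the phantom shape; the master is enlarged
    to cover the diffuser offsets and model margins.
    """
    if acq.n_positions > 1 and acq.step <= pattern.speckle_size:
        logger.warning(
            "diffuser step (%.2f px) should exceed the speckle size (%.2f px)",
            acq.step,
            pattern.speckle_size,
        )
    if phantom.shape != tuple(pattern.shape):
        raise ValueError(
            f"pattern shape {pattern.shape} must match phantom shape {phantom.shape}"
        )
    m = _extension_margin(phantom)
    offsets = spiral_positions(acq.n_positions, acq.step)
    extent = offsets.max(axis=0) - offsets.min(axis=0)
    master_shape = (
        pattern.shape[0] + 2 * m + int(extent[1]) + 1,
        pattern.shape[1] + 2 * m + int(extent[0]) + 1,
    )
    master = generate_speckle_pattern(
        PatternSpec(
            shape=master_shape,
            speckle_size=pattern.speckle_size,
            visibility=pattern.visibility,
            mean_counts=pattern.mean_counts,
            seed=pattern.seed,
        )
    )
    return synthesize_dataset(master, phantom, acq, geometry)
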