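"""End-to-end benchmark studies on synthetic phantoms.

These drive the full pipeline (synthesise -> retrieve -> evaluate) and are
used by the acceptance suite:

* :func:`four_tube_study` — orientation accuracy on the four-quadrant fibre
  phantom at a 31x31 window and 25 diffuser positions.
* :func:`precision_scaling_study` — scattering-angle precision versus the
  number of independent pixel measurements P, with the power-law fit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .darkfield import summary_maps
from .retrieval import SolverConfig, WindowSpec, solve_level
from .stats import ROISpec, fit_power_law, independent_measurements, roi_report
from .synth import AcquisitionSpec, PatternSpec, PhantomSpec, simulate
from .model import PrincipalAxes, SpeckleFrameSet

logger = logging.getLogger(__name__)

__all__ = ["four_tube_study", "precision_scaling_study"]


def four_tube_study(
    seed: int = 1,
    shape: int = 256,
    window_size: int = 31,
    n_positions: int = 25,
    mean_counts: float = 1e4,
    roi_size: int = 64,
    stride: int = 8,
    max_evals: int = 200,
) -> pd.DataFrame:
    """Recover per-region scattering orientations on the four-tube phantom.

    Returns the ROI report (phi, axial mean/std of theta, deviation from
    orthogonality) computed from pixels solved on a ``stride`` grid inside
    one square ROI per quadrant.
    """
    phantom = PhantomSpec.four_tube((shape, shape))
    pattern = PatternSpec(shape=(shape, shape), mean_counts=mean_counts, seed=seed)
    acq = AcquisitionSpec(n_positions=n_positions, noise=True, seed=seed + 1)
    frames, truth = simulate(pattern, phantom, acq)
    window = WindowSpec.hamming(window_size)
    config = SolverConfig(
        window=window, levels=(1,), max_shift=2.0,
        width_bounds=(0.02, 3.0), max_evals=max_evals, seed=seed,
    )
    q = shape // 4
    centres = [(q, q), (q, 3 * q), (3 * q, q), (3 * q, 3 * q)]
    rois = []
    select = np.zeros((shape, shape), bool)
    for r, c in centres:
        half = roi_size // 2
        select[r - half : r + half : stride, c - half : c + half : stride] = True
        rois.append(ROISpec((r, c), roi_size))
    logger.info("four-tube study: solving %d pixels", int(select.sum()))
    maps = solve_level(frames, window, config, select=select)
    theta = summary_maps(maps.alpha1, maps.alpha2, maps.alpha3)["theta_deg"]
    # quadrant label layout of PhantomSpec.four_tube: 0 tl, 1 tr, 2 bl, 3 br
    phis = [phantom.meta["fibre_angles"][lab] for lab in (0, 1, 2, 3)]
    report = roi_report(
        theta, rois, phis, valid=maps.valid, allow_partial=True
    )
    report["n_positions"] = n_positions
    report["window_size"] = window_size
    report["P"] = independent_measurements(window_size, n_positions)
    return report


_DEFAULT_COMBOS = (
    (5, 13),
    (5, 25),
    (7, 13),
    (7, 25),
    (11, 13),
    (11, 25),
    (15, 25),
    (21, 25),
)


def precision_scaling_study(
    seed: int = 1,
    shape: int = 320,
    combos=_DEFAULT_COMBOS,
    mean_counts: float = 1e4,
    axes: PrincipalAxes = PrincipalAxes(2.0, 1.0, 30.0),
    target_pixels: int = 128,
    max_evals: int = 200,
):
    """Measure sigma_theta(P) over (window, N) combinations and fit the power law.

    One uniform eccentric phantom is synthesised once with the maximum N;
    each combination solves ~``target_pixels`` pixels on a sparse grid
    (spacing >= window size, so the measurements are approximately
    independent) and records the axial standard deviation of theta.

    Returns ``(points, fit)`` where points is a list of
    ``(P, sigma_theta, standard_error)`` and fit the PowerLawFit.
    """
    n_max = max(n for _, n in combos)
    phantom = PhantomSpec.uniform(
        (shape, shape), T=0.8, shift=(0.6, -0.4), axes=axes
    )
    pattern = PatternSpec(shape=(shape, shape), mean_counts=mean_counts, seed=seed)
    acq = AcquisitionSpec(n_positions=n_max, noise=True, seed=seed + 1)
    frames, _ = simulate(pattern, phantom, acq)
    true_theta = axes.theta
    points = []
    for window_size, n_pos in combos:
        window = WindowSpec.hamming(window_size)
        config = SolverConfig(
            window=window, levels=(1,), max_shift=2.0,
            width_bounds=(0.02, 3.0), max_evals=max_evals, seed=seed,
        )
        sub = SpeckleFrameSet(
            frames.sample[:n_pos], frames.reference[:n_pos], frames.geometry
        )
        margin = config.margin
        spacing = max(window_size, 9)
        grid = np.arange(margin + 1, shape - margin - 1, spacing)
        # trim to roughly target_pixels, keeping the grid regular
        while grid.size**2 > target_pixels * 1.6 and grid.size > 4:
            grid = grid[::2] if grid.size % 2 else grid[: -1 : 2]
        select = np.zeros((shape, shape), bool)
        select[np.ix_(grid, grid)] = True
        maps = solve_level(sub, window, config, select=select)
        theta = summary_maps(maps.alpha1, maps.alpha2, maps.alpha3)["theta_deg"]
        vals = theta[maps.valid]
        vals = vals[np.isfinite(vals)]
        from .stats import AxialSample, axial_mean_and_std

        _, sigma_theta = axial_mean_and_std(AxialSample(vals))
        m = vals.size
        err = sigma_theta / np.sqrt(2.0 * (m - 1))
        p = independent_measurements(window_size, n_pos)
        logger.info(
            "combo window=%d N=%d: P=%d sigma_theta=%.3f deg (%d pixels)",
            window_size, n_pos, p, sigma_theta, m,
        )
        points.append((float(p), float(sigma_theta), float(err)))
    fit = fit_power_law(points, exclude_below=50.0)
    return points, fit
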