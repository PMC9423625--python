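import math

import numpy as np
import pytest
from scipy import optimize

from speckleddf.model import (
    BlurKernelParams,
    PrincipalAxes,
    SpeckleFrameSet,
    alpha_to_axes,
    axes_to_alpha,
)
from speckleddf.retrieval import (
    DegenerateWindowError,
    SolverConfig,
    WindowSpec,
    bin_stack,
    cost_function,
    grid_init,
    multires_solve,
    optimal_transmission,
    solve_level,
    solve_pixel,
)
from speckleddf.synth import AcquisitionSpec, PatternSpec, PhantomSpec, simulate

from oracles import straight_loop_cost

DELTA = BlurKernelParams(1e4, 0.0, 1e4)


class TestWindowSpec:
    def test_even_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec.hamming(8)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec.hamming(1)

    def test_hamming_properties(self):
        w = WindowSpec.hamming(7)
        assert w.weights.max() == pytest.approx(1.0)
        assert w.weights[3, 3] == pytest.approx(1.0)
        assert (w.weights > 0).all()


class TestSolverConfig:
    def test_levels_must_decrease_to_one(self):
        with pytest.raises(ValueError):
            SolverConfig(levels=(2, 4, 1))
        with pytest.raises(ValueError):
            SolverConfig(levels=(4, 2))

    def test_negative_shift(self):
        with pytest.raises(ValueError):
            SolverConfig(max_shift=-1.0)


class TestCostFunction:
    def test_perfect_model_zero_cost(self, rng, window7):
        img = rng.uniform(1, 2, (30, 30))
        frames = SpeckleFrameSet(np.stack([img, img]), np.stack([img, img]))
        c = cost_function((15, 15), 1.0, (0, 0), DELTA, frames, window7)
        assert c == pytest.approx(0.0, abs=1e-18)

    def test_zero_transmission_closed_form(self, small_frames, window7):
        r0 = (20, 20)
        c = cost_function(r0, 0.0, (0.5, -0.25), BlurKernelParams(1, 0, 1),
                          small_frames, window7)
        wh = window7.half
        expected = 0.0
        for j in range(small_frames.n_positions):
            win = small_frames.sample[j, r0[0] - wh : r0[0] + wh + 1,
                                      r0[1] - wh : r0[1] + wh + 1]
            expected += (window7.weights * win**2).sum()
        assert c == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "T, u, alpha",
        [
            (0.7, (1.3, -0.8), (1.3, 0.4, 0.9)),
            (1.1, (-0.4, 0.6), (4.0, 0.0, 1.0)),
            (0.9, (0.0, 0.0), (0.5, -0.2, 0.7)),
        ],
    )
    def test_matches_straight_loop_oracle(self, small_frames, T, u, alpha):
        window = WindowSpec.hamming(9)
        r0 = (20, 19)
        c = cost_function(r0, T, u, BlurKernelParams(*alpha), small_frames, window)
        oracle = straight_loop_cost(
            small_frames.sample, small_frames.reference, window.weights,
            r0, T, u, alpha,
        )
        assert c == pytest.approx(oracle, rel=1e-10)

    def test_margin_error(self, small_frames, window7):
        with pytest.raises(ValueError, match="margin|bounds"):
            cost_function((2, 2), 1.0, (0, 0), BlurKernelParams(1, 0, 1),
                          small_frames, window7)


class TestOptimalTransmission:
    def test_proportional_data(self, rng, window7):
        ref = rng.uniform(1, 2, (3, 36, 36))
        params = BlurKernelParams(1.0, 0.2, 0.8)
        c = 0.63
        from speckleddf.model import model_intensity

        sample = np.stack(
            [c * model_intensity(ref[j], 1.0, (0.7, -0.3), params) for j in range(3)]
        )
        frames = SpeckleFrameSet(sample, ref)
        t = optimal_transmission((0.7, -0.3), params, (18, 18), frames, window7)
        assert t == pytest.approx(c, rel=1e-6)

    def test_uncorrelated_noise_orthogonality(self, window7):
        # sample = c + zero-mean noise against a constant model: T* deviates
        # from c only through the noise, within 3 sigma of the weighted mean
        gen = np.random.default_rng(17)
        n, c, s = 4, 10.0, 1.0
        sample = c + gen.normal(0.0, s, (n, 40, 40))
        frames = SpeckleFrameSet(np.clip(sample, 0, None), np.ones((n, 40, 40)))
        t = optimal_transmission((0, 0), DELTA, (20, 20), frames, window7)
        w = window7.weights
        n_eff = n * w.sum() ** 2 / (w**2).sum()
        assert abs(t - c) < 3.0 * s / np.sqrt(n_eff)

    def test_matches_scalar_minimisation(self, small_frames, window7):
        params = BlurKernelParams(1.1, -0.3, 0.9)
        u, r0 = (0.9, -0.4), (21, 22)
        t_star = optimal_transmission(u, params, r0, small_frames, window7)
        res = optimize.minimize_scalar(
            lambda t: cost_function(r0, t, u, params, small_frames, window7),
            bracket=(0.0, 2.0),
            method="brent",
            options={"xtol": 1e-12},
        )
        assert t_star == pytest.approx(res.x, abs=1e-8)
        # and no other T does better
        for t in (t_star - 0.01, t_star + 0.01):
            assert cost_function(r0, t_star, u, params, small_frames, window7) <= \
                cost_function(r0, t, u, params, small_frames, window7)

    def test_degenerate_window(self, window7):
        frames = SpeckleFrameSet(np.ones((1, 40, 40)), np.zeros((1, 40, 40)))
        with pytest.raises(DegenerateWindowError):
            optimal_transmission((0, 0), DELTA, (20, 20), frames, window7)


TRUTH = dict(T=0.8, u=(1.4, -0.6), axes=PrincipalAxes(2.0, 1.0, 30.0))


class TestSolvePixel:
    def test_noiseless_recovery(self, uniform_noiseless, window7, fast_config):
        frames, _ = uniform_noiseless
        sol = solve_pixel((48, 48), frames, window7, fast_config)
        axes = alpha_to_axes(sol.kernel)
        assert abs(sol.T - TRUTH["T"]) < 0.01
        assert abs(sol.u[0] - TRUTH["u"][0]) < 0.05
        assert abs(sol.u[1] - TRUTH["u"][1]) < 0.05
        dth = (axes.theta - TRUTH["axes"].theta + 90) % 180 - 90
        assert abs(dth) < 2.0

    def test_fixed_point(self, uniform_noiseless, window7, fast_config):
        frames, _ = uniform_noiseless
        sol = solve_pixel((40, 52), frames, window7, fast_config)
        again = solve_pixel((40, 52), frames, window7, fast_config, init=sol)
        assert again.residual <= sol.residual + 1e-12
        assert abs(again.u[0] - sol.u[0]) < 1e-2
        assert abs(again.u[1] - sol.u[1]) < 1e-2
        assert abs(again.T - sol.T) < 1e-3

    def test_cost_not_worse_than_init(self, uniform_noisy, window7, fast_config):
        frames, _ = uniform_noisy
        init = grid_init((50, 50), frames, window7, fast_config)
        sol = solve_pixel((50, 50), frames, window7, fast_config, init=init)
        assert sol.residual <= init.residual + 1e-9

    def test_beats_coarse_grid(self, uniform_noisy, window7, fast_config):
        frames, _ = uniform_noisy
        r0 = (44, 60)
        best = np.inf
        for ux in np.linspace(-2, 2, 5):
            for uy in np.linspace(-2, 2, 5):
                for s in (0.05, 0.5, 1.0, 2.0):
                    p = BlurKernelParams(1 / s**2, 0.0, 1 / s**2)
                    t = optimal_transmission((ux, uy), p, r0, frames, window7)
                    best = min(
                        best, cost_function(r0, t, (ux, uy), p, frames, window7)
                    )
        sol = solve_pixel(r0, frames, window7, fast_config)
        assert sol.residual <= best + 1e-9

    def test_positive_definite_kernel_always(self, uniform_noisy, window7, fast_config):
        frames, _ = uniform_noisy
        sol = solve_pixel((52, 40), frames, window7, fast_config)
        assert sol.kernel.determinant > 0

    def test_margin_rejected(self, uniform_noisy, window7, fast_config):
        frames, _ = uniform_noisy
        with pytest.raises(ValueError):
            solve_pixel((3, 3), frames, window7, fast_config)


class TestOracleEquivalence:
    def test_dense_grid_search(self, window7):
        """Solver cost within 1e-6 (relative) of a dense 6-D grid around truth."""
        truth_axes = PrincipalAxes(1.2, 0.8, 20.0)
        phantom = PhantomSpec.uniform(
            (44, 44), T=0.9, shift=(0.7, -0.3), axes=truth_axes
        )
        frames, _ = simulate(
            PatternSpec(shape=(44, 44), seed=31, mean_counts=1e4),
            phantom,
            AcquisitionSpec(n_positions=2, noise=True, seed=33),
        )
        window = WindowSpec.hamming(9)
        cfg = SolverConfig(
            window=window, levels=(1,), max_shift=2.0, width_bounds=(0.02, 1.8)
        )
        r0 = (22, 22)
        best = np.inf
        for t in np.linspace(0.85, 0.95, 5):
            for ux in 0.7 + np.linspace(-0.12, 0.12, 5):
                for uy in -0.3 + np.linspace(-0.12, 0.12, 5):
                    for lsa in np.log(1.2) + np.linspace(-0.12, 0.12, 5):
                        for lsb in np.log(0.8) + np.linspace(-0.12, 0.12, 5):
                            for th in 20.0 + np.linspace(-6, 6, 5):
                                p = axes_to_alpha(
                                    PrincipalAxes(math.exp(lsa), math.exp(lsb), th)
                                    if lsa >= lsb
                                    else PrincipalAxes(math.exp(lsb), math.exp(lsa), th)
                                )
                                c = cost_function(r0, t, (ux, uy), p, frames, window)
                                best = min(best, c)
        sol = solve_pixel(r0, frames, window, cfg)
        assert sol.residual <= best * (1 + 1e-6)


class TestSolveLevel:
    def test_uniform_phantom_agreement(self, uniform_noiseless, window7, fast_config):
        frames, _ = uniform_noiseless
        select = np.zeros(frames.frame_shape, bool)
        select[40:60:8, 40:60:8] = True
        maps = solve_level(frames, window7, fast_config, select=select)
        t_vals = maps.T[maps.valid]
        assert t_vals.size >= 6
        assert np.ptp(t_vals) < 5e-3
        assert np.ptp(maps.u_x[maps.valid]) < 0.03
        assert np.ptp(maps.u_y[maps.valid]) < 0.03

    def test_two_region_phantom(self, window7):
        labels = np.zeros((96, 96), np.int32)
        labels[:, 48:] = 1
        phantom = PhantomSpec(
            labels=labels,
            transmittance={0: 0.9, 1: 0.6},
            shift={0: (0.5, 0.0), 1: (-0.5, 0.5)},
            axes={0: PrincipalAxes(2.0, 1.0, 60.0), 1: PrincipalAxes(1.8, 0.9, -30.0)},
        )
        frames, truth = simulate(
            PatternSpec(shape=(96, 96), seed=41),
            phantom,
            AcquisitionSpec(n_positions=15, noise=False, seed=43),
        )
        cfg = SolverConfig(
            window=window7, levels=(1,), max_shift=2.0, width_bounds=(0.02, 2.5)
        )
        select = np.zeros((96, 96), bool)
        select[44:52:4, 26:36:4] = True  # interior of region 0
        select[44:52:4, 62:72:4] = True  # interior of region 1
        maps = solve_level(frames, window7, cfg, select=select)
        from speckleddf.darkfield import summary_maps

        theta = summary_maps(maps.alpha1, maps.alpha2, maps.alpha3)["theta_deg"]
        for lab, expected in ((0, 60.0), (1, -30.0)):
            region = (truth["labels"] == lab) & maps.valid
            d = (theta[region] - expected + 90) % 180 - 90
            assert np.abs(d).max() < 2.0
            assert np.abs(maps.T[region] - phantom.transmittance[lab]).max() < 0.01

    def test_determinism(self, uniform_noisy, window7, fast_config):
        frames, _ = uniform_noisy
        select = np.zeros(frames.frame_shape, bool)
        select[44:54:6, 44:54:6] = True
        a = solve_level(frames, window7, fast_config, select=select)
        b = solve_level(frames, window7, fast_config, select=select)
        for name in ("T", "u_x", "u_y", "alpha1", "alpha2", "alpha3", "residual"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_window_too_large(self, uniform_noisy):
        frames, _ = uniform_noisy
        big = WindowSpec.hamming(63)
        cfg = SolverConfig(window=big, levels=(1,))
        with pytest.raises(ValueError, match="margin"):
            solve_level(frames, big, cfg)


class TestInvariants:
    def test_shift_equivariance(self, uniform_noiseless, window7, fast_config):
        frames, _ = uniform_noiseless
        v = (1, 2)  # (x, y)
        shifted = SpeckleFrameSet(
            np.roll(frames.sample, (v[1], v[0]), axis=(1, 2)),
            frames.reference,
            frames.geometry,
        )
        r0 = (48, 48)
        base = solve_pixel(r0, frames, window7, fast_config)
        cfg = SolverConfig(
            window=window7, levels=(1,), max_shift=4.0, width_bounds=(0.02, 2.5)
        )
        moved = solve_pixel(r0, shifted, window7, cfg)
        # model samples the reference at r + u, so moving the sample content
        # by +v lowers the recovered u by v
        assert abs(moved.u[0] - base.u[0] + v[0]) < 0.05
        assert abs(moved.u[1] - base.u[1] + v[1]) < 0.05

    def test_intensity_scaling(self, uniform_noiseless, window7, fast_config):
        frames, _ = uniform_noiseless
        c = 1.7
        scaled = SpeckleFrameSet(
            c * frames.sample, frames.reference, frames.geometry
        )
        r0 = (52, 44)
        base = solve_pixel(r0, frames, window7, fast_config)
        got = solve_pixel(r0, scaled, window7, fast_config)
        assert got.T == pytest.approx(c * base.T, rel=5e-3)

    def test_noise_robustness_orientation(self, uniform_noisy, window7, fast_config):
        frames, truth = uniform_noisy
        select = np.zeros(frames.frame_shape, bool)
        select[36:62:8, 36:62:8] = True
        maps = solve_level(frames, window7, fast_config, select=select)
        from speckleddf.darkfield import summary_maps

        theta = summary_maps(maps.alpha1, maps.alpha2, maps.alpha3)["theta_deg"]
        d = (theta[maps.valid] - 30.0 + 90) % 180 - 90
        assert abs(d.mean()) < 3.0


class TestMultires:
    def test_single_level_equals_solve_level(self, uniform_noisy, window7, fast_config):
        frames, _ = uniform_noisy
        select = np.zeros(frames.frame_shape, bool)
        select[46:56:6, 46:56:6] = True
        a = multires_solve(frames, fast_config, select=select)
        b = solve_level(frames, window7, fast_config, select=select)
        for name in ("T", "u_x", "u_y", "alpha1", "alpha2", "alpha3", "residual"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_binning_consistency(self):
        phantom = PhantomSpec.uniform(
            (96, 96), T=0.9, shift=(2.0, 0.0), axes=PrincipalAxes(1.6, 1.0, 45.0)
        )
        frames, _ = simulate(
            PatternSpec(shape=(96, 96), speckle_size=4.0, seed=51),
            phantom,
            AcquisitionSpec(n_positions=15, noise=False, seed=53),
        )
        binned = SpeckleFrameSet(
            bin_stack(frames.sample, 2), bin_stack(frames.reference, 2)
        )
        window = WindowSpec.hamming(7)
        cfg = SolverConfig(
            window=window, levels=(1,), max_shift=2.0, width_bounds=(0.02, 1.25)
        )
        sol = solve_pixel((24, 24), binned, window, cfg)
        assert sol.u[0] == pytest.approx(1.0, abs=0.1)  # 2 px at full res
        assert 2 * sol.u[0] == pytest.approx(2.0, abs=0.2)

    def test_cascade_not_worse(self, uniform_noisy, window7):
        frames, _ = uniform_noisy
        select = np.zeros(frames.frame_shape, bool)
        select[40:58:8, 40:58:8] = True
        cfg_multi = SolverConfig(
            window=window7, levels=(2, 1), max_shift=2.0, width_bounds=(0.02, 2.5)
        )
        cfg_single = SolverConfig(
            window=window7, levels=(1,), max_shift=2.0, width_bounds=(0.02, 2.5)
        )
        m_multi = multires_solve(frames, cfg_multi, select=select)
        m_single = multires_solve(frames, cfg_single, select=select)
        from speckleddf.darkfield import summary_maps

        def mean_dtheta(maps):
            theta = summary_maps(maps.alpha1, maps.alpha2, maps.alpha3)["theta_deg"]
            d = (theta[maps.valid] - 30.0 + 90) % 180 - 90
            return np.abs(d).mean()

        assert mean_dtheta(m_multi) <= mean_dtheta(m_single) + 1.0


def test_bin_stack_block_average():
    arr = np.arange(32.0).reshape(1, 4, 8)
    out = bin_stack(arr, 2)
    assert out.shape == (1, 2, 4)
    assert out[0, 0, 0] == pytest.approx(np.mean([0, 1, 8, 9]))
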