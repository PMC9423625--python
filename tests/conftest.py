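import numpy as np
import pytest

from speckleddf import (
    AcquisitionSpec,
    PatternSpec,
    PhantomSpec,
    PrincipalAxes,
    SolverConfig,
    SpeckleFrameSet,
    WindowSpec,
)
from speckleddf.synth import simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_frames():
    """Tiny random frame set (positive, away from zero) for cost oracles."""
    gen = np.random.default_rng(7)
    sample = gen.uniform(1.0, 2.0, (2, 40, 40))
    reference = gen.uniform(1.0, 2.0, (2, 40, 40))
    return SpeckleFrameSet(sample, reference)


STANDARD_AXES = PrincipalAxes(2.0, 1.0, 30.0)


@pytest.fixture(scope="session")
def uniform_noiseless():
    """Noiseless uniform phantom: T=0.8, u=(1.4, -0.6), axes (2, 1, 30 deg)."""
    phantom = PhantomSpec.uniform(
        (96, 96), T=0.8, shift=(1.4, -0.6), axes=STANDARD_AXES
    )
    pattern = PatternSpec(shape=(96, 96), seed=11)
    acq = AcquisitionSpec(n_positions=25, noise=False, seed=13)
    frames, truth = simulate(pattern, phantom, acq)
    return frames, truth


@pytest.fixture(scope="session")
def uniform_noisy():
    """Same phantom with Poisson noise at 1e4 counts, 50 reference averages."""
    phantom = PhantomSpec.uniform(
        (96, 96), T=0.8, shift=(0.6, -0.4), axes=STANDARD_AXES
    )
    pattern = PatternSpec(shape=(96, 96), seed=21, mean_counts=1e4)
    acq = AcquisitionSpec(n_positions=25, noise=True, seed=23)
    frames, truth = simulate(pattern, phantom, acq)
    return frames, truth


@pytest.fixture
def window7():
    return WindowSpec.hamming(7)


@pytest.fixture
def fast_config(window7):
    """Solver configuration sized for small test frames."""
    return SolverConfig(
        window=window7,
        levels=(1,),
        max_shift=2.0,
        width_bounds=(0.02, 2.5),
    )
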