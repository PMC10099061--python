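import numpy as np
import pytest

from fescycling import CircularInterval, MuscleModel, RevolutionProfile, SimulationConfig


@pytest.fixture
def cfg50():
    """Ten noiseless revolutions at 50 rpm, 1 kHz."""
    return SimulationConfig(cadence=50.0, duration=12.0, seed=7)


@pytest.fixture
def quad_right():
    return MuscleModel(
        name="right_quadriceps",
        side="right",
        active_arc=CircularInterval(330.0, 90.0),
        peak_force=50.0,
        emd=0.0,
    )


def profile_from_function(fn, bin_width=1.0, n_revolutions=1):
    """RevolutionProfile sampling ``fn`` (degrees -> value) at bin centers."""
    n = int(round(360.0 / bin_width))
    grid = (np.arange(n) + 0.5) * bin_width
    return RevolutionProfile(
        grid=grid,
        values=np.asarray([fn(g) for g in grid], dtype=float),
        counts=np.full(n, 3, dtype=int),
        n_revolutions=n_revolutions,
        bin_width=bin_width,
    )


@pytest.fixture
def make_profile():
    return profile_from_function
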