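import numpy as np
import pytest

from thermotol.thermo_io import Thermogram, uniform_grid


def make_thermogram(temperature, heat_flow, *, mass=20.0, normalized=True,
                    sample_id="test", species="", run_kind="initial"):
    temperature = np.asarray(temperature, dtype=float)
    return Thermogram(sample_id=sample_id, species=species, fresh_mass=mass,
                      time=temperature - temperature[0],
                      temperature=temperature,
                      heat_flow=np.asarray(heat_flow, dtype=float),
                      normalized=normalized, run_kind=run_kind)


@pytest.fixture
def grid():
    return uniform_grid(25.0, 65.0, 0.1)


@pytest.fixture
def piecewise_curve(grid):
    """Noise-free two-segment decline: slope -0.5 to 45 °C, -3 after."""
    bp = 45.0
    y = np.where(grid <= bp, -0.5 * (grid - 25.0),
                 -0.5 * (bp - 25.0) - 3.0 * (grid - bp))
    return make_thermogram(grid, y)


@pytest.fixture
def linear_curve(grid):
    return make_thermogram(grid, -0.5 * (grid - 25.0))
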