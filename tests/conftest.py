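import numpy as np
import pytest
from hypothesis import settings

from pestfate.grid import Grid
from pestfate.pipeline import derive_terrain
from pestfate.synthetic import ScenarioSpec, synth_scenario

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


def make_grid(values, cell: float = 1.0, units: str = "") -> Grid:
    """Grid on a simple planar north-up transform."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    nr = values.shape[0]
    return Grid(values, (0.0, cell, 0.0, nr * cell, 0.0, -cell), units=units)


@pytest.fixture(scope="session")
def spec64() -> ScenarioSpec:
    return ScenarioSpec(shape=(64, 64), seed=7)


@pytest.fixture(scope="session")
def scenario64(spec64):
    return synth_scenario(spec64)


@pytest.fixture(scope="session")
def terrain64(scenario64):
    return derive_terrain(scenario64["dem"])
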