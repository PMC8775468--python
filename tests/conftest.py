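import numpy as np
import pytest

from calnet import SimulationConfig, simulate_traces
from calnet.types import CellMap, TraceMatrix


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recording():
    """A 20-cell, 4-minute recording with defaults otherwise."""
    cfg = SimulationConfig(n_cells=20, n_frames=1200, frame_rate=5.0,
                           inactive_fraction=0.3, seed=42)
    traces, truth = simulate_traces(cfg)
    return cfg, traces, truth


@pytest.fixture()
def grid_cell_map():
    """A 3x3 grid of cells, 100 um apart, radius 8 um."""
    xs, ys = np.meshgrid(np.arange(3) * 100.0 + 50, np.arange(3) * 100.0 + 50)
    return CellMap(cell_ids=list(range(9)), x=xs.ravel(), y=ys.ravel(),
                   radius=np.full(9, 8.0))


def make_traces(values, frame_rate=5.0):
    return TraceMatrix(values=np.asarray(values, dtype=float),
                       frame_rate=frame_rate)
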