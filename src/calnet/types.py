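"""Shared data containers used across the pipeline.

The containers are deliberately thin: a trace matrix is a frames x cells
array with a frame rate, a cell map is a table of disc-shaped somata, a
spike table is a flat list of (electrode, time) records.  Heavier structure
(graphs, events) lives in the modules that produce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TraceMatrix:
    """Per-cell fluorescence (or characteristic) time series.

    Parameters
    ----------
    values : ndarray, shape (n_frames, n_cells)
        Intensity in arbitrary fluorescence units; one column per cell.
    frame_rate : float
        Acquisition rate in frames per second.  Must be positive.
    cell_ids : list of int
        Column labels.  Defaults to ``0..n_cells-1``.
    """

    values: np.ndarray
    frame_rate: float
    cell_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (frames x cells) array")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if not self.cell_ids:
            self.cell_ids = list(range(self.values.shape[1]))
        if len(self.cell_ids) != self.values.shape[1]:
            raise ValueError("cell_ids length must match the number of columns")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    def trace(self, cell_id: int) -> np.ndarray:
        """Return the series for one cell id (not column index)."""
        return self.values[:, self.cell_ids.index(cell_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=[str(c) for c in self.cell_ids])


@dataclass
class CellMap:
    """Disc model of cell somata: centroids and radii in micrometres."""

    cell_ids: list[int]
    x: np.ndarray
    y: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        n = len(self.cell_ids)
        if not (len(self.x) == len(self.y) == len(self.radius) == n):
            raise ValueError("cell_ids, x, y and radius must have equal length")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids must be unique")
        if n and not np.all(self.radius > 0):
            raise ValueError("radii must be positive")

    def __len__(self) -> int:
        return len(self.cell_ids)

    def position(self, cell_id: int) -> tuple[float, float]:
        i = self.cell_ids.index(cell_id)
        return float(self.x[i]), float(self.y[i])

    def distance(self, i: int, j: int) -> float:
        """Euclidean centre-to-centre distance between two cell ids, in um."""
        xi, yi = self.position(i)
        xj, yj = self.position(j)
        return float(np.hypot(xi - xj, yi - yj))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "x_um": self.x, "y_um": self.y,
             "radius_um": self.radius}
        )


@dataclass
class SpikeTable:
    """Extracellular spike records from a multi-electrode array.

    ``electrode`` and ``time_ms`` are parallel arrays sorted by time
    (ties broken by electrode id, for determinism).  ``layout`` optionally
    maps electrode ids to grid (row, col) positions.
    """

    electrode: np.ndarray
    time_ms: np.ndarray
    duration_min: float
    layout: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.electrode = np.asarray(self.electrode, dtype=int)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.electrode.shape != self.time_ms.shape:
            raise ValueError("electrode and time_ms must have equal length")
        if not self.duration_min > 0:
            raise ValueError("duration_min must be positive")
        if len(self.time_ms):
            if self.time_ms.min() < 0 or self.time_ms.max() > self.duration_min * 60_000:
                raise ValueError("spike times must lie within the recording")
        order = np.lexsort((self.electrode, self.time_ms))
        self.electrode = self.electrode[order]
        self.time_ms = self.time_ms[order]

    def __len__(self) -> int:
        return len(self.time_ms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"electrode_id": self.electrode, "time_ms": self.time_ms})
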