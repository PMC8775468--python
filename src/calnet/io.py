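"""File formats: CSV tables, multi-page TIFF movies, GraphML, JSON.

Round-trip fidelity is part of the contract: traces and spikes are written
with full float precision (``repr`` roundtrip), movies as float32 TIFF
stacks, graphs as GraphML with vertex coordinates and edge attributes.
Every write helper is paired with a reader that reproduces the in-memory
object exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .bursts import NetworkBurst
from .events import CalciumEvent
from .network import FunctionalNetwork
from .segmentation import ActivityMovie, CellSignalPair
from .types import CellMap, SpikeTable, TraceMatrix

# ---------------------------------------------------------------------------
# traces


def write_traces_csv(traces: TraceMatrix, path) -> None:
    """Cells as columns (header = cell id), frames as rows."""
    traces.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_traces_csv(path, frame_rate: float) -> TraceMatrix:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return TraceMatrix(values=np.empty((0, 0)), frame_rate=frame_rate)
    if df.empty and df.shape[1] == 0:
        return TraceMatrix(values=np.empty((0, 0)), frame_rate=frame_rate)
    return TraceMatrix(values=df.to_numpy(dtype=float), frame_rate=frame_rate,
                       cell_ids=[int(c) for c in df.columns])


# ---------------------------------------------------------------------------
# cell maps


def write_cell_map_csv(cell_map: CellMap, path) -> None:
    cell_map.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_cell_map_csv(path) -> CellMap:
    df = pd.read_csv(path, float_precision="round_trip")
    return CellMap(cell_ids=[int(c) for c in df["cell_id"]],
                   x=df["x_um"].to_numpy(), y=df["y_um"].to_numpy(),
                   radius=df["radius_um"].to_numpy())


# ---------------------------------------------------------------------------
# movies


def write_movie_tiff(movie: ActivityMovie, path) -> None:
    tifffile.imwrite(path, movie.frames.astype(np.float32))


def read_movie_tiff(path, frame_rate: float, um_per_pixel: float = 1.0
                    ) -> ActivityMovie:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return ActivityMovie(frames=np.asarray(frames, dtype=float),
                         frame_rate=frame_rate, um_per_pixel=um_per_pixel)


# ---------------------------------------------------------------------------
# spikes


def write_spikes_csv(spikes: SpikeTable, path) -> None:
    spikes.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_spikes_csv(path, duration_min: float,
                    layout: pd.DataFrame | None = None) -> SpikeTable:
    df = pd.read_csv(path, float_precision="round_trip")
    return SpikeTable(electrode=df["electrode_id"].to_numpy(dtype=int),
                      time_ms=df["time_ms"].to_numpy(dtype=float),
                      duration_min=duration_min, layout=layout)


def read_layout_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"electrode_id", "row", "col"} - set(df.columns)
    if missing:
        raise ValueError(f"layout file is missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# events / signals / bursts tables


def events_to_frame(events: dict[int, list[CalciumEvent]]) -> pd.DataFrame:
    rows = [(cid, ev.t_start, ev.t_end, ev.peak_amplitude)
            for cid in sorted(events) for ev in events[cid]]
    return pd.DataFrame(rows, columns=["cell_id", "t_start_s", "t_end_s",
                                       "amplitude"])


def signals_to_frame(signals: list[CellSignalPair]) -> pd.DataFrame:
    rows = []
    for sig in signals:
        for frame in range(len(sig.C)):
            rows.append((frame, sig.cell_id, sig.C[frame], int(sig.A[frame])))
    return pd.DataFrame(rows, columns=["frame", "cell_id", "C", "A"])


def bursts_to_frame(bursts: list[NetworkBurst]) -> pd.DataFrame:
    rows = [(i, b.start_ms, b.end_ms, b.duration_ms, b.n_spikes,
             len(b.electrodes)) for i, b in enumerate(bursts)]
    return pd.DataFrame(rows, columns=["burst", "start_ms", "end_ms",
                                       "duration_ms", "n_spikes",
                                       "n_electrodes"])


def activation_patterns_to_frame(patterns: list[dict[int, float]]
                                 ) -> pd.DataFrame:
    rows = [(i, e, d) for i, pat in enumerate(patterns)
            for e, d in pat.items()]
    return pd.DataFrame(rows, columns=["burst", "electrode_id", "delay_ms"])


# ---------------------------------------------------------------------------
# graphs


def write_network_graphml(network: FunctionalNetwork, path) -> None:
    g = network.graph.copy()
    g.graph["rho_thr"] = network.rho_thr
    g.graph["mode"] = network.mode
    nx.write_graphml(g, path)


def read_network_graphml(path) -> FunctionalNetwork:
    g = nx.read_graphml(path, node_type=int)
    for _, _, attrs in g.edges(data=True):
        if "tau" in attrs:
            attrs["tau"] = int(attrs["tau"])
    return FunctionalNetwork(graph=g, rho_thr=float(g.graph.get("rho_thr", 0.0)),
                             mode=g.graph.get("mode",
                                              "directed" if g.is_directed()
                                              else "undirected"))


def edge_list_frame(network: FunctionalNetwork) -> pd.DataFrame:
    rows = [(u, v, a.get("rho"), a.get("rho_max"), a.get("tau"),
             bool(a.get("directed", network.mode == "directed")))
            for u, v, a in network.edge_list()]
    return pd.DataFrame(rows, columns=["i", "j", "rho", "rho_max",
                                       "tau_frames", "directed"])


# ---------------------------------------------------------------------------
# JSON + provenance


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, newline-terminated."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     allow_nan=False, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def provenance_record(stage: str, params: dict,
                      inputs: dict[str, str] | None = None,
                      timestamp: str | None = None) -> dict:
    """Provenance block emitted next to every artifact.

    The timestamp is optional and kept out of analysis outputs so that two
    runs from the same seed produce byte-identical result files.
    """
    from . import __version__

    rec = {
        "tool": "calnet",
        "version": __version__,
        "stage": stage,
        "parameters": params,
        "config_sha256": hashlib.sha256(
            json.dumps(params, sort_keys=True, default=_jsonify).encode()
        ).hexdigest(),
        "input_sha256": inputs or {},
    }
    if timestamp is not None:
        rec["timestamp"] = timestamp
    return rec
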