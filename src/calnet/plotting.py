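"""Optional figures: correlation-vs-distance scatter and network graph plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx

from .metrics import adjacency_pairs
from .network import CorrelationResult, FunctionalNetwork
from .types import CellMap


def plot_correlation_vs_distance(pairs: list[CorrelationResult],
                                 cell_map: CellMap, path,
                                 contact_slack: float = 1.2) -> None:
    """Scatter of lag-maximized correlation against pair distance.

    Spatially adjacent pairs (somata in contact) are drawn in red, distant
    pairs in blue.
    """
    adj = adjacency_pairs(cell_map, contact_slack)
    fig, ax = plt.subplots(figsize=(5, 4))
    for p in pairs:
        if not p.defined:
            continue
        key = (min(p.i, p.j), max(p.i, p.j))
        ax.scatter(p.rho_max, cell_map.distance(p.i, p.j),
                   s=8, c="red" if key in adj else "tab:blue", alpha=0.6)
    ax.set_xlabel("max lagged correlation")
    ax.set_ylabel("pair distance (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_network(network: FunctionalNetwork, cell_map: CellMap, path) -> None:
    """Draw the functional graph at the cells' spatial positions."""
    pos = {cid: cell_map.position(cid) for cid in network.graph.nodes
           if cid in cell_map.cell_ids}
    fig, ax = plt.subplots(figsize=(5, 5))
    nx.draw_networkx(network.graph, pos=pos, ax=ax, node_size=30,
                     with_labels=False, arrows=network.graph.is_directed(),
                     edge_color="gray", node_color="tab:green")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_burst_raster(spikes, bursts, path) -> None:
    """Spike raster with detected network bursts shaded."""
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.scatter(spikes.time_ms / 1000.0, spikes.electrode, s=1, c="black")
    for b in bursts:
        ax.axvspan(b.start_ms / 1000.0, b.end_ms / 1000.0, color="orange",
                   alpha=0.3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("electrode")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
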