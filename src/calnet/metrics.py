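"""Summary statistics of a reconstructed functional network.

Five characteristics describe one recording: the number of functional
connections N_c, the average number of connections per cell N_n, the
average signal-propagation speed S between connected cells, the average
network correlation P over all cell pairs, and the average correlation
P_a over spatially adjacent pairs (somata in contact).  A sixth figure,
the percentage of the maximum possible number of connections, normalizes
N_c by the all-to-all pair count n(n-1)/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import CorrelationResult, FunctionalNetwork
from .types import CellMap

logger = logging.getLogger(__name__)

#: Centroid distance up to this multiple of the summed radii counts as
#: soma-soma contact; the 20 % slack absorbs centroid/radius estimation
#: error in what is visually a "touching somata" criterion.
DEFAULT_CONTACT_SLACK = 1.2


@dataclass
class NetworkMetrics:
    """The network characteristics of one recording.

    Speed fields are ``None`` when no edge has a nonzero lag; correlation
    means are ``None`` when the relevant pair set is empty.  ``n_cells < 2``
    leaves every field ``None`` (metrics undefined-as-absent).
    """

    n_cells: int
    Nc: int | None = None
    Nn: float | None = None
    S_um_per_frame: float | None = None
    S_um_per_s: float | None = None
    P: float | None = None
    Pa: float | None = None
    pct_max: float | None = None
    n_zero_lag_excluded: int = 0
    n_adjacent_pairs: int = 0

    def as_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_connections": self.Nc,
            "mean_connections_per_cell": self.Nn,
            "mean_speed_um_per_frame": self.S_um_per_frame,
            "mean_speed_um_per_s": self.S_um_per_s,
            "mean_correlation_all_pairs": self.P,
            "mean_correlation_adjacent_pairs": self.Pa,
            "pct_of_max_connections": self.pct_max,
            "n_zero_lag_edges_excluded_from_speed": self.n_zero_lag_excluded,
            "n_adjacent_pairs": self.n_adjacent_pairs,
        }


def adjacency_pairs(cell_map: CellMap,
                    contact_slack: float = DEFAULT_CONTACT_SLACK
                    ) -> set[tuple[int, int]]:
    """Unordered pairs of cells whose somata are in direct contact.

    Pair (i, j) is adjacent when the centroid distance does not exceed
    ``contact_slack x (r_i + r_j)``.
    """
    if len(cell_map) == 0:
        raise ValueError("cell map is empty")
    ids = cell_map.cell_ids
    xy = np.column_stack([cell_map.x, cell_map.y])
    out: set[tuple[int, int]] = set()
    for a in range(len(ids)):
        d = np.hypot(*(xy[a + 1:] - xy[a]).T)
        limit = contact_slack * (cell_map.radius[a] + cell_map.radius[a + 1:])
        for off in np.flatnonzero(d <= limit):
            b = a + 1 + int(off)
            out.add((min(ids[a], ids[b]), max(ids[a], ids[b])))
    return out


def compute_metrics(network: FunctionalNetwork,
                    correlations: list[CorrelationResult],
                    cell_map: CellMap,
                    frame_rate: float | None = None,
                    contact_slack: float = DEFAULT_CONTACT_SLACK
                    ) -> NetworkMetrics:
    """Compute the network characteristics of one recording.

    * ``Nc`` — edge count of the thresholded graph;
    * ``Nn`` — mean incident-edge count per cell (direction ignored);
    * ``S`` — mean over edges with nonzero lag of d_ij / |tau_ij|, in
      um/frame (and um/s when ``frame_rate`` is given); zero-lag edges are
      excluded from the mean and counted;
    * ``P`` — mean lag-maximized correlation over all defined pairs;
    * ``Pa`` — the same mean restricted to spatially adjacent pairs
      (adjacency is a property of the cell map, not of the graph);
    * ``pct_max`` — 100 x Nc / (n(n-1)/2).
    """
    n = network.n_cells
    if n < 2:
        return NetworkMetrics(n_cells=n)
    g = network.graph
    nc = g.number_of_edges()
    undirected_degree = (g.to_undirected() if g.is_directed() else g).degree
    nn = float(np.mean([d for _, d in undirected_degree]))

    speeds = []
    zero_lag = 0
    for u, v, attrs in g.edges(data=True):
        tau = attrs.get("tau", 0)
        if tau == 0:
            zero_lag += 1
            continue
        speeds.append(cell_map.distance(u, v) / abs(tau))
    if zero_lag:
        logger.info("excluded %d zero-lag edges from the speed average", zero_lag)
    s_frame = float(np.mean(speeds)) if speeds else None
    s_sec = s_frame * frame_rate if (s_frame is not None and frame_rate) else None

    defined = [p for p in correlations if p.defined]
    p_all = float(np.mean([p.rho_max for p in defined])) if defined else None
    adj = adjacency_pairs(cell_map, contact_slack)
    adj_vals = [p.rho_max for p in defined
                if (min(p.i, p.j), max(p.i, p.j)) in adj]
    p_adj = float(np.mean(adj_vals)) if adj_vals else None

    max_pairs = n * (n - 1) / 2
    metrics = NetworkMetrics(
        n_cells=n, Nc=nc, Nn=nn,
        S_um_per_frame=s_frame, S_um_per_s=s_sec,
        P=p_all, Pa=p_adj,
        pct_max=100.0 * nc / max_pairs,
        n_zero_lag_excluded=zero_lag,
        n_adjacent_pairs=len(adj),
    )
    # handshake identity: the mean undirected degree is twice the edge
    # count over the cell count, always
    assert abs(metrics.Nn - 2.0 * nc / n) < 1e-9
    assert 0.0 <= metrics.pct_max <= 100.0 + 1e-9
    return metrics
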