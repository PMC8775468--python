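"""Functional-network reconstruction from per-cell activity signals.

Cells are vertices; a pair is functionally connected when the Pearson
correlation of its detrended activity signals exceeds a threshold
(0.3 by default).  Two graph variants are built:

* undirected — zero-lag correlation ``rho`` against the threshold;
* directed — the correlation is maximized over integer frame shifts
  ``tau`` in ``[-W, W]`` (W = 10 frames by default); the sign of the
  optimal shift orients the edge (``tau > 0``: the first cell leads).

Signals are detrended by subtracting a trailing moving average before
correlating, which removes slow drift and baseline offsets so that the
correlation is carried by the timing of activity events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .types import CellMap

logger = logging.getLogger(__name__)

#: Correlation threshold for a functionally significant connection.
DEFAULT_RHO_THR = 0.3
#: Half-range W of the lag scan, frames.
DEFAULT_LAG_RANGE = 10
#: Default trailing moving-average window for detrending, seconds.
#: Longer than a transient's rise, shorter than the transient itself, so
#: detrending sharpens event onsets without erasing them.
DEFAULT_DETREND_S = 3.0
#: Minimum overlapping samples for a correlation to be defined.
MIN_OVERLAP = 3


@dataclass
class DetrendedSignal:
    """A signal after trailing-moving-average subtraction."""

    values: np.ndarray
    w: int  # window length, frames
    source: str = "C"  # which characteristic the signal came from


@dataclass
class CorrelationResult:
    """Correlation of one unordered cell pair.

    ``rho`` is the zero-lag Pearson coefficient, ``rho_max`` the maximum
    over the scanned shifts and ``tau`` the shift (frames, signed) at which
    the maximum is attained.  ``tau > 0`` means cell ``i`` leads cell ``j``.
    """

    i: int
    j: int
    rho: float
    rho_max: float
    tau: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.rho_max)


@dataclass
class FunctionalNetwork:
    """A reconstructed functional graph over cells.

    ``graph`` is a :class:`networkx.Graph` (undirected mode) or
    :class:`networkx.DiGraph` (directed mode) whose edges carry ``weight``
    (the correlation that admitted the edge), ``rho``, ``rho_max``,
    ``tau`` (frames) and ``directed`` attributes.
    """

    graph: nx.Graph | nx.DiGraph
    rho_thr: float
    mode: str  # "undirected" | "directed"

    @property
    def n_cells(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list[tuple]:
        """Edges as (i, j, attrs) with deterministic ordering."""
        return sorted(self.graph.edges(data=True), key=lambda e: (e[0], e[1]))


def detrend(signal: np.ndarray, w: int, source: str = "C") -> DetrendedSignal:
    """Subtract the trailing moving average with a ``w``-frame window.

    ``x'[k] = x[k] - mean(x[max(0, k-w) .. k])`` — the window covers the
    current frame and the ``w`` preceding ones, truncated at the start of
    the recording.  A constant signal detrends to all zeros.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if w < 1:
        raise ValueError("w must be >= 1")
    if len(x) <= w:
        raise ValueError("signal must be longer than the window")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    k = np.arange(len(x))
    lo = np.maximum(k - w, 0)
    means = (csum[k + 1] - csum[lo]) / (k + 1 - lo)
    return DetrendedSignal(values=x - means, w=w, source=source)


def pearson(xi: np.ndarray, xj: np.ndarray) -> float:
    """Centered Pearson correlation coefficient of two equal-length signals.

    Returns ``nan`` when either side has zero variance (undefined
    correlation; such pairs are excluded from the graph).
    """
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape or xi.ndim != 1:
        raise ValueError("signals must be 1-D and equally long")
    if len(xi) < MIN_OVERLAP:
        raise ValueError(f"need at least {MIN_OVERLAP} samples")
    a = xi - xi.mean()
    b = xj - xj.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def lagged_max_correlation(xi: np.ndarray, xj: np.ndarray,
                           W: int = DEFAULT_LAG_RANGE) -> tuple[float, int]:
    """Maximize the correlation over integer shifts ``tau`` in ``[-W, W]``.

    For each shift the coefficient is computed on the overlapping segment
    (pairing ``xi[k]`` with ``xj[k + tau]``) with per-segment means, so the
    zero-shift value equals :func:`pearson`.  Returns ``(rho_max, tau)``;
    ``tau > 0`` means ``xi`` leads ``xj``.  Shifts whose overlap is shorter
    than 3 samples are skipped; if every shift is undefined the result is
    ``(nan, 0)``.
    """
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape or xi.ndim != 1:
        raise ValueError("signals must be 1-D and equally long")
    if W < 0:
        raise ValueError("W must be non-negative")
    n = len(xi)
    best_rho, best_tau = float("nan"), 0
    for tau in range(-W, W + 1):
        if tau >= 0:
            a, b = xi[:n - tau], xj[tau:]
        else:
            a, b = xi[-tau:], xj[:n + tau]
        if len(a) < MIN_OVERLAP:
            continue
        r = pearson(a, b)
        if np.isnan(r):
            continue
        if np.isnan(best_rho) or r > best_rho:
            best_rho, best_tau = r, tau
    return best_rho, best_tau


def correlate_pairs(signals: np.ndarray, cell_ids: list[int] | None = None,
                    w: int = 15, W: int = DEFAULT_LAG_RANGE
                    ) -> list[CorrelationResult]:
    """Detrend every signal and correlate every unordered cell pair.

    ``signals`` is frames x cells.  Zero-variance cells are excluded before
    pair enumeration (their correlation is undefined); the exclusion count
    is logged.
    """
    signals = np.asarray(signals, dtype=float)
    if cell_ids is None:
        cell_ids = list(range(signals.shape[1]))
    detrended = {}
    excluded = 0
    for col, cid in enumerate(cell_ids):
        d = detrend(signals[:, col], w).values
        if np.allclose(d, 0.0) or np.std(d) == 0.0:
            excluded += 1
            continue
        detrended[cid] = d
    if excluded:
        logger.info("excluded %d zero-variance cells from pair enumeration",
                    excluded)
    kept = sorted(detrended)
    results = []
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            i, j = kept[a], kept[b]
            rho = pearson(detrended[i], detrended[j])
            rho_max, tau = lagged_max_correlation(detrended[i], detrended[j], W)
            results.append(CorrelationResult(i=i, j=j, rho=rho,
                                             rho_max=rho_max, tau=tau))
    return results


def build_network(pairs: list[CorrelationResult],
                  rho_thr: float = DEFAULT_RHO_THR,
                  mode: str = "undirected",
                  cell_ids: list[int] | None = None,
                  cell_map: CellMap | None = None,
                  strict_lag: bool = False) -> FunctionalNetwork:
    """Assemble the functional graph from pairwise correlations.

    Undirected mode keeps pair (i, j) when ``rho > rho_thr``.  Directed mode
    keeps it when ``rho_max > rho_thr`` and orients it by the sign of
    ``tau``; pairs whose optimum shift is zero have no defined direction and
    are kept as ``directed=False`` edges (stored as i->j) unless
    ``strict_lag`` is set, in which case they are dropped.

    ``cell_ids`` fixes the vertex set (isolated cells included); otherwise
    the vertices are the cells appearing in ``pairs``.  ``cell_map``
    attaches ``x``/``y`` coordinates (um) to vertices.
    """
    if mode not in ("undirected", "directed"):
        raise ValueError("mode must be 'undirected' or 'directed'")
    g = nx.Graph() if mode == "undirected" else nx.DiGraph()
    if cell_ids is None:
        cell_ids = sorted({c for p in pairs for c in (p.i, p.j)})
    g.add_nodes_from(cell_ids)
    if cell_map is not None:
        for cid in cell_ids:
            if cid in cell_map.cell_ids:
                x, y = cell_map.position(cid)
                g.nodes[cid]["x"] = x
                g.nodes[cid]["y"] = y
    dropped_zero_lag = 0
    for p in pairs:
        if not p.defined:
            continue
        attrs = {"rho": p.rho, "rho_max": p.rho_max, "tau": int(p.tau)}
        if mode == "undirected":
            if p.rho > rho_thr:
                g.add_edge(p.i, p.j, weight=p.rho, directed=False, **attrs)
        else:
            if p.rho_max > rho_thr:
                if p.tau > 0:
                    g.add_edge(p.i, p.j, weight=p.rho_max, directed=True, **attrs)
                elif p.tau < 0:
                    g.add_edge(p.j, p.i, weight=p.rho_max, directed=True,
                               rho=p.rho, rho_max=p.rho_max, tau=-int(p.tau))
                elif strict_lag:
                    dropped_zero_lag += 1
                else:
                    g.add_edge(p.i, p.j, weight=p.rho_max, directed=False, **attrs)
    if dropped_zero_lag:
        logger.info("dropped %d zero-lag pairs under strict-lag", dropped_zero_lag)
    return FunctionalNetwork(graph=g, rho_thr=rho_thr, mode=mode)


def infer_network(signals: np.ndarray, cell_ids: list[int] | None = None,
                  w: int = 15, W: int = DEFAULT_LAG_RANGE,
                  rho_thr: float = DEFAULT_RHO_THR, mode: str = "directed",
                  cell_map: CellMap | None = None, strict_lag: bool = False
                  ) -> tuple[FunctionalNetwork, list[CorrelationResult]]:
    """Convenience: detrend + correlate + threshold in one call."""
    if cell_ids is None:
        cell_ids = list(range(np.asarray(signals).shape[1]))
    pairs = correlate_pairs(signals, cell_ids, w=w, W=W)
    net = build_network(pairs, rho_thr=rho_thr, mode=mode, cell_ids=cell_ids,
                        cell_map=cell_map, strict_lag=strict_lag)
    return net, pairs
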