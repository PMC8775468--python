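"""Synthetic calcium-imaging and MEA recordings with planted ground truth.

The generator emulates the recording conditions the analysis modules are
built for: sparse 2-D fields of disc-shaped somata (tens of cells per mm^2),
per-cell calcium transients of roughly 12 s at roughly 1.3 oscillations per
minute, pairwise coupling with frame-scale lags, and multi-electrode-array
recordings containing small network bursts.  Every output carries the ground
truth needed to score the downstream stages: planted event intervals,
planted directed edges with lags, planted burst times.

Transient template
------------------
A transient is a fast linear rise (10 % of the nominal duration), a shallow
exponential decay to 90 % of peak (85 % of the duration), and a fast linear
return to baseline (final 5 %).  The nominal ``transient_duration`` is the
width of the template at typical detection-threshold level, so durations
measured by the event detector track the parameter; the abrupt return to
baseline is a simplification relative to real indicator kinetics (see the
methods note).

All randomness flows from one root seed through named child streams
(placement, events, coupling, noise, spikes), so the same configuration is
bit-reproducible and adding one output does not perturb another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import SeedSequence, default_rng

from .segmentation import ActivityMovie
from .types import CellMap, SpikeTable, TraceMatrix

#: Hard refractory gap between successive transients of one cell, seconds.
#: Keeps planted events non-overlapping and separable by the detector.
REFRACTORY_S = 4.0

_STREAMS = ("placement", "events", "coupling", "noise", "spikes")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic calcium recording.

    Defaults describe a healthy 21-DIV hippocampal culture: 45 cells in a
    1 x 1 mm field (4500 cells/cm^2), 10 min at 5 frames/s, ~12 s transients
    at ~1.3 per minute, 60 % of cells active, event amplitude 10x the noise
    standard deviation.
    """

    n_cells: int = 45
    field_size: tuple[float, float] = (1000.0, 1000.0)  # um x um
    frame_rate: float = 5.0  # frames / s
    n_frames: int = 3000  # 10 min at 5 fps
    transient_rate: float = 1.34  # events / min per active cell
    transient_duration: float = 12.0  # s
    transient_amplitude: float = 10.0  # fluorescence units
    noise_sd: float = 1.0  # fluorescence units
    planted_edges: list[tuple] = field(default_factory=list)
    inactive_fraction: float = 0.4
    active_cells: list[int] | None = None
    radius_range: tuple[float, float] = (6.0, 9.0)  # um
    cluster_fraction: float = 0.0  # share of cells placed in soma contact
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.n_frames < 0:
            raise ValueError("n_frames must be non-negative")
        if not (0.0 <= self.inactive_fraction <= 1.0):
            raise ValueError("inactive_fraction must be in [0, 1]")
        if self.field_size[0] <= 0 or self.field_size[1] <= 0:
            raise ValueError("field_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for edge in self.planted_edges:
            src, dst, lag, p = edge[:4]
            if not (0 <= src < self.n_cells and 0 <= dst < self.n_cells):
                raise ValueError(f"planted edge ({src}, {dst}) references unknown cells")
            if src == dst:
                raise ValueError("self-edges cannot be planted")
            if abs(int(lag)) >= max(self.n_frames, 1):
                raise ValueError(f"lag {lag} must be smaller than n_frames")
            if not (0.0 <= p <= 1.0):
                raise ValueError("coupling probability must be in [0, 1]")
            if len(edge) > 4 and edge[4] <= 0:
                raise ValueError("coupling gain must be positive")
        if self.active_cells is not None:
            if not set(self.active_cells) <= set(range(self.n_cells)):
                raise ValueError("active_cells references unknown cells")

    def rng(self, stream: str):
        """Child generator for a named stream, derived from the root seed."""
        idx = _STREAMS.index(stream)
        return default_rng(SeedSequence(self.seed).spawn(len(_STREAMS))[idx])


@dataclass
class GroundTruth:
    """What was planted: cells, directed edges, and event intervals.

    ``event_times`` holds the intrinsic (self-generated) transients per cell,
    non-overlapping by construction; transients copied through planted edges
    are listed separately in ``coupled_events`` because they may superpose on
    the target's own activity.
    """

    cell_map: CellMap
    edges: list[tuple[int, int, int, float]]
    event_times: dict[int, list[tuple[float, float]]]
    coupled_events: dict[int, list[tuple[float, float]]] = field(default_factory=dict)

    def planted_network(self, rho: float = 1.0):
        """The planted edges as a directed :class:`~calnet.network.FunctionalNetwork`."""
        from .network import CorrelationResult, build_network

        pairs = [
            CorrelationResult(i=src, j=dst, rho=rho, rho_max=rho, tau=int(lag))
            for src, dst, lag, _ in self.edges
        ]
        return build_network(pairs, rho_thr=0.0, mode="directed",
                             cell_ids=list(self.cell_map.cell_ids))


def transient_template(duration_s: float, frame_rate: float,
                       amplitude: float = 1.0) -> np.ndarray:
    """Sample the transient kernel on the frame grid.

    Linear rise over the first 7 % of ``duration_s``, then a shallow
    exponential decay to 95 % of peak across the rest of the support, then
    a return to baseline.  The plateau-like shape makes the width of the
    transient at detection-threshold level track ``duration_s``.
    """
    n = max(int(round(duration_s * frame_rate)), 3)
    n_rise = max(int(round(0.07 * n)), 1)
    n_decay = max(n - n_rise, 1)
    rise = np.linspace(0.0, 1.0, n_rise, endpoint=False)
    lam = -np.log(0.95) / n_decay
    decay = np.exp(-lam * np.arange(n_decay))
    kernel = np.concatenate([rise, decay])
    return amplitude * kernel[:n]


def simulate_cell_map(config: SimulationConfig) -> CellMap:
    """Place ``n_cells`` non-overlapping discs uniformly at random.

    Hard-disc rejection sampling: a candidate centre is redrawn until its
    disc neither leaves the field nor overlaps an accepted disc.  With
    ``cluster_fraction > 0`` that share of cells is instead placed just
    touching a randomly chosen earlier cell (cultured cells aggregate, and
    soma-soma contacts are what the neighbor-correlation statistic averages
    over).  Raises ``RuntimeError`` when the packing cannot be completed
    within a bounded number of attempts (density too high for the field).
    """
    rng = config.rng("placement")
    w, h = config.field_size
    xs = np.empty(config.n_cells)
    ys = np.empty(config.n_cells)
    rs = np.empty(config.n_cells)
    per_cell_attempts = 2000
    lo, hi = config.radius_range
    if 2 * hi > min(w, h):
        raise RuntimeError("cells do not fit inside the field at all")
    for n in range(config.n_cells):
        for attempt in range(per_cell_attempts):
            r = rng.uniform(lo, hi)
            if n > 0 and rng.random() < config.cluster_fraction:
                anchor = int(rng.integers(n))
                gap = rng.uniform(1.001, 1.15) * (r + rs[anchor])
                angle = rng.uniform(0.0, 2 * np.pi)
                x = xs[anchor] + gap * np.cos(angle)
                y = ys[anchor] + gap * np.sin(angle)
                if not (r <= x <= w - r and r <= y <= h - r):
                    continue
            else:
                x = rng.uniform(r, w - r)
                y = rng.uniform(r, h - r)
            if not np.any((x - xs[:n]) ** 2 + (y - ys[:n]) ** 2
                          <= (r + rs[:n]) ** 2):
                xs[n], ys[n], rs[n] = x, y, r
                break
        else:
            raise RuntimeError(
                f"could not place cell {n + 1} of {config.n_cells} in a "
                f"{w:g}x{h:g} um field after {per_cell_attempts} attempts; "
                "reduce the density"
            )
    return CellMap(cell_ids=list(range(config.n_cells)),
                   x=xs, y=ys, radius=rs)


def _draw_event_starts(rng, config: SimulationConfig) -> list[int]:
    """Start frames of one cell's transients.

    Poisson-timed with a dead time: candidate starts form a Poisson process
    whose intensity is raised so that, after discarding candidates closer
    than one transient plus the refractory gap to the previous accepted
    start, the accepted rate equals ``transient_rate`` (the classic
    non-paralyzable dead-time correction ``lam' = r / (1 - r * dead)``).
    Events that would overrun the recording are dropped.
    """
    if config.transient_rate <= 0:
        return []
    rate_per_s = config.transient_rate / 60.0
    dead_s = config.transient_duration + REFRACTORY_S
    if rate_per_s * dead_s >= 1.0:
        raise ValueError(
            "transient_rate too high for the transient duration plus the "
            f"{REFRACTORY_S:g}-s refractory gap"
        )
    lam = rate_per_s / (1.0 - rate_per_s * dead_s)
    dur_frames = int(round(config.transient_duration * config.frame_rate))
    duration_s = config.n_frames / config.frame_rate
    starts: list[int] = []
    t = rng.exponential(1.0 / lam)
    last_accepted = -np.inf
    while t < duration_s:
        if t - last_accepted >= dead_s:
            start = int(round(t * config.frame_rate))
            if start + dur_frames <= config.n_frames:
                starts.append(start)
                last_accepted = t
        t += rng.exponential(1.0 / lam)
    return starts


def simulate_traces(config: SimulationConfig,
                    cell_map: CellMap | None = None,
                    ) -> tuple[TraceMatrix, GroundTruth]:
    """Simulate coupled per-cell fluorescence traces.

    Each active cell fires template transients at renewal-process times; for
    every planted edge ``(i, j, lag, p[, gain])`` each intrinsic event of
    ``i`` is copied into ``j`` shifted by ``lag`` frames with probability
    ``p`` and amplitude scaled by ``gain`` (1 when omitted); Gaussian noise
    of ``noise_sd`` is then added everywhere.  Copies are made of intrinsic
    events only — coupling does not cascade along chains.

    Which cells are active is controlled by ``active_cells`` when given,
    otherwise a random subset of size ``round(n x (1 - inactive_fraction))``.

    Returns the trace matrix and the :class:`GroundTruth` that records the
    cell map, the planted edges and all event intervals.
    """
    if cell_map is None:
        cell_map = simulate_cell_map(config)
    ev_rng = config.rng("events")
    cp_rng = config.rng("coupling")
    noise_rng = config.rng("noise")

    n, t = config.n_cells, config.n_frames
    values = np.zeros((t, n))
    kernel = transient_template(config.transient_duration, config.frame_rate,
                                config.transient_amplitude)
    k = len(kernel)

    if config.active_cells is not None:
        inactive = set(range(n)) - set(config.active_cells)
    else:
        n_inactive = int(round(config.inactive_fraction * n))
        inactive = (set(ev_rng.choice(n, size=n_inactive, replace=False).tolist())
                    if n else set())

    event_times: dict[int, list[tuple[float, float]]] = {c: [] for c in range(n)}
    starts_by_cell: dict[int, list[int]] = {c: [] for c in range(n)}
    for c in range(n):
        if c in inactive:
            continue
        for s in _draw_event_starts(ev_rng, config):
            starts_by_cell[c].append(s)
            values[s:s + k, c] += kernel
            event_times[c].append((s / config.frame_rate,
                                   (s + k) / config.frame_rate))

    coupled: dict[int, list[tuple[float, float]]] = {}
    for edge in config.planted_edges:
        src, dst, lag, p = edge[:4]
        gain = float(edge[4]) if len(edge) > 4 else 1.0
        lag = int(lag)
        for s in starts_by_cell[src]:
            if p < 1.0 and cp_rng.random() >= p:
                continue
            s2 = s + lag
            if s2 < 0 or s2 + k > t:
                continue
            values[s2:s2 + k, dst] += gain * kernel
            coupled.setdefault(dst, []).append((s2 / config.frame_rate,
                                                (s2 + k) / config.frame_rate))

    if config.noise_sd > 0:
        values += noise_rng.normal(0.0, config.noise_sd, size=values.shape)

    traces = TraceMatrix(values=values, frame_rate=config.frame_rate,
                         cell_ids=list(range(n)))
    truth = GroundTruth(cell_map=cell_map,
                        edges=[(e[0], e[1], int(e[2]), e[3])
                               for e in config.planted_edges],
                        event_times=event_times, coupled_events=coupled)
    return traces, truth


def render_movie(traces: TraceMatrix, cell_map: CellMap,
                 image_shape: tuple[int, int], um_per_pixel: float = 4.0,
                 frame_rate: float | None = None) -> ActivityMovie:
    """Paint the traces as a grayscale movie of glowing discs.

    Each frame paints every cell's disc at the cell's current trace value
    over a dark (zero) background; overlapping discs add.  Cells must fit
    inside the image at the stated scale.
    """
    h, w = image_shape
    if h <= 0 or w <= 0:
        raise ValueError("image shape must be positive")
    if um_per_pixel <= 0:
        raise ValueError("um_per_pixel must be positive")
    yy, xx = np.mgrid[0:h, 0:w]
    masks = np.zeros((len(cell_map), h, w))
    for idx, cid in enumerate(cell_map.cell_ids):
        cx, cy = cell_map.position(cid)
        r_px = cell_map.radius[idx] / um_per_pixel
        cx_px, cy_px = cx / um_per_pixel, cy / um_per_pixel
        if (cx_px - r_px < 0 or cx_px + r_px > w
                or cy_px - r_px < 0 or cy_px + r_px > h):
            raise ValueError(f"cell {cid} does not fit inside the image bounds")
        masks[idx] = ((xx - cx_px) ** 2 + (yy - cy_px) ** 2 <= r_px ** 2)
    frames = np.tensordot(traces.values, masks, axes=(1, 0))
    return ActivityMovie(frames=frames,
                         frame_rate=frame_rate or traces.frame_rate,
                         um_per_pixel=um_per_pixel)


def plant_random_network(n_cells: int, n_edges: int, strength: float = 0.45,
                         lag_range: tuple[int, int] = (1, 8),
                         max_in_degree: int = 3,
                         seed: int = 0) -> list[tuple]:
    """Sample a random directed network of uniform planted edge strength.

    Every returned edge ``(src, dst, lag, 1.0, gain)`` is constructed to
    carry the same pairwise lag-maximized correlation ``strength`` between
    source and target, independent of the target's in-degree: the copy
    gain is ``strength / sqrt(1 - d * strength**2)`` for a target with
    ``d`` incoming edges (power normalization for superposed copies).

    The topology is constrained so that planted adjacency stays
    identifiable by pairwise correlation: sources and targets are disjoint
    (no chains), targets have in-degree at most ``max_in_degree``, and two
    targets never share more than one source, which bounds the correlation
    of any non-edge pair by ``strength**2`` (a shared-driver fork).
    Without these constraints no pairwise-correlation method could
    recover the planted adjacency, and a recovery benchmark would measure
    the topology sampler rather than the estimator.

    Raises ``ValueError`` when the requested density is infeasible under
    the constraints.
    """
    if not (0.0 < strength < 1.0):
        raise ValueError("strength must be in (0, 1)")
    if max_in_degree * strength ** 2 >= 1.0:
        raise ValueError("strength too high for the in-degree cap")
    rng = default_rng(seed)
    lo, hi = lag_range
    for _ in range(50):  # restarts
        edges: set[tuple[int, int]] = set()
        sources: dict[int, set[int]] = {}  # target -> its sources
        out: dict[int, set[int]] = {}  # source -> its targets
        stalled = 0
        while len(edges) < n_edges and stalled < 2000:
            stalled += 1
            src, dst = (int(v) for v in rng.choice(n_cells, 2, replace=False))
            if src in sources or dst in out:  # keep it bipartite
                continue
            if (src, dst) in edges or len(sources.get(dst, ())) >= max_in_degree:
                continue
            # two targets may share at most one source
            if any(sources.get(dst, set()) & sources[sib]
                   for sib in out.get(src, set())):
                continue
            edges.add((src, dst))
            sources.setdefault(dst, set()).add(src)
            out.setdefault(src, set()).add(dst)
            stalled = 0
        if len(edges) == n_edges:
            result = []
            for src, dst in sorted(edges):
                d = len(sources[dst])
                gain = strength / np.sqrt(1.0 - d * strength ** 2)
                lag = int(rng.integers(lo, hi + 1))
                result.append((src, dst, lag, 1.0, float(gain)))
            return result
    raise ValueError(
        f"could not plant {n_edges} edges over {n_cells} cells under the "
        "identifiability constraints; lower the density"
    )


# ---------------------------------------------------------------------------
# MEA spike trains


@dataclass
class BurstSpec:
    """One planted network burst.

    Electrodes fire in listed order, ``propagation_ms`` apart; each electrode
    contributes ``spikes_per_electrode`` spikes ``intra_gap_ms`` apart; every
    spike is jittered by up to ``jitter_ms`` (uniform).
    """

    start_ms: float
    electrodes: list[int]
    spikes_per_electrode: int = 1
    jitter_ms: float = 0.0
    propagation_ms: float = 10.0
    intra_gap_ms: float = 5.0


@dataclass
class PlantedBurst:
    """Realized ground truth for one planted burst."""

    start_ms: float
    end_ms: float
    electrodes: list[int]
    n_spikes: int


def make_burst_specs(n_bursts: int, duration_min: float, n_electrodes: int,
                     electrodes_per_burst: int = 10,
                     spikes_per_electrode: int = 9,
                     jitter_ms: float = 1.0, seed: int = 0) -> list[BurstSpec]:
    """Evenly spaced burst specs with random electrode subsets.

    Defaults emulate a healthy culture: ~36 bursts / 10 min of ~90 spikes on
    ~10 electrodes.
    """
    rng = default_rng(seed)
    total_ms = duration_min * 60_000
    starts = np.linspace(0.1 * total_ms / n_bursts, total_ms * (1 - 1.0 / n_bursts),
                         n_bursts)
    specs = []
    for s in starts:
        elec = rng.choice(n_electrodes, size=electrodes_per_burst,
                          replace=False).tolist()
        specs.append(BurstSpec(start_ms=float(s), electrodes=elec,
                               spikes_per_electrode=spikes_per_electrode,
                               jitter_ms=jitter_ms))
    return specs


def _burst_gap_bound(spec: BurstSpec) -> float:
    """Worst-case consecutive-spike gap inside one planted burst, ms."""
    nominal = max(spec.propagation_ms, spec.intra_gap_ms)
    return nominal + 2.0 * spec.jitter_ms


def simulate_spikes(n_electrodes: int, duration_min: float,
                    burst_spec: list[BurstSpec] | None = None,
                    background_rate: float = 0.0,
                    max_gap_ms: float = 100.0,
                    seed: int = 0) -> tuple[SpikeTable, list[PlantedBurst]]:
    """Background Poisson spikes plus planted network bursts.

    ``background_rate`` is per-electrode, spikes/s.  Planted bursts are
    validated so that, even at worst-case jitter, consecutive within-burst
    gaps stay below ``max_gap_ms`` and neighbouring bursts cannot merge.
    Returns the spike table and the realized planted-burst list.
    """
    if duration_min <= 0:
        raise ValueError("duration_min must be positive")
    burst_spec = burst_spec or []
    total_ms = duration_min * 60_000
    rng = default_rng(SeedSequence(seed).spawn(1)[0])

    for spec in burst_spec:
        for e in spec.electrodes:
            if not (0 <= e < n_electrodes):
                raise ValueError(f"burst references unknown electrode {e}")
        if _burst_gap_bound(spec) >= max_gap_ms:
            raise ValueError(
                "jitter/propagation would allow within-burst gaps of "
                f"{_burst_gap_bound(spec):g} ms >= {max_gap_ms:g} ms"
            )

    electrodes: list[int] = []
    times: list[float] = []
    planted: list[PlantedBurst] = []
    for spec in sorted(burst_spec, key=lambda s: s.start_ms):
        b_elec: list[int] = []
        b_times: list[float] = []
        for m, e in enumerate(spec.electrodes):
            for s in range(spec.spikes_per_electrode):
                nominal = (spec.start_ms + m * spec.propagation_ms
                           + s * spec.intra_gap_ms)
                t = nominal + rng.uniform(-spec.jitter_ms, spec.jitter_ms)
                b_elec.append(e)
                b_times.append(min(max(t, 0.0), total_ms))
        electrodes.extend(b_elec)
        times.extend(b_times)
        planted.append(PlantedBurst(start_ms=min(b_times), end_ms=max(b_times),
                                    electrodes=sorted(set(b_elec)),
                                    n_spikes=len(b_times)))

    for a, b in zip(planted, planted[1:]):
        if b.start_ms - a.end_ms <= max_gap_ms:
            raise ValueError("planted bursts are too close and would merge")

    if background_rate > 0:
        for e in range(n_electrodes):
            n_bg = rng.poisson(background_rate * duration_min * 60.0)
            bg = rng.uniform(0.0, total_ms, size=n_bg)
            electrodes.extend([e] * n_bg)
            times.extend(bg.tolist())

    layout = mea_layout(n_electrodes)
    table = SpikeTable(electrode=np.array(electrodes, dtype=int),
                       time_ms=np.array(times), duration_min=duration_min,
                       layout=layout)
    return table, planted


def mea_layout(n_electrodes: int = 60):
    """Grid layout for an MEA: 8x8 minus corners for the standard 60-electrode
    array, otherwise a near-square grid filled row-major."""
    import pandas as pd

    if n_electrodes == 60:
        cells = [(r, c) for r in range(8) for c in range(8)
                 if (r, c) not in {(0, 0), (0, 7), (7, 0), (7, 7)}]
    else:
        side = int(np.ceil(np.sqrt(n_electrodes)))
        cells = [(r, c) for r in range(side) for c in range(side)][:n_electrodes]
    return pd.DataFrame({"electrode_id": range(n_electrodes),
                         "row": [r for r, _ in cells],
                         "col": [c for _, c in cells]})
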