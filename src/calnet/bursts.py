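"""Small network-burst detection in MEA spike trains.

Spikes from all electrodes are pooled into one train; a network burst is a
maximal run of consecutive spikes whose inter-spike gaps never exceed
``max_gap`` (100 ms by default) and that spans at least ``min_electrodes``
distinct electrodes (4 by default).  Electrode distinctness is evaluated
over the whole run.  Each burst also carries its activation pattern: the
first-spike latency of every participating electrode from burst start,
which describes how the discharge propagates across the array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import SpikeTable

DEFAULT_MIN_ELECTRODES = 4
DEFAULT_MAX_GAP_MS = 100.0


@dataclass
class NetworkBurst:
    """One detected network burst."""

    start_ms: float
    end_ms: float
    electrodes: list[int]
    spike_times: np.ndarray
    spike_electrodes: np.ndarray

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class BurstSummary:
    bursts_per_10min: float
    mean_spikes_per_burst: float | None
    mean_duration_ms: float | None
    n_bursts: int


def detect_bursts(spikes: SpikeTable,
                  min_electrodes: int = DEFAULT_MIN_ELECTRODES,
                  max_gap: float = DEFAULT_MAX_GAP_MS) -> list[NetworkBurst]:
    """Detect network bursts in the pooled spike train.

    The pooled train (already time-sorted, ties ordered by electrode id) is
    cut wherever a consecutive-spike gap exceeds ``max_gap`` ms; each
    maximal run spanning at least ``min_electrodes`` distinct electrodes
    becomes one burst.  Runs are maximal by construction, so no two
    detected bursts could be merged without violating ``max_gap``, every
    spike belongs to at most one burst, and bursts are time-ordered and
    non-overlapping.
    """
    if len(spikes) == 0:
        return []
    t = spikes.time_ms
    e = spikes.electrode
    cut = np.flatnonzero(np.diff(t) > max_gap)
    starts = np.concatenate([[0], cut + 1])
    ends = np.concatenate([cut, [len(t) - 1]])
    bursts = []
    for s, f in zip(starts, ends):
        elecs = np.unique(e[s:f + 1])
        if len(elecs) < min_electrodes:
            continue
        bursts.append(NetworkBurst(
            start_ms=float(t[s]), end_ms=float(t[f]),
            electrodes=elecs.tolist(),
            spike_times=t[s:f + 1].copy(),
            spike_electrodes=e[s:f + 1].copy(),
        ))
    return bursts


def summarize_bursts(bursts: list[NetworkBurst],
                     duration_min: float) -> BurstSummary:
    """Burst statistics normalized to a 10-minute record."""
    if not duration_min > 0:
        raise ValueError("duration must be positive")
    n = len(bursts)
    per10 = 10.0 * n / duration_min
    if n:
        spikes = float(np.mean([b.n_spikes for b in bursts]))
        dur = float(np.mean([b.duration_ms for b in bursts]))
    else:
        spikes = None
        dur = None
    return BurstSummary(bursts_per_10min=per10, mean_spikes_per_burst=spikes,
                        mean_duration_ms=dur, n_bursts=n)


def activation_pattern(burst: NetworkBurst) -> dict[int, float]:
    """First-spike latency (ms from burst start) per participating electrode.

    The electrode that opens the burst has latency 0.  Exported in
    electrode-id order; pair with the array layout for raster or
    colour-map rendering.
    """
    out: dict[int, float] = {}
    for e, t in zip(burst.spike_electrodes, burst.spike_times):
        e = int(e)
        if e not in out:
            out[e] = float(t - burst.start_ms)
    return dict(sorted(out.items()))
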