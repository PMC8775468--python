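"""Per-cell calcium-event detection and activity summaries.

An oscillation is a maximal run of frames in which the (lightly smoothed)
fluorescence trace F(t) exceeds its mean by a multiple of its deviation;
Tstart and Tend are the run's first and last frame converted to seconds.
Three activity parameters summarize a recording: the share of working
cells, the mean event frequency over active cells (oscillations/min), and
the mean event duration (s).

Thresholding is one-sided (above the mean only): calcium transients are
positive-going deflections of the indicator signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Default moving-average window applied before thresholding, seconds.
#: Suppresses single-frame noise dips that would otherwise split one
#: transient into several runs.  Set to 0 to threshold the raw trace.
DEFAULT_SMOOTH_S = 1.0

#: Default minimum event duration, seconds.  Calcium oscillations last
#: seconds; excursions shorter than this are treated as noise crossings.
DEFAULT_MIN_DURATION_S = 3.5


@dataclass
class CalciumEvent:
    """One oscillation of one cell, bounded by threshold crossings."""

    cell_id: int
    t_start: float  # s
    t_end: float  # s
    peak_amplitude: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must precede t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ActivitySummary:
    """Recording-level activity parameters.

    ``mean_frequency`` and ``mean_duration`` are ``None`` when no cell has
    any event (undefined-as-absent rather than zero).
    """

    share_active: float  # %
    mean_frequency: float | None  # oscillations / min over active cells
    mean_duration: float | None  # s over all events
    per_cell_counts: dict[int, int]


def _deviation(trace: np.ndarray, mode: str) -> float:
    if mode == "std":
        return float(np.std(trace, ddof=1))
    if mode == "sem":
        return float(np.std(trace, ddof=1) / math.sqrt(len(trace)))
    if mode == "mad":
        med = np.median(trace)
        return float(1.4826 * np.median(np.abs(trace - med)))
    raise ValueError(f"unknown deviation mode {mode!r}")


def _runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive frame indices."""
    if not above.any():
        return []
    padded = np.diff(np.concatenate([[0], above.view(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_events(trace: np.ndarray, frame_rate: float, cell_id: int = 0,
                  threshold_multiplier: float = 1.0,
                  min_duration: int | None = None,
                  smooth_window: int | None = None,
                  merge_gap: int = 2,
                  deviation_mode: str = "std") -> list[CalciumEvent]:
    """Detect calcium oscillations on a single-cell trace.

    Parameters
    ----------
    trace : 1-D array
        Fluorescence intensity per frame; must be finite, length >= 3.
    frame_rate : float
        Frames per second; converts frame indices to seconds.
    threshold_multiplier : float
        Threshold = mean + multiplier x deviation of the trace.  The mean
        and deviation are computed on the raw trace; one unit of the
        deviation is the default.
    min_duration : int, optional
        Minimum event length in frames; defaults to 2.5 s worth of frames
        (at least 3).
    smooth_window : int, optional
        Moving-average window (frames) applied before the threshold
        comparison; defaults to 1 s worth of frames.  0 disables smoothing.
    merge_gap : int
        Sub-threshold gaps of at most this many frames between two runs are
        bridged before the duration filter (debouncing), so a single noisy
        frame cannot split one oscillation in two.  0 disables merging.
    deviation_mode : {"std", "sem", "mad"}
        How the deviation is computed: sample standard deviation (default),
        standard error of the mean, or scaled median absolute deviation.

    Returns
    -------
    list of CalciumEvent, disjoint and time-ordered.  A constant trace has
    zero deviation and yields no events (the comparison is strict).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or len(trace) < 3:
        raise ValueError("trace must be 1-D with at least 3 frames")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    if not threshold_multiplier > 0:
        raise ValueError("threshold_multiplier must be positive")
    if not frame_rate > 0:
        raise ValueError("frame_rate must be positive")
    if min_duration is None:
        min_duration = max(3, int(round(DEFAULT_MIN_DURATION_S * frame_rate)))
    if smooth_window is None:
        smooth_window = int(round(DEFAULT_SMOOTH_S * frame_rate))

    deviation = _deviation(trace, deviation_mode)
    if deviation == 0.0:  # constant trace: no events by definition
        return []
    threshold = trace.mean() + threshold_multiplier * deviation

    if smooth_window and smooth_window > 1:
        kernel = np.full(smooth_window, 1.0 / smooth_window)
        smoothed = np.convolve(trace, kernel, mode="same")
    else:
        smoothed = trace

    runs = _runs(smoothed > threshold)
    if merge_gap > 0 and len(runs) > 1:
        merged = [runs[0]]
        for first, last in runs[1:]:
            if first - merged[-1][1] - 1 <= merge_gap:
                merged[-1] = (merged[-1][0], last)
            else:
                merged.append((first, last))
        runs = merged

    events = []
    for first, last in runs:
        if last - first + 1 < min_duration:
            continue
        events.append(CalciumEvent(
            cell_id=cell_id,
            t_start=first / frame_rate,
            t_end=(last + 1) / frame_rate,
            peak_amplitude=float(trace[first:last + 1].max()),
        ))
    return events


def detect_all_events(traces, **kwargs) -> dict[int, list[CalciumEvent]]:
    """Run :func:`detect_events` over every cell of a TraceMatrix."""
    return {
        cid: detect_events(traces.values[:, col], traces.frame_rate,
                           cell_id=cid, **kwargs)
        for col, cid in enumerate(traces.cell_ids)
    }


def summarize_activity(events: dict[int, list[CalciumEvent]],
                       n_cells: int, duration_min: float) -> ActivitySummary:
    """Aggregate per-cell event lists into recording-level parameters.

    share_active = 100 x (cells with >= 1 event) / n_cells;
    mean_frequency = mean over active cells of events per minute;
    mean_duration = mean over all events of (t_end - t_start).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if not duration_min > 0:
        raise ValueError("duration must be positive")
    counts = {cid: len(evs) for cid, evs in events.items()}
    active = [cid for cid, c in counts.items() if c > 0]
    share = 100.0 * len(active) / n_cells
    if active:
        freq = float(np.mean([counts[cid] / duration_min for cid in active]))
        durs = [ev.duration for evs in events.values() for ev in evs]
        dur = float(np.mean(durs))
    else:
        freq = None
        dur = None
    return ActivitySummary(share_active=share, mean_frequency=freq,
                           mean_duration=dur, per_cell_counts=counts)
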