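"""Whole-frame activity-event segmentation for calcium movies.

The movie is treated as a single spatio-temporal volume: a pixel-frame is
*active* when its intensity exceeds that pixel's own temporal mean by a
multiple of its temporal standard deviation, active voxels are grouped into
26-connected components, and each component ("event") is split into
individual cell regions by watershed on its maximum-intensity projection.
Per-cell characteristics are then read off the movie: C, the mean intensity
over the cell region per frame, and A, the number of the region's pixels
active in each frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.segmentation import watershed


@dataclass
class ActivityMovie:
    """A frames x height x width grayscale intensity stack."""

    frames: np.ndarray
    frame_rate: float
    um_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (t, y, x) array")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class SpatioTemporalEvent:
    """One connected blob of active voxels, optionally split into cells.

    ``voxels`` is an (n, 3) integer array of (frame, row, col) coordinates,
    26-connected in (t, y, x).  After :func:`split_event_by_cells`,
    ``cell_regions`` holds disjoint voxel subsets whose union is ``voxels``.
    """

    voxels: np.ndarray
    cell_regions: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.size == 0:
            raise ValueError("an event must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def t_range(self) -> tuple[int, int]:
        """First and last frame touched by the event (inclusive)."""
        return int(self.voxels[:, 0].min()), int(self.voxels[:, 0].max())

    def spatial_footprint(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean (h, w) mask of pixels the event ever occupies."""
        mask = np.zeros(shape, dtype=bool)
        mask[self.voxels[:, 1], self.voxels[:, 2]] = True
        return mask


@dataclass
class CellSignalPair:
    """Per-cell characteristics extracted from the movie.

    C is the per-frame mean intensity over the cell-region pixels; A is the
    per-frame count of the region's active pixels (zero outside events).
    """

    cell_id: int
    C: np.ndarray
    A: np.ndarray
    centroid: tuple[float, float] | None = None  # (row, col), px


def active_mask(movie: ActivityMovie, pixel_threshold_multiplier: float = 1.5
                ) -> np.ndarray:
    """Boolean (t, y, x) mask of significantly active pixel-frames.

    A pixel-frame is active when its intensity exceeds the pixel's temporal
    mean plus ``pixel_threshold_multiplier`` temporal standard deviations.
    Constant pixels (zero SD) are never active: the comparison is strict.
    """
    mean = movie.frames.mean(axis=0)
    sd = movie.frames.std(axis=0)
    return movie.frames > mean + pixel_threshold_multiplier * sd


def find_activity_events(movie: ActivityMovie,
                         pixel_threshold_multiplier: float = 1.5,
                         min_voxels: int = 20) -> list[SpatioTemporalEvent]:
    """Find connected spatio-temporal areas of significant activity.

    Active voxels are grouped by 26-connectivity in (t, y, x); components
    with fewer than ``min_voxels`` voxels are discarded.  An all-constant
    movie yields an empty list.  Events are returned ordered by their first
    (frame, row, col) voxel, so output order is deterministic.
    """
    if movie.frames.size == 0:
        raise ValueError("movie is empty")
    mask = active_mask(movie, pixel_threshold_multiplier)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    events = []
    objects = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        local = np.argwhere(labels[sl] == lab)
        if len(local) < min_voxels:
            continue
        offs = np.array([s.start for s in sl])
        events.append(SpatioTemporalEvent(voxels=local + offs))
    events.sort(key=lambda e: tuple(e.voxels[0]))
    return events


def split_event_by_cells(event: SpatioTemporalEvent,
                         frame_projection: np.ndarray,
                         smoothing_sigma: float = 2.0,
                         min_seed_distance: int = 5) -> list[np.ndarray]:
    """Split one event into per-cell voxel subsets by watershed.

    The event's maximum-intensity spatial projection is smoothed with a
    Gaussian (``smoothing_sigma`` px) and regional maxima at least
    ``min_seed_distance`` px apart seed a watershed restricted to the event's
    spatial footprint.  Every voxel is assigned to exactly one region; a
    single-maximum event is returned unsplit.  Also stored on
    ``event.cell_regions``.
    """
    proj = np.asarray(frame_projection, dtype=float)
    footprint = event.spatial_footprint(proj.shape)
    smoothed = gaussian(proj, sigma=smoothing_sigma, preserve_range=True)
    peaks = peak_local_max(smoothed, min_distance=min_seed_distance,
                           labels=footprint, exclude_border=False)
    if len(peaks) <= 1:
        event.cell_regions = [event.voxels.copy()]
        return event.cell_regions
    markers = np.zeros(proj.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-smoothed, markers=markers, mask=footprint)
    regions = []
    vox_labels = labels[event.voxels[:, 1], event.voxels[:, 2]]
    for lab in range(1, len(peaks) + 1):
        sub = event.voxels[vox_labels == lab]
        if len(sub):
            regions.append(sub)
    # watershed covers the whole footprint, so no voxel can be unlabeled;
    # guard anyway so the partition property cannot silently break
    assigned = sum(len(r) for r in regions)
    unassigned = event.voxels[vox_labels == 0]
    if len(unassigned):
        regions.append(unassigned)
        assigned += len(unassigned)
    assert assigned == event.n_voxels
    event.cell_regions = regions
    return regions


def max_projection(movie: ActivityMovie, event: SpatioTemporalEvent) -> np.ndarray:
    """Maximum-intensity projection of the movie over the event's frame span."""
    t0, t1 = event.t_range
    return movie.frames[t0:t1 + 1].max(axis=0)


def segment_movie(movie: ActivityMovie,
                  pixel_threshold_multiplier: float = 1.5,
                  min_voxels: int = 20,
                  smoothing_sigma: float = 2.0,
                  min_seed_distance: int = 5) -> list[SpatioTemporalEvent]:
    """Find all activity events and split each into cell regions."""
    events = find_activity_events(movie, pixel_threshold_multiplier, min_voxels)
    for ev in events:
        split_event_by_cells(ev, max_projection(movie, ev),
                             smoothing_sigma, min_seed_distance)
    return events


def extract_cell_signals(events: list[SpatioTemporalEvent],
                         movie: ActivityMovie,
                         cell_map=None) -> list[CellSignalPair]:
    """Compute the per-cell characteristics C and A from segmented events.

    Each cell region contributes C = per-frame mean intensity over its
    pixels and A = per-frame count of its active (event) voxels; frames
    outside any event contribute A = 0.  When ``cell_map`` (a
    :class:`~calnet.types.CellMap`) is given, regions are matched to known
    centroids by nearest neighbour within one cell radius and regions of the
    same cell (e.g. from successive transients) are merged; otherwise each
    distinct region centroid becomes its own cell, numbered in order of
    appearance.
    """
    t = movie.n_frames
    groups: dict[int, dict] = {}
    next_id = 0
    for ev in events:
        regions = ev.cell_regions if ev.cell_regions else [ev.voxels]
        for reg in regions:
            rc = reg[:, 1:].mean(axis=0)  # (row, col) centroid in px
            cid = None
            if cell_map is not None:
                best, best_d = None, np.inf
                for idx, mapped in enumerate(cell_map.cell_ids):
                    mx, my = cell_map.position(mapped)
                    # cell map is in um with x=col, y=row
                    d = np.hypot(rc[0] - my / movie.um_per_pixel,
                                 rc[1] - mx / movie.um_per_pixel)
                    if d < best_d:
                        best, best_d = mapped, d
                if best is not None:
                    r_px = cell_map.radius[cell_map.cell_ids.index(best)] \
                        / movie.um_per_pixel
                    if best_d <= r_px:
                        cid = best
            if cid is None:
                # match to an existing unlabeled group within a few px
                for gid, g in groups.items():
                    if g["mapped"] is None and np.hypot(*(g["rc"] - rc)) <= 3.0:
                        cid = gid
                        break
            if cid is None:
                cid = next_id if cell_map is None else -1 - next_id
                next_id += 1
            g = groups.setdefault(cid, {"pixels": set(), "A": np.zeros(t, dtype=int),
                                        "rc": rc, "mapped": cid if cell_map is not None
                                        and cid >= 0 else None})
            g["pixels"].update(map(tuple, reg[:, 1:]))
            frames, counts = np.unique(reg[:, 0], return_counts=True)
            g["A"][frames] += counts

    out = []
    for cid in sorted(groups):
        g = groups[cid]
        px = np.array(sorted(g["pixels"]))
        c_sig = movie.frames[:, px[:, 0], px[:, 1]].mean(axis=1)
        out.append(CellSignalPair(cell_id=cid, C=c_sig, A=g["A"],
                                  centroid=tuple(np.round(g["rc"], 3))))
    return out
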