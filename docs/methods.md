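# Methods

This note documents the models and numerical choices behind `calnet`: what
each stage computes, which parameters matter and why their defaults are
what they are, what the synthetic-data generator does and does not emulate,
and the known limitations.

## 1. Calcium-event detection (`calnet.events`)

A cell's oscillation is a maximal run of frames in which the fluorescence
trace exceeds `mean(F) + k · dev(F)`, one-sided above the mean (calcium
transients are positive-going).  `dev` is the sample standard deviation of
the whole trace by default; standard error of the mean (`sem`) and a
robust scaled median absolute deviation (`mad`) are selectable.  SD is the
default because SEM shrinks with recording length, which would make
detection depend on how long one records.

Three practical guards surround the threshold rule, all standard for
seconds-long indicator transients:

* **Smoothing** (`smooth_window`, default 1 s): a moving average applied
  before the comparison.  Without it, a single noisy frame inside a
  transient splits one oscillation into two, and event counts become
  noise-dependent.  The threshold itself is always computed from the raw
  trace.
* **Gap merging** (`merge_gap`, default 2 frames): sub-threshold gaps up to
  this length between runs are bridged (debouncing).
* **Minimum duration** (`min_duration`, default 3.5 s): excursions shorter
  than a few seconds are noise crossings, not calcium oscillations.  With
  a mean+1·SD threshold, a pure-noise trace spends ~16% of frames above
  threshold; only the duration requirement separates "no events" from
  noise, and sustained multi-second noise excursions are (measurably)
  absent at these settings.

The threshold multiplier defaults to 1.0 — one unit of deviation.  A
constant trace has zero deviation and yields zero events by definition.

Summary parameters: share of working cells (% of cells with ≥ 1 event),
mean frequency over active cells (osc/min), mean duration over events (s).
When no cell is active the frequency and duration are reported as absent,
not zero.

## 2. Movie segmentation (`calnet.segmentation`)

The movie is one spatio-temporal volume.  A pixel-frame is *active* when
its intensity exceeds that pixel's temporal mean plus `k` temporal SDs
(per-pixel statistics; a global threshold would be dominated by bright
cells).  Active voxels are grouped by 26-connectivity in (t, y, x) — the
diagonal connectivity tolerates 1-frame flicker — and components smaller
than `min_voxels` (default 20) are discarded.

The pixel threshold multiplier defaults to 1.5, not higher: cells in an
active culture are bright for a substantial fraction of the recording
(duty cycle ~25% at the default event statistics), which inflates both the
temporal mean and SD; at mean+2SD the threshold would sit above the
transient plateau and nothing would be detected.

Each event is split into cell regions by watershed on its
maximum-intensity spatial projection, Gaussian-smoothed (σ = 2 px), seeded
at regional maxima at least 5 px apart and restricted to the event's
spatial footprint.  The regions partition the event exactly (asserted at
run time), so the per-frame sum of the active-pixel counts A over cells
always equals the total active voxels per frame.

Per region, C is the mean raw intensity over the region's pixels in every
frame and A the count of the region's event voxels per frame (zero outside
events).  Regions are matched to a known cell map, when given, by nearest
centroid within one cell radius; regions of the same cell from successive
transients are merged.

## 3. Network inference (`calnet.network`)

Signals are detrended by subtracting a trailing moving average over the
window `[k − w, k]`, truncated at the recording start.  The window
defaults to 3 s of frames: longer than a transient's rise (~0.9 s at the
default kernel), much shorter than slow drift, and short enough that the
correlation is carried by event onsets rather than by the plateaus.  In
development benchmarks on planted networks the 3-s window recovered edges
substantially better than a 10-s window (mean F1 0.94 vs 0.84 under the
benchmark conditions of §6); w is configurable everywhere.

The pairwise statistic is the Pearson coefficient of the detrended
signals, maximized over integer shifts τ ∈ [−W, W] with W = 10 frames.
Each shifted correlation is computed on the overlapping segment with
per-segment means, so the zero-shift value equals the plain Pearson
coefficient.  Ties in the maximum resolve to the most negative shift
(first maximum in scan order); for continuous data exact ties do not
occur.  Pairs in which either signal has zero variance are excluded from
the vertex set before enumeration, with a logged count.

Graphs: undirected mode thresholds the zero-lag coefficient; directed
mode thresholds the maximized coefficient and orients each edge by the
sign of the optimal shift (τ > 0: first cell leads).  A directed edge
requires a nonzero lag; pairs whose optimum is τ = 0 have no defined
direction and are kept in the directed graph flagged `directed=False`
(dropped under `strict_lag`).  The significance threshold defaults to
ρ_thr = 0.3.  Correlation can be computed on either cell characteristic
(C or A); both give a network, and headline metrics use C.

## 4. Network metrics (`calnet.metrics`)

For a graph over n cells: N_c = |E|; N_n = mean incident-edge count
(direction ignored; the handshake identity N_n = 2N_c/n is asserted on
every run); S = mean over edges with τ ≠ 0 of d_ij/|τ_ij| in µm/frame
(µm/s when the frame rate is known) — zero-lag edges cannot define a speed
and are excluded with a logged count; P = mean ρ̆ over all defined pairs;
P_a = the same mean over spatially adjacent pairs; and
pct_max = 100 · N_c / (n(n−1)/2), the share of the all-to-all maximum,
counted over unordered pairs.

Adjacency is a property of the cell map, not of the graph: pair (i, j) is
adjacent when the centroid distance is at most `contact_slack · (r_i +
r_j)` with a default slack of 1.2, since "somata in contact" is a visual
criterion and centroids/radii carry estimation error.  P_a averages
correlations of adjacent *pairs*, whether or not they pass the edge
threshold.

## 5. MEA network bursts (`calnet.bursts`)

All spikes are pooled into one train (sorted by time, ties by electrode id
for determinism).  The train is cut wherever a consecutive gap exceeds
`max_gap` (100 ms); each maximal run spanning at least `min_electrodes`
(4) distinct electrodes — distinctness counted over the whole run, not per
gap — is one network burst.  Runs are maximal, so detected bursts are
non-overlapping, time-ordered, and no two could merge without violating
the gap rule; raising `max_gap` can only merge runs, never split them.
Burst statistics are normalized to a 10-minute record.  The activation
pattern of a burst is each participating electrode's first-spike latency
from burst start, exported in electrode order for raster/colour-map
rendering against the array layout.

## 6. The synthetic-data generator (`calnet.synthetic`)

Defaults describe a healthy 21-DIV hippocampal culture: 45 cells in a
1 × 1 mm field (4500 cells/cm²), soma radii 6–9 µm, 10 minutes at
5 frames/s, calcium transients of 12 s at 1.34 per minute in 60% of cells,
transient amplitude 10× the Gaussian noise SD; a 60-electrode (8×8 minus
corners) MEA with 36 planted network bursts of ~90 spikes per 10 minutes
over a sparse asynchronous background (0.02 spikes/s/electrode).  One root
seed feeds named child streams (placement, events, coupling, noise,
spikes), so identical configurations are bit-reproducible and enabling one
output does not perturb another.

**Transient kernel.** A linear rise over 7% of the nominal duration, a
shallow exponential decay to 95% of peak over the rest, and a return to
baseline at the end of the support.  The kernel is deliberately
plateau-like: the nominal `transient_duration` is defined as the width of
the transient at detection-threshold level, so durations measured by the
event detector track the parameter.  Real indicator transients decay
exponentially to baseline; against such data the detector reports the
width above threshold, which is shorter than the full transient.

**Event timing.** Candidate event starts form a Poisson process thinned by
a dead time of one transient plus a 4-s refractory gap, with the candidate
intensity raised by the non-paralyzable dead-time correction
λ′ = r/(1 − r·dead) so the accepted rate equals the nominal
`transient_rate`.  Planted events therefore never overlap within a cell
and the realized rate matches the nominal one.

**Coupling.** A planted edge (i → j, lag τ, p, gain) copies each intrinsic
event of i into j, shifted by τ frames, with probability p and amplitude
scaled by gain.  Copies are made of intrinsic events only — couplings do
not cascade along chains.  Copies whose shifted support would leave the
recording are dropped.

**Planted-network benchmark design.** `plant_random_network` samples
topologies under identifiability constraints and calibrates per-edge gains
so that *every planted edge carries the same pairwise correlation*
(default 0.45) regardless of the target's in-degree
(gain = s/√(1 − d·s²) for in-degree d, capped at 3).  Sources and targets
are disjoint and two targets share at most one source, which bounds the
correlation of any non-edge pair by s² ≈ 0.2 (a shared-driver fork).
These constraints are what make planted adjacency recoverable by *any*
pairwise-correlation method: without them, common drivers induce genuine
super-threshold correlations between non-edges and multi-input targets
dilute true edges below threshold, and a recovery benchmark would measure
the topology sampler rather than the estimator.  Real cultures are under
no such constraint — recovered networks on real data describe functional
correlation structure, not a ground-truth synaptic wiring.

**Cell placement.** Hard-disc rejection sampling, uniform over the field.
Pure hard-disc packing forbids soma contact, so `cluster_fraction` places
that share of cells just touching an earlier cell (cultured neurons
aggregate); this is what gives the neighbor-correlation statistic a
non-trivial pair set.

**What is not emulated.** Indicator photobleaching, motion, cell-type
(neuron vs astrocyte) differences in kinetics, distance-dependent coupling
probability, biophysical calcium dynamics, spike waveforms.  Passing tests
demonstrate correctness of the analysis pipeline on data with known
structure, not performance on real recordings.

## 7. Problem sizes and determinism

The test-suite and acceptance-script problem sizes are chosen so each
check isolates one property at the scale where its statistics are stable:
200 cells × 10 min for detection statistics, 30 cells × 40 edges × 10
seeds for network recovery, 20 small movies for segmentation
conservation, 20 planted bursts for detection, full-pipeline runs on
15-cell recordings for determinism.  All analysis outputs (metrics and
summary JSON) are written with sorted keys and no timestamps, so two runs
from one seed are byte-identical; provenance records (tool version, config
hash, input checksums) live in separate files.

## 8. Known limitations

* The event detector's mean+k·SD threshold is computed per trace, so very
  active cells have elevated thresholds; measured durations shrink
  slightly as activity rises.
* Zero-lag pairs carry no direction; under the default settings they stay
  in the directed graph as undirected edges and are excluded from the
  speed average.
* The watershed split is seeded from one spatial projection per event;
  two cells that only ever fire simultaneously and overlap heavily in
  space can merge into one region.
* Pooled-train burst detection has no rate criterion beyond the gap rule;
  at high asynchronous background rates chance runs qualify as bursts.
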