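# calnet

Functional network analysis of neuron–glial activity in dissociated
cultures: calcium-event detection on fluorescence traces, watershed
segmentation of activity movies, directed network reconstruction by
lag-maximized cross-correlation, network summary statistics, and
network-burst detection in multi-electrode-array (MEA) spike trains.

The package is aimed at labs that record spontaneous activity of primary
neuronal cultures with a calcium indicator (per-cell fluorescence traces
F(t) or full image stacks) and/or extracellular MEA electrodes, and want to
quantify how the *collective* activity — the functional architecture of the
neuron-glial network — changes under an intervention (ischemic factors,
pharmacological protection, development).  Because such recordings are
rarely shareable, a synthetic-data generator with planted ground truth
(event times, directed couplings with frame lags, network bursts) is a
first-class part of the package: every analysis stage is validated against
what was planted.

## The model

**Calcium events.** For each cell, an oscillation is a maximal run of
frames with F(t) above `mean(F) + k·SD(F)` (one SD by default, lightly
smoothed), bounded by the threshold crossings T_start and T_end.  A
recording is summarized by the share of working cells, the event frequency
(osc/min over active cells), and the event duration (s).

**Functional network.** Per-cell signals x_i (the cell characteristic C —
mean calcium intensity — or A — active-pixel count) are detrended by a
trailing moving average with window w:

    x̆_i[k] = x_i[k] − ⟨x_i⟩_{[k−w, k]}

For every cell pair the Pearson correlation is maximized over integer
frame shifts τ ∈ [−W, W] (W = 10 frames):

    ρ̆_ij = max_τ ρ_ij(τ),   τ_ij = argmax_τ ρ_ij(τ)

A pair is functionally connected when ρ̆_ij > ρ_thr (0.3 by default); the
sign of τ_ij orients the edge (τ > 0: cell i leads).  The resulting graph
G = (V, E) is summarized by the number of connections N_c = |E|, the mean
connections per cell N_n = 2N_c/n, the mean propagation speed
S = ⟨d_ij/|τ_ij|⟩ over edges with nonzero lag, the mean correlation P over
all pairs, the mean correlation P_a over spatially adjacent pairs (somata
in contact), and N_c as a percentage of the all-to-all maximum n(n−1)/2.

**Network bursts.** Spikes from all electrodes are pooled; a small network
burst is a maximal run of spikes with consecutive gaps ≤ 100 ms spanning at
least 4 distinct electrodes.  Bursts are summarized per 10 minutes, by
spikes per burst and duration, and by their activation pattern — the
first-spike latency of each electrode from burst start.

## Worked example

```python
from calnet import (SimulationConfig, simulate_traces, detect_all_events,
                    summarize_activity, infer_network, compute_metrics,
                    score_edge_recovery)
from calnet.synthetic import plant_random_network

edges = plant_random_network(n_cells=30, n_edges=20, seed=0)
cfg = SimulationConfig(n_cells=30, n_frames=3000, frame_rate=5.0,
                       inactive_fraction=0.0, planted_edges=edges,
                       cluster_fraction=0.3, seed=0)
traces, truth = simulate_traces(cfg)

events = detect_all_events(traces)
activity = summarize_activity(events, cfg.n_cells, traces.duration_min)
print(f"active cells: {activity.share_active:.1f}%")
print(f"oscillation duration: {activity.mean_duration:.2f} s")
print(f"oscillation frequency: {activity.mean_frequency:.2f} /min")

net, pairs = infer_network(traces.values, w=15, W=10, rho_thr=0.3,
                           mode="directed", cell_map=truth.cell_map)
m = compute_metrics(net, pairs, truth.cell_map, frame_rate=cfg.frame_rate)
print(f"connections: {m.Nc} ({m.pct_max:.1f}% of maximum)")
score = score_edge_recovery(net, truth)
print(f"planted-edge recovery: F1={score['f1']:.3f}, "
      f"direction accuracy={score['lag_sign_accuracy']:.3f}")
```

prints

```
active cells: 100.0%
oscillation duration: 10.41 s
oscillation frequency: 1.32 /min
connections: 20 (4.6% of maximum)
planted-edge recovery: F1=1.000, direction accuracy=1.000
```

All 30 cells were simulated active, so the detector reports 100% working
cells; the measured duration and frequency sit at the generator's nominal
12-s / 1.34-per-minute conditions (durations shorten slightly where coupled
transients superpose).  All 20 planted directed couplings — and no spurious
ones — are recovered with the correct lead–lag direction at the 0.3
threshold, so N_c equals the planted edge count, 4.6% of the 435 possible
pairs.

The same stages are available from the shell:

```sh
calnet run --config pipeline.yaml --out results/
calnet detect-events --traces traces.csv --frame-rate 5 --out events/
calnet infer-network --signals traces.csv --frame-rate 5 --threshold 0.3 --out net/
calnet segment --movie movie.tif --frame-rate 5 --out seg/
calnet bursts --spikes spikes.csv --duration-min 10 --out bursts/
```

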