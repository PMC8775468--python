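"""Generator contracts: determinism, packing, planted events and couplings."""

import numpy as np
import pytest

from calnet import (SimulationConfig, render_movie, simulate_cell_map,
                    simulate_spikes, simulate_traces)
from calnet.synthetic import (BurstSpec, make_burst_specs,
                              plant_random_network, transient_template)
from calnet.types import CellMap, TraceMatrix


class TestCellMap:
    def test_empty_map(self):
        cfg = SimulationConfig(n_cells=0)
        assert len(simulate_cell_map(cfg)) == 0

    def test_same_seed_identical(self):
        cfg = SimulationConfig(n_cells=30, seed=7)
        m1 = simulate_cell_map(cfg)
        m2 = simulate_cell_map(cfg)
        np.testing.assert_array_equal(m1.x, m2.x)
        np.testing.assert_array_equal(m1.y, m2.y)
        np.testing.assert_array_equal(m1.radius, m2.radius)

    def test_no_overlap_brute_force(self):
        """Every pairwise centre distance exceeds the summed radii."""
        cfg = SimulationConfig(n_cells=50, field_size=(1000.0, 1000.0), seed=3)
        m = simulate_cell_map(cfg)
        for a in range(50):
            for b in range(a + 1, 50):
                d = np.hypot(m.x[a] - m.x[b], m.y[a] - m.y[b])
                assert d > m.radius[a] + m.radius[b]

    def test_cluster_fraction_creates_contacts(self):
        """Clustered placement yields soma-soma contacts that plain
        hard-disc sampling forbids."""
        from calnet import adjacency_pairs

        plain = simulate_cell_map(SimulationConfig(n_cells=40, seed=5))
        clustered = simulate_cell_map(
            SimulationConfig(n_cells=40, cluster_fraction=0.5, seed=5))
        assert len(adjacency_pairs(clustered, 1.2)) > len(
            adjacency_pairs(plain, 1.2))
        assert len(adjacency_pairs(clustered, 1.2)) >= 10
        # still non-overlapping
        for a in range(40):
            for b in range(a + 1, 40):
                d = np.hypot(clustered.x[a] - clustered.x[b],
                             clustered.y[a] - clustered.y[b])
                assert d > clustered.radius[a] + clustered.radius[b]

    def test_infeasible_packing_raises(self):
        cfg = SimulationConfig(n_cells=200, field_size=(100.0, 100.0), seed=0)
        with pytest.raises(RuntimeError, match="density"):
            simulate_cell_map(cfg)


class TestTraces:
    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(n_cells=10, n_frames=600, seed=11)
        t1, _ = simulate_traces(cfg)
        t2, _ = simulate_traces(cfg)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_noise_free_single_event_matches_template(self):
        cfg = SimulationConfig(n_cells=1, n_frames=400, noise_sd=0.0,
                               active_cells=[0], transient_rate=1.34, seed=5)
        traces, truth = simulate_traces(cfg)
        kernel = transient_template(cfg.transient_duration, cfg.frame_rate,
                                    cfg.transient_amplitude)
        (t0, _t1) = truth.event_times[0][0]
        s = int(round(t0 * cfg.frame_rate))
        np.testing.assert_allclose(traces.values[s:s + len(kernel), 0], kernel)

    def test_all_inactive_pure_noise(self):
        cfg = SimulationConfig(n_cells=5, n_frames=300, inactive_fraction=1.0,
                               noise_sd=1.0, seed=2)
        traces, truth = simulate_traces(cfg)
        assert all(not v for v in truth.event_times.values())
        assert abs(traces.values.mean()) < 0.1
        assert abs(traces.values.std() - 1.0) < 0.1

    def test_event_count_conservation(self, small_recording):
        """Ground truth lists exactly the events the generator drew."""
        cfg, traces, truth = small_recording
        kernel_sum = transient_template(cfg.transient_duration, cfg.frame_rate,
                                        cfg.transient_amplitude).sum()
        # noise-free resimulation: total intensity = n_events x kernel mass
        cfg2 = SimulationConfig(**{**cfg.__dict__, "noise_sd": 0.0})
        t2, truth2 = simulate_traces(cfg2)
        n_events = sum(len(v) for v in truth2.event_times.values())
        assert n_events > 0
        np.testing.assert_allclose(t2.values.sum(), n_events * kernel_sum)

    def test_planted_lagged_copy_exact(self):
        """With p=1 and zero noise the target is a lagged copy of the source."""
        lag = 3
        cfg = SimulationConfig(n_cells=2, n_frames=500, noise_sd=0.0,
                               active_cells=[0],
                               planted_edges=[(0, 1, lag, 1.0)], seed=9)
        traces, truth = simulate_traces(cfg)
        src, dst = traces.values[:, 0], traces.values[:, 1]
        np.testing.assert_allclose(dst[lag:], src[:-lag])
        # exhaustive cross-correlation scan finds the planted lag
        best = max(range(-10, 11),
                   key=lambda t: np.corrcoef(src[max(0, -t):500 - max(t, 0)],
                                             dst[max(t, 0):500 + min(t, 0)])[0, 1]
                   if 500 - abs(t) > 2 else -2)
        assert best == lag

    def test_lag_exceeding_recording_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            SimulationConfig(n_cells=2, n_frames=100,
                             planted_edges=[(0, 1, 100, 1.0)])

    def test_events_non_overlapping_within_recording(self, small_recording):
        cfg, traces, truth = small_recording
        horizon = traces.n_frames / traces.frame_rate
        for evs in truth.event_times.values():
            for (a0, a1), (b0, b1) in zip(evs, evs[1:]):
                assert a1 <= b0
            for (t0, t1) in evs:
                assert 0 <= t0 < t1 <= horizon


class TestPlantRandomNetwork:
    def test_constraints_hold(self):
        edges = plant_random_network(30, 40, seed=1)
        assert len(edges) == 40
        sources = {}
        pairs = set()
        for s, d, lag, p, gain in edges:
            assert s != d and 1 <= lag <= 8 and p == 1.0 and gain > 0
            pairs.add((s, d))
            sources.setdefault(d, set()).add(s)
        assert len(pairs) == 40
        src_nodes = {s for s, *_ in edges}
        assert not src_nodes & set(sources)  # bipartite
        assert max(len(v) for v in sources.values()) <= 3
        targets = list(sources)
        for a in range(len(targets)):
            for b in range(a + 1, len(targets)):
                assert len(sources[targets[a]] & sources[targets[b]]) <= 1

    def test_infeasible_density_raises(self):
        with pytest.raises(ValueError):
            plant_random_network(6, 40, seed=0)


class TestRenderMovie:
    def _map2(self):
        return CellMap(cell_ids=[0, 1], x=np.array([40.0, 60.0]),
                       y=np.array([50.0, 50.0]), radius=np.array([12.0, 12.0]))

    def test_zero_traces_zero_frames(self):
        traces = TraceMatrix(values=np.zeros((5, 2)), frame_rate=5.0)
        movie = render_movie(traces, self._map2(), (50, 50), um_per_pixel=2.0)
        assert movie.frames.sum() == 0

    def test_constant_disc_mean(self):
        cm = CellMap(cell_ids=[0], x=np.array([50.0]), y=np.array([50.0]),
                     radius=np.array([16.0]))
        traces = TraceMatrix(values=np.full((4, 1), 7.0), frame_rate=5.0)
        movie = render_movie(traces, cm, (50, 50), um_per_pixel=2.0)
        disc = movie.frames[0] > 0
        for frame in movie.frames:
            assert frame[disc].mean() == pytest.approx(7.0)

    def test_overlapping_cells_sum_per_pixel(self):
        """Intensity of overlapping discs equals the per-pixel oracle sum."""
        cm = self._map2()
        traces = TraceMatrix(values=np.array([[2.0, 5.0]]), frame_rate=5.0)
        movie = render_movie(traces, cm, (50, 50), um_per_pixel=2.0)
        yy, xx = np.mgrid[0:50, 0:50]
        expected = np.zeros((50, 50))
        for idx in range(2):
            mask = ((xx - cm.x[idx] / 2.0) ** 2 + (yy - cm.y[idx] / 2.0) ** 2
                    <= (cm.radius[idx] / 2.0) ** 2)
            expected += mask * traces.values[0, idx]
        np.testing.assert_allclose(movie.frames[0], expected)

    def test_cell_outside_bounds_rejected(self):
        traces = TraceMatrix(values=np.zeros((2, 2)), frame_rate=5.0)
        with pytest.raises(ValueError, match="bounds"):
            render_movie(traces, self._map2(), (20, 20), um_per_pixel=2.0)


class TestSimulateSpikes:
    def test_empty(self):
        table, planted = simulate_spikes(60, 10.0, [], background_rate=0.0)
        assert len(table) == 0 and planted == []

    def test_planted_burst_within_span(self):
        spec = BurstSpec(start_ms=1000.0, electrodes=list(range(6)),
                         spikes_per_electrode=3, jitter_ms=2.0)
        table, planted = simulate_spikes(60, 1.0, [spec], seed=4)
        b = planted[0]
        assert np.all((table.time_ms >= b.start_ms) & (table.time_ms <= b.end_ms))
        assert b.electrodes == list(range(6))

    def test_gap_contract_violation_rejected(self):
        spec = BurstSpec(start_ms=0.0, electrodes=[0, 1, 2, 3],
                         propagation_ms=60.0, jitter_ms=30.0)
        with pytest.raises(ValueError, match="gap"):
            simulate_spikes(60, 1.0, [spec])

    def test_determinism(self):
        specs = make_burst_specs(5, 2.0, 60, seed=8)
        t1, _ = simulate_spikes(60, 2.0, specs, background_rate=0.5, seed=8)
        t2, _ = simulate_spikes(60, 2.0, specs, background_rate=0.5, seed=8)
        np.testing.assert_array_equal(t1.time_ms, t2.time_ms)
        np.testing.assert_array_equal(t1.electrode, t2.electrode)
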