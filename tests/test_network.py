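"""Detrending, correlation, lag maximization and graph construction,
checked against independent naive-loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from calnet import (SimulationConfig, build_network, detrend, infer_network,
                    lagged_max_correlation, pearson, score_edge_recovery,
                    simulate_traces)
from calnet.network import CorrelationResult, correlate_pairs

# ---------------------------------------------------------------------------
# independent oracles (naive loops, no shared code with the implementation)


def detrend_oracle(x, w):
    out = np.empty(len(x))
    for k in range(len(x)):
        lo = max(k - w, 0)
        acc = 0.0
        for i in range(lo, k + 1):
            acc += x[i]
        out[k] = x[k] - acc / (k + 1 - lo)
    return out


def pearson_oracle(a, b):
    am, bm = sum(a) / len(a), sum(b) / len(b)
    num = sum((x - am) * (y - bm) for x, y in zip(a, b))
    da = sum((x - am) ** 2 for x in a) ** 0.5
    db = sum((y - bm) ** 2 for y in b) ** 0.5
    if da == 0 or db == 0:
        return float("nan")
    return num / (da * db)


def lag_scan_oracle(a, b, W):
    n = len(a)
    best = (-2.0, 0)
    for tau in range(-W, W + 1):
        if tau >= 0:
            seg_a, seg_b = a[:n - tau], b[tau:]
        else:
            seg_a, seg_b = a[-tau:], b[:n + tau]
        if len(seg_a) < 3:
            continue
        r = pearson_oracle(list(seg_a), list(seg_b))
        if not np.isnan(r) and r > best[0]:
            best = (r, tau)
    return best


class TestDetrend:
    def test_constant_series_all_zero(self):
        np.testing.assert_allclose(detrend(np.full(50, 4.2), 5).values,
                                   np.zeros(50), atol=1e-12)

    def test_hand_computed_example(self):
        np.testing.assert_allclose(detrend(np.array([1.0, 2.0, 3.0]), 1).values,
                                   [0.0, 0.5, 0.5])

    def test_matches_naive_loop(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            w = int(rng.integers(1, n - 1))
            x = rng.normal(size=n)
            np.testing.assert_allclose(detrend(x, w).values,
                                       detrend_oracle(x, w), atol=1e-12)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            detrend(np.arange(10.0), 0)
        with pytest.raises(ValueError):
            detrend(np.arange(5.0), 10)
        with pytest.raises(ValueError, match="finite"):
            detrend(np.array([1.0, np.inf, 2.0, 1.0]), 1)


class TestPearson:
    def test_identical_signals(self, rng):
        x = rng.normal(size=100)
        assert pearson(x, x) == pytest.approx(1.0)

    def test_negated_signals(self, rng):
        x = rng.normal(size=100)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 80))
            assert pearson(a, b) == pytest.approx(pearson_oracle(a, b),
                                                  abs=1e-12)

    def test_zero_variance_is_nan(self, rng):
        assert np.isnan(pearson(np.ones(10), rng.normal(size=10)))

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(2, 60))
        assert pearson(a, b) == pearson(b, a)


class TestLaggedMaxCorrelation:
    def test_w_zero_reduces_to_pearson(self, rng):
        a, b = rng.normal(size=(2, 100))
        rho, tau = lagged_max_correlation(a, b, 0)
        assert tau == 0
        assert rho == pytest.approx(pearson(a, b))

    def test_exact_shift_recovered(self, rng):
        x = np.convolve(rng.normal(size=300), np.ones(8) / 8, mode="same")
        y = np.zeros_like(x)
        y[3:] = x[:-3]
        rho, tau = lagged_max_correlation(x[20:280], y[20:280], 10)
        assert tau == 3
        assert rho > 0.999

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 120))
            rho, tau = lagged_max_correlation(a, b, 10)
            rho_o, tau_o = lag_scan_oracle(a, b, 10)
            assert rho == pytest.approx(rho_o, abs=1e-10)
            assert tau == tau_o

    def test_antisymmetry(self, rng):
        """Swapping the pair preserves rho_max and negates tau."""
        for _ in range(10):
            a, b = rng.normal(size=(2, 150))
            r1, t1 = lagged_max_correlation(a, b, 8)
            r2, t2 = lagged_max_correlation(b, a, 8)
            assert r1 == pytest.approx(r2, abs=1e-12)
            assert t1 == -t2

    def test_rho_max_at_least_zero_lag_rho(self, rng):
        a, b = rng.normal(size=(2, 100))
        rho, _ = lagged_max_correlation(a, b, 10)
        assert rho >= pearson(a, b) - 1e-12


@settings(max_examples=30, deadline=None)
@given(arrays(np.float64, (2, 64),
              elements=st.floats(-100, 100, allow_nan=False)))
def test_lagged_correlation_oracle_property(pair):
    """Exhaustive-scan oracle equivalence on arbitrary bounded signals."""
    a, b = pair
    if np.std(a[:54]) == 0 or np.std(b[:54]) == 0:  # degenerate overlaps
        return
    try:
        rho, tau = lagged_max_correlation(a, b, 5)
    except ValueError:
        return
    rho_o, tau_o = lag_scan_oracle(a, b, 5)
    if np.isnan(rho):
        return
    assert rho == pytest.approx(rho_o, abs=1e-9)


class TestBuildNetwork:
    def _pairs(self, rhos):
        return [CorrelationResult(i=i, j=j, rho=r, rho_max=r, tau=t)
                for (i, j, r, t) in rhos]

    def test_all_below_threshold_edgeless(self):
        net = build_network(self._pairs([(0, 1, 0.1, 2), (1, 2, 0.2, 1)]),
                            rho_thr=0.3)
        assert net.n_edges == 0

    def test_complete_triangle(self):
        pairs = self._pairs([(0, 1, 0.9, 0), (0, 2, 0.9, 0), (1, 2, 0.9, 0)])
        net = build_network(pairs, rho_thr=0.3, mode="undirected")
        assert net.n_edges == 3 and net.n_cells == 3

    def test_direction_follows_lag_sign(self):
        pairs = self._pairs([(0, 1, 0.8, 3), (2, 3, 0.8, -2)])
        net = build_network(pairs, rho_thr=0.3, mode="directed")
        assert net.graph.has_edge(0, 1) and not net.graph.has_edge(1, 0)
        assert net.graph.has_edge(3, 2) and not net.graph.has_edge(2, 3)
        assert net.graph[3][2]["tau"] == 2

    def test_zero_lag_kept_unless_strict(self):
        pairs = self._pairs([(0, 1, 0.8, 0)])
        keep = build_network(pairs, rho_thr=0.3, mode="directed")
        drop = build_network(pairs, rho_thr=0.3, mode="directed",
                             strict_lag=True)
        assert keep.n_edges == 1 and not keep.graph[0][1]["directed"]
        assert drop.n_edges == 0

    def test_threshold_monotonicity(self, rng):
        rhos = [(i, j, float(rng.uniform(0, 1)), int(rng.integers(-5, 6)))
                for i in range(8) for j in range(i + 1, 8)]
        pairs = self._pairs(rhos)
        edges = {}
        for thr in (0.3, 0.5, 0.7):
            net = build_network(pairs, rho_thr=thr, mode="undirected")
            edges[thr] = {frozenset(e) for e in net.graph.edges()}
        assert edges[0.7] <= edges[0.5] <= edges[0.3]

    def test_zero_variance_cells_excluded(self, rng):
        sig = rng.normal(size=(200, 3))
        sig[:, 1] = 5.0  # constant cell
        pairs = correlate_pairs(sig, w=10, W=5)
        cells = {c for p in pairs for c in (p.i, p.j)}
        assert 1 not in cells and cells == {0, 2}


class TestPlantedRecovery:
    def test_noise_free_matching_recovered_exactly(self):
        """A 30-cell planted matching (noise-free, p=1) is recovered with
        every directed edge and lag sign correct."""
        edges = [(2 * k, 2 * k + 1, 1 + (k % 8), 1.0) for k in range(15)]
        cfg = SimulationConfig(n_cells=30, n_frames=3000, noise_sd=0.0,
                               inactive_fraction=0.0, planted_edges=edges,
                               field_size=(1500.0, 1500.0), seed=13)
        traces, truth = simulate_traces(cfg)
        net, _ = infer_network(traces.values, w=15, W=10, rho_thr=0.3,
                               mode="directed")
        score = score_edge_recovery(net, truth)
        assert score["f1"] == 1.0
        assert score["lag_sign_accuracy"] == 1.0

    def test_recovery_f1_with_noise(self):
        """Planted networks at SNR 10 are recovered with F1 >= 0.9."""
        from calnet.synthetic import plant_random_network

        f1 = []
        for seed in range(3):
            edges = plant_random_network(30, 40, seed=200 + seed)
            cfg = SimulationConfig(n_cells=30, n_frames=3000,
                                   inactive_fraction=0.0, planted_edges=edges,
                                   field_size=(1500.0, 1500.0), seed=seed)
            traces, truth = simulate_traces(cfg)
            net, _ = infer_network(traces.values, w=15, W=10, rho_thr=0.3,
                                   mode="directed")
            f1.append(score_edge_recovery(net, truth)["f1"])
        assert np.mean(f1) >= 0.9
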