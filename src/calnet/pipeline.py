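"""End-to-end orchestration: simulate -> detect -> (segment) -> infer ->
metrics -> bursts, with per-stage artifacts and provenance.

Given the same configuration (including the seed) a pipeline run is
idempotent: analysis outputs (metrics.json, summary.json, tables) are
byte-identical between runs.  Provenance records are written separately so
that timestamps never leak into comparable outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import bursts as bursts_mod
from . import io as cio
from . import segmentation as seg
from .config import PipelineConfig
from .events import detect_all_events, summarize_activity
from .metrics import compute_metrics
from .network import FunctionalNetwork, infer_network
from .synthetic import (GroundTruth, SimulationConfig, make_burst_specs,
                        render_movie, simulate_spikes, simulate_traces)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def score_edge_recovery(network: FunctionalNetwork,
                        truth: GroundTruth) -> dict:
    """Compare a reconstructed network with the planted one.

    Edge identity is scored on unordered pairs (F1, precision, recall);
    direction is scored separately as the fraction of recovered true pairs
    whose edge orientation matches the planted source -> target direction
    (a recovered zero-lag, undirected edge counts as a miss).
    """
    true_pairs = {frozenset((s, d)): (s, d) for s, d, _, _ in truth.edges}
    rec = {}
    for u, v, attrs in network.graph.edges(data=True):
        rec[frozenset((u, v))] = (u, v, bool(attrs.get("directed", True)))
    tp_keys = set(true_pairs) & set(rec)
    tp, fp, fn = len(tp_keys), len(set(rec) - set(true_pairs)), \
        len(set(true_pairs) - set(rec))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) else 0.0
    correct_sign = sum(
        1 for k in tp_keys
        if rec[k][2] and (rec[k][0], rec[k][1]) == true_pairs[k]
    )
    sign_acc = correct_sign / tp if tp else 0.0
    return {"f1": f1, "precision": precision, "recall": recall,
            "lag_sign_accuracy": sign_acc, "tp": tp, "fp": fp, "fn": fn}


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every configured stage, writing artifacts under ``out_dir``.

    Returns the summary dictionary (also written to ``summary.json``).
    Any stage failure raises :class:`StageError` naming the stage.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # --- simulate -----------------------------------------------------
    try:
        sim = config.simulate
        sim_config = SimulationConfig(
            n_cells=sim.n_cells, field_size=tuple(sim.field_size),
            frame_rate=config.frame_rate, n_frames=sim.n_frames,
            transient_rate=sim.transient_rate,
            transient_duration=sim.transient_duration,
            transient_amplitude=sim.transient_amplitude,
            noise_sd=sim.noise_sd,
            planted_edges=[tuple(e) for e in sim.planted_edges],
            inactive_fraction=sim.inactive_fraction, seed=config.seed)
        traces, truth = simulate_traces(sim_config)
        cio.write_traces_csv(traces, out / "traces.csv")
        cio.write_cell_map_csv(truth.cell_map, out / "cell_map.csv")
        cio.write_json({
            "edges": [list(e) for e in truth.edges],
            "event_times": {str(c): v for c, v in truth.event_times.items()},
        }, out / "ground_truth.json")
        cio.write_json(cio.provenance_record("simulate", sim_config.__dict__
                                             | {"field_size": list(sim_config.field_size),
                                                "planted_edges": [list(e) for e in
                                                                  sim_config.planted_edges]}),
                       out / "simulate.provenance.json")
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        raise StageError("simulate", exc) from exc

    # --- detect-events ------------------------------------------------
    try:
        det = config.detect
        events = detect_all_events(
            traces,
            threshold_multiplier=det.threshold_multiplier,
            min_duration=max(3, int(round(det.min_duration_s * config.frame_rate))),
            smooth_window=int(round(det.smooth_s * config.frame_rate)),
            deviation_mode=det.deviation_mode)
        activity = summarize_activity(events, traces.n_cells,
                                      traces.duration_min)
        cio.events_to_frame(events).to_csv(out / "events.csv", index=False)
        summary["activity"] = {
            "share_active_pct": activity.share_active,
            "mean_frequency_per_min": activity.mean_frequency,
            "mean_duration_s": activity.mean_duration,
        }
    except Exception as exc:
        raise StageError("detect-events", exc) from exc

    # --- segment (optional) -------------------------------------------
    if config.segment.enabled:
        try:
            shape = tuple(config.segment.image_shape)
            movie = render_movie(traces, truth.cell_map, shape,
                                 um_per_pixel=config.um_per_pixel)
            cio.write_movie_tiff(movie, out / "movie.tif")
            st_events = seg.segment_movie(
                movie,
                pixel_threshold_multiplier=config.segment.pixel_threshold_multiplier,
                min_voxels=config.segment.min_voxels,
                smoothing_sigma=config.segment.smoothing_sigma,
                min_seed_distance=config.segment.min_seed_distance)
            signals = seg.extract_cell_signals(st_events, movie,
                                               cell_map=truth.cell_map)
            cio.signals_to_frame(signals).to_csv(out / "cell_signals.csv",
                                                 index=False)
            summary["segmentation"] = {"n_events": len(st_events),
                                       "n_cells_detected": len(signals)}
        except Exception as exc:
            raise StageError("segment", exc) from exc

    # --- infer-network ------------------------------------------------
    try:
        netcfg = config.network
        w = max(1, int(round(netcfg.detrend_s * config.frame_rate)))
        network, pairs = infer_network(
            traces.values, cell_ids=traces.cell_ids, w=w,
            W=netcfg.lag_range, rho_thr=netcfg.rho_thr, mode=netcfg.mode,
            cell_map=truth.cell_map, strict_lag=netcfg.strict_lag)
        cio.edge_list_frame(network).to_csv(out / "edges.csv", index=False)
        cio.write_network_graphml(network, out / "network.graphml")
        cio.write_json(cio.provenance_record(
            "infer-network", {"w": w, "W": netcfg.lag_range,
                              "rho_thr": netcfg.rho_thr, "mode": netcfg.mode,
                              "strict_lag": netcfg.strict_lag}),
            out / "network.provenance.json")
        if truth.edges:
            summary["edge_recovery"] = score_edge_recovery(network, truth)
    except Exception as exc:
        raise StageError("infer-network", exc) from exc

    # --- metrics ------------------------------------------------------
    try:
        net_metrics = compute_metrics(network, pairs, truth.cell_map,
                                      frame_rate=config.frame_rate,
                                      contact_slack=config.metrics.contact_slack)
        cio.write_json(net_metrics.as_dict(), out / "metrics.json")
        summary["network"] = net_metrics.as_dict()
    except Exception as exc:
        raise StageError("metrics", exc) from exc

    # --- bursts (optional MEA branch) ----------------------------------
    if config.mea.enabled:
        try:
            mea = config.mea
            specs = make_burst_specs(
                mea.n_bursts, mea.duration_min, mea.n_electrodes,
                electrodes_per_burst=mea.electrodes_per_burst,
                spikes_per_electrode=mea.spikes_per_electrode,
                jitter_ms=mea.jitter_ms, seed=config.seed)
            spikes, planted = simulate_spikes(
                mea.n_electrodes, mea.duration_min, specs,
                background_rate=mea.background_rate,
                max_gap_ms=mea.max_gap_ms, seed=config.seed)
            cio.write_spikes_csv(spikes, out / "spikes.csv")
            detected = bursts_mod.detect_bursts(
                spikes, min_electrodes=mea.min_electrodes,
                max_gap=mea.max_gap_ms)
            bsum = bursts_mod.summarize_bursts(detected, mea.duration_min)
            cio.bursts_to_frame(detected).to_csv(out / "bursts.csv",
                                                 index=False)
            patterns = [bursts_mod.activation_pattern(b) for b in detected]
            cio.activation_patterns_to_frame(patterns).to_csv(
                out / "activation_patterns.csv", index=False)
            summary["bursts"] = {
                "bursts_per_10min": bsum.bursts_per_10min,
                "mean_spikes_per_burst": bsum.mean_spikes_per_burst,
                "mean_duration_ms": bsum.mean_duration_ms,
                "n_planted": len(planted),
                "n_detected": bsum.n_bursts,
            }
        except Exception as exc:
            raise StageError("bursts", exc) from exc

    cio.write_json(summary, out / "summary.json")
    cio.write_json(cio.provenance_record("pipeline", config.as_dict()),
                   out / "pipeline.provenance.json")
    return summary
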