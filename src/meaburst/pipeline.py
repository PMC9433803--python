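"""End-to-end analysis pipeline: simulate, localize, connect, measure, map
bursts and quantify onset/hub associations into one report bundle.

All stages are seeded from the run seed, every output file is a plain-text
CSV or JSON, and the effective configuration (plus its hash) is echoed next
to the results, so two runs with the same seed produce byte-identical
bundles.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List

import numpy as np

from . import association as assoc
from . import bursts as bd
from . import connectivity as conn
from . import graph_metrics as gm
from . import io as mio
from . import learning as ll
from . import propagation as prop
from . import synthetic as syn
from .config import RunConfig
from .core import active_electrodes

__all__ = ["run_all"]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, payload) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _disk_electrodes(grid, center_rc, radius_pitch: float) -> List[int]:
    cx, cy = grid.position(grid.index(*center_rc))
    pos = grid.positions()
    d = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy)
    return [int(e) for e in np.flatnonzero(d <= radius_pitch * grid.pitch)]


def run_all(cfg: RunConfig, outdir, log=lambda msg: None) -> dict:
    """Execute the full pipeline and write the report bundle to ``outdir``.

    Returns the summary report dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = cfg.grid
    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    seed_learn, seed_pre, seed_post = (int(s.generate_state(1)[0] % (2**31)) for s in seeds)

    planted = tuple(_disk_electrodes(grid, cfg.pipeline.learning_center, cfg.pipeline.learning_radius))
    sim_cfg = dataclasses.replace(cfg.simulation, learning_set=planted)

    # 1. learning phase + localization -------------------------------------
    log("simulating learning phase")
    learn = syn.simulate_learning_phase(
        dataclasses.replace(sim_cfg, seed=seed_learn), cfg.protocol, grid
    )
    mio.write_spike_trains(learn.spike_set, outdir / "spikes_learning.csv")
    learn.stimulus_log.write_csv(outdir / "stimulus_log.csv")
    _write_json(outdir / "ground_truth.json", learn.ground_truth_dict())

    log("localizing learning population")
    act = active_electrodes(learn.spike_set)
    table = ll.build_trial_response_table(learn.spike_set, learn.stimulus_log, cfg.window, act)
    lmap = ll.localize(
        table,
        min_defined_trials=cfg.localization.min_defined_trials,
        significance_alpha=cfg.localization.significance_alpha,
    )
    lmap.to_frame(grid).to_csv(outdir / "learning_map.csv", index=False)
    learning_electrodes = lmap.learning_electrodes()

    entropies = ll.isi_entropy_map(
        learn.spike_set, act, bin_width=cfg.localization.isi_bin_width, max_isi=cfg.localization.isi_max
    )
    ent_ratio = ll.entropy_ratio(learning_electrodes, entropies)

    # 2. pre / post spontaneous recordings ----------------------------------
    log("simulating spontaneous recordings")
    pre_cfg = dataclasses.replace(sim_cfg, seed=seed_pre, duration=cfg.pipeline.pre_duration_ms)
    pre = syn.simulate_spontaneous(pre_cfg, grid, phase="before")
    mio.write_spike_trains(pre.spike_set, outdir / "spikes_pre.csv")

    hub_sites = sorted(learning_electrodes or planted)[: cfg.pipeline.n_hub_sites]
    post_cfg = dataclasses.replace(sim_cfg, seed=seed_post, duration=cfg.pipeline.post_duration_ms)
    post = syn.simulate_post_learning(post_cfg, grid, hub_sites)
    mio.write_spike_trains(post.spike_set, outdir / "spikes_post.csv")

    # 3. burst detection -----------------------------------------------------
    log("detecting bursts")
    bursts_pre = bd.detect_bursts(pre.spike_set, active_electrodes(pre.spike_set), cfg.burst_detection)
    bursts_post = bd.detect_bursts(post.spike_set, active_electrodes(post.spike_set), cfg.burst_detection)
    bd.bursts_to_frame(bursts_pre).to_csv(outdir / "bursts_pre.csv", index=False)
    bd.bursts_to_frame(bursts_post).to_csv(outdir / "bursts_post.csv", index=False)

    # 4. functional graph + metrics over learning nodes ---------------------
    log("building functional graph")
    nodes = sorted(learning_electrodes or planted)[: cfg.pipeline.max_graph_nodes]
    graph_report: dict = {"n_nodes": len(nodes)}
    metrics = None
    if len(nodes) >= 2:
        fg = conn.build_functional_graph(post.spike_set, nodes, cfg.connectivity)
        edges = [
            {"src": u, "dst": v, "weight": d["weight"], "peak_lag_ms": d["peak_lag"]}
            for u, v, d in sorted(fg.graph.edges(data=True))
        ]
        _write_json(outdir / "edges.json", {"threshold": fg.threshold, "edges": edges})
        metrics = gm.compute_graph_metrics(fg, seed=cfg.seed, n_nulls=cfg.pipeline.graph_n_nulls)
        with open(outdir / "node_metrics.csv", "w", encoding="utf-8") as fh:
            fh.write("electrode,degree,betweenness,module\n")
            module_of = {n: i for i, mod in enumerate(metrics.partition) for n in mod}
            for e in nodes:
                fh.write(f"{e},{metrics.degree[e]},{metrics.betweenness[e]!r},{module_of[e]}\n")
        graph_report.update(
            {
                "n_links": metrics.n_links,
                "density": metrics.density,
                "global_efficiency": metrics.global_efficiency,
                "modularity": metrics.modularity,
                "threshold": fg.threshold,
                "small_world": dataclasses.asdict(metrics.small_world) if metrics.small_world else None,
            }
        )

    # 5. propagation ---------------------------------------------------------
    log("mapping burst propagation")
    entries, clusters = prop.analyze_bursts(
        bursts_post, grid, learning_electrodes or list(planted), cluster_radius=cfg.association.cluster_radius
    )
    prop.propagation_frame(entries).to_csv(outdir / "propagation.csv", index=False)
    dist_fracs = (
        prop.distance_distribution(
            [e.site for e in entries], learning_electrodes or list(planted), grid
        )
        if entries
        else {}
    )

    # 6. association ---------------------------------------------------------
    log("quantifying associations")
    association_report: Dict = {"distance_fractions": {str(k): v for k, v in dist_fracs.items()}}
    if metrics is not None and clusters:
        for name, metric in (("degree", metrics.degree), ("betweenness", metrics.betweenness)):
            reg = assoc.metric_burst_regression(
                clusters, metric, grid, metric_name=name, link_radius=cfg.association.link_radius
            )
            association_report[f"regression_{name}"] = dataclasses.asdict(reg) if reg else None
        onset_union = sorted({e for en in entries for e in en.onset_electrodes})
        for name, metric in (("degree", metrics.degree), ("betweenness", metrics.betweenness)):
            association_report[f"overlap_{name}"] = assoc.top_percentile_overlap(
                onset_union, metric, grid,
                percentile_keep=cfg.association.percentile_keep,
                link_radius=cfg.association.link_radius,
            )

    comparisons = []
    if len(bursts_pre) >= 2 and len(bursts_post) >= 2:
        comparisons.append(
            dataclasses.asdict(
                assoc.pre_post_compare(
                    [b.duration for b in bursts_pre], [b.duration for b in bursts_post], "burst_duration_ms"
                )
            )
        )
        comparisons.append(
            dataclasses.asdict(
                assoc.pre_post_compare(
                    [b.n_electrodes for b in bursts_pre], [b.n_electrodes for b in bursts_post],
                    "electrodes_per_burst",
                )
            )
        )

    report = {
        "config": cfg.to_dict(),
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "learning": {
            "n_planted": len(planted),
            "n_detected": len(learning_electrodes),
            "entropy_ratio": ent_ratio,
        },
        "bursts": {
            "pre": bd.burst_summary(bursts_pre) | {"rate_per_min": bd.burst_rate(bursts_pre, pre.spike_set.duration)},
            "post": bd.burst_summary(bursts_post)
            | {"rate_per_min": bd.burst_rate(bursts_post, post.spike_set.duration)},
        },
        "graph": graph_report,
        "association": association_report,
        "comparisons": comparisons,
    }
    _write_json(outdir / "report.json", report)
    _write_json(outdir / "effective_config.json", {"digest": cfg.digest(), "config": cfg.to_dict()})
    return report
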