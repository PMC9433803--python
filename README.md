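# meaburst

Analysis pipeline for spike trains recorded on high-density microelectrode
arrays (default: 64 × 64 electrodes at 81 μm pitch). Given per-electrode
spike timestamps, a stimulation log, and a run configuration, the package

- localizes the **learning population** from stimulus-evoked responses
  (rising response/stimulus ratio and falling response time across trials),
- detects **network bursts** (time bins in which strictly more than 25 % of
  active electrodes fire) and summarizes their rate, size and duration,
- builds a **functional graph** over learning electrodes from spike-train
  cross-correlograms (threshold: network mean plus three average SDs,
  direction from peak-lag polarity) and computes degree, density, global
  efficiency, modularity, betweenness centrality and small-worldness,
- maps **burst initiation and propagation** (first-spike rank order, onset
  electrodes, initiation sites, distance–latency regression, distances to
  the learning population), and
- quantifies the **association** between burst-onset clusters and
  learning-population hubs (metric–burst regressions, top-percentile
  overlap, Welch-t pre/post comparisons).

A synthetic spike-train generator (`meaburst.synthetic`) produces recordings
with all the structure the pipeline assumes — Poisson background, radially
propagating bursts from planted sites, learning electrodes with linearly
improving evoked responses, a post-learning regime with new burst-initiation
sites, and a disinhibition mode — together with explicit ground-truth
annotations, so the whole chain is testable without any external data.

## Command line

```bash
meaburst run-all --seed 7 --outdir out/            # full pipeline, default config
meaburst run-all --config my_config.yaml --outdir out/
meaburst simulate --phase learning --outdir sim/   # synthetic data only
meaburst detect-bursts --spikes sim/spikes.csv --out bursts.csv
meaburst localize --spikes ... --stimlog ... --out learning_map.csv
meaburst connect | metrics | propagate | associate # stage-by-stage runs
```

`run-all` executes simulate → localize → connect → metrics → detect-bursts
(pre/post) → propagate → associate and writes a deterministic JSON + CSV
report bundle (`report.json`, `learning_map.csv`, `bursts_{pre,post}.csv`,
`propagation.csv`, `node_metrics.csv`, `edges.json`, spike-event CSVs and
the effective configuration with its hash). Identical seeds and configs give
byte-identical bundles. Configuration is YAML/JSON with one block per stage;
unknown keys are rejected. The default configuration runs a reduced grid for
speed; scale `grid`, `simulation` and `pipeline` blocks up as needed.

Spike-event files are plain CSV (`electrode,row,col,time_ms`) with a JSON
metadata sidecar (`*.meta.json`) carrying the recording duration and grid
geometry; timestamps round-trip bit exactly.

## Layout

| Module | Contents |
| --- | --- |
| `meaburst.core` | electrode grid geometry, spike-train data model, active-electrode rule |
| `meaburst.io` | spike-event CSV + metadata sidecar reader/writer |
| `meaburst.protocol` | stimulation schedule (cycles/trials/stimuli) and post-stimulus windowing |
| `meaburst.synthetic` | seeded synthetic recording generator with ground truth |
| `meaburst.bursts` | network-burst detection and summaries |
| `meaburst.learning` | R/S ratio, response time, trial-trend fits, learning-population map, ISI entropy |
| `meaburst.connectivity` | cross-correlograms, functional graph, rate correlation, synchrony |
| `meaburst.graph_metrics` | degree, density, efficiency, modularity, betweenness, small-worldness |
| `meaburst.propagation` | rank-order maps, initiation sites, distance–latency fits, onset clusters |
| `meaburst.association` | metric–burst regressions, top-percentile overlap, pre/post comparisons |
| `meaburst.cli` / `meaburst.pipeline` / `meaburst.config` | CLI, end-to-end runner, schema-checked config |
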