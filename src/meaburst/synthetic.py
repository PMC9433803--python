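"""Synthetic HD-MEA spike-train generator.

Produces recordings with the statistical structure the analysis pipeline
assumes: independent Poisson background per electrode, network bursts with
spatially localized initiation and radial recruitment, and stimulus-evoked
responses in a planted learning subset whose response probability rises and
latency falls linearly across trials.  Every simulation returns its ground
truth (burst annotations, learning mask) explicitly; nothing downstream ever
infers it.

Randomness is split into three named streams (background, bursts, responses)
spawned from the master seed, so enabling one component never shifts the
draws of another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import ElectrodeGrid, SpikeTrainSet
from .errors import ConfigError
from .protocol import StimulationProtocol, StimulusLog, build_schedule

__all__ = [
    "SimulationConfig",
    "BurstAnnotation",
    "SimulationResult",
    "simulate_spontaneous",
    "simulate_learning_phase",
    "simulate_post_learning",
]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    duration: float = 300_000.0  # ms
    background_rate: float = 0.5  # Hz per electrode
    burst_rate: float = 4.0  # bursts / min (pre-learning)
    post_burst_rate: float = 8.0  # bursts / min (post-learning)
    burst_sites: Tuple[Tuple[int, int], ...] = ((16, 16),)
    propagation_speed: float = 20.0  # μm / ms
    latency_jitter_sd: float = 3.0  # ms
    participation_fraction: float = 0.6
    spikes_per_burst_mean: float = 4.0  # per recruited electrode, Poisson
    burst_len_range: Tuple[float, float] = (100.0, 300.0)  # ms
    min_burst_interval: float = 1000.0  # ms refractory between burst onsets
    learning_set: Tuple[int, ...] = ()
    rs_start: float = 0.2
    rs_end: float = 0.9
    rt_start: float = 150.0  # ms
    rt_end: float = 40.0  # ms
    nonlearning_response_prob: float = 0.15
    nonlearning_latency: float = 100.0  # ms, constant mean
    bicuculline_mode: bool = False
    n_neurons: int = 90_000  # modeled culture size (metadata; sampling ratio)

    def __post_init__(self) -> None:
        for name in ("rs_start", "rs_end", "nonlearning_response_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not self.rt_start > self.rt_end >= 10.0:
            raise ConfigError("require rt_start > rt_end >= 10 ms")
        if self.background_rate < 0:
            raise ConfigError("background_rate must be >= 0")
        if self.burst_rate < 0 or self.post_burst_rate < 0:
            raise ConfigError("burst rates must be >= 0")
        if self.propagation_speed <= 0:
            raise ConfigError("propagation_speed must be positive")
        if not 0 < self.participation_fraction <= 1:
            raise ConfigError("participation_fraction must be in (0, 1]")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")

    # Effective parameters under the disinhibition regime.
    @property
    def eff_burst_rate(self) -> float:
        return self.burst_rate * (2.0 if self.bicuculline_mode else 1.0)

    @property
    def eff_burst_len_range(self) -> Tuple[float, float]:
        f = 1.5 if self.bicuculline_mode else 1.0
        return (self.burst_len_range[0] * f, self.burst_len_range[1] * f)

    @property
    def eff_participation(self) -> float:
        f = 1.3 if self.bicuculline_mode else 1.0
        return min(1.0, self.participation_fraction * f)


@dataclass
class BurstAnnotation:
    t0: float  # site onset time, ms
    t_end: float
    site_rc: Tuple[int, int]
    site_index: int
    electrodes: List[int]
    kind: str = "baseline"  # or "new_pattern"


@dataclass
class SimulationResult:
    spike_set: SpikeTrainSet
    bursts: List[BurstAnnotation] = field(default_factory=list)
    stimulus_log: Optional[StimulusLog] = None
    learning_mask: Optional[np.ndarray] = None

    def ground_truth_dict(self) -> dict:
        return {
            "bursts": [
                {
                    "t0": b.t0,
                    "t_end": b.t_end,
                    "site": list(b.site_rc),
                    "electrodes": b.electrodes,
                    "kind": b.kind,
                }
                for b in self.bursts
            ],
            "learning_mask": self.learning_mask.astype(int).tolist() if self.learning_mask is not None else None,
        }


def _streams(seed: int):
    bg, bu, re_ = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(bg),
        np.random.default_rng(bu),
        np.random.default_rng(re_),
    )


def _background(rng: np.random.Generator, grid: ElectrodeGrid, rate_hz: float, duration: float) -> List[np.ndarray]:
    """Independent homogeneous Poisson train per electrode."""
    n = grid.n_electrodes
    if rate_hz == 0:
        return [np.empty(0) for _ in range(n)]
    lam = rate_hz * duration / 1000.0
    counts = rng.poisson(lam, size=n)
    total = int(counts.sum())
    times = rng.random(total) * duration
    out: List[np.ndarray] = []
    start = 0
    for c in counts:
        seg = np.sort(times[start : start + c])
        out.append(seg)
        start += c
    return out


def _poisson_onsets(rng: np.random.Generator, rate_per_min: float, duration: float, margin: float,
                    refractory: float) -> np.ndarray:
    """Poisson-process onsets on [0, duration - margin) thinned so consecutive
    onsets are at least ``refractory`` apart."""
    if rate_per_min <= 0:
        return np.empty(0)
    horizon = max(duration - margin, 0.0)
    rate_ms = rate_per_min / 60_000.0
    onsets: List[float] = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_ms)
        if t >= horizon:
            break
        if not onsets or t - onsets[-1] >= refractory:
            onsets.append(t)
    return np.asarray(onsets)


def _recruit(grid: ElectrodeGrid, site_rc: Tuple[int, int], fraction: float) -> tuple[int, np.ndarray, np.ndarray]:
    """Electrodes within the ``fraction`` distance quantile of the site.

    Returns (site index, recruited electrode indices, their distances)."""
    site_e = grid.index(*site_rc)
    pos = grid.positions()
    sp = grid.position(site_e)
    d = np.hypot(pos[:, 0] - sp[0], pos[:, 1] - sp[1])
    k = max(1, int(round(fraction * grid.n_electrodes)))
    order = np.argsort(d, kind="stable")
    chosen = order[:k]
    return site_e, chosen, d[chosen]


def _add_bursts(
    rng: np.random.Generator,
    grid: ElectrodeGrid,
    cfg: SimulationConfig,
    duration: float,
    rate_per_min: float,
    sites: Sequence[Tuple[int, int]],
    new_pattern_sites: frozenset = frozenset(),
) -> tuple[List[List[np.ndarray]], List[BurstAnnotation]]:
    """Burst spikes per electrode plus ground-truth annotations."""
    len_lo, len_hi = cfg.eff_burst_len_range
    onsets = _poisson_onsets(rng, rate_per_min, duration, margin=len_hi + 400.0,
                             refractory=cfg.min_burst_interval)
    per_elec: List[List[np.ndarray]] = [[] for _ in range(grid.n_electrodes)]
    annotations: List[BurstAnnotation] = []
    if onsets.size == 0:
        return per_elec, annotations
    recruit_cache = {rc: _recruit(grid, rc, cfg.eff_participation) for rc in sites}
    for t0 in onsets:
        rc = sites[int(rng.integers(len(sites)))]
        site_e, chosen, dist = recruit_cache[rc]
        first = dist / cfg.propagation_speed
        if cfg.latency_jitter_sd > 0:
            first = np.maximum(first + rng.normal(0.0, cfg.latency_jitter_sd, size=first.size), 0.0)
        burst_len = float(rng.uniform(len_lo, len_hi))
        extras_n = rng.poisson(max(cfg.spikes_per_burst_mean - 1.0, 0.0), size=chosen.size)
        t_end = t0 + max(burst_len, float(first.max()) + 10.0)
        for e, f, k in zip(chosen, first, extras_n):
            ts = [t0 + f]
            if k > 0:
                hi = t_end - t0
                ts.extend(t0 + f + rng.random(k) * max(hi - f, 1.0))
            arr = np.asarray(ts)
            per_elec[e].append(arr[arr < duration])
        annotations.append(
            BurstAnnotation(
                t0=float(t0),
                t_end=float(min(t_end, duration)),
                site_rc=rc,
                site_index=site_e,
                electrodes=[int(e) for e in chosen],
                kind="new_pattern" if rc in new_pattern_sites else "baseline",
            )
        )
    return per_elec, annotations


def _assemble(grid: ElectrodeGrid, duration: float, parts: Sequence[Sequence], metadata: dict) -> SpikeTrainSet:
    """Merge per-electrode spike fragments into a valid SpikeTrainSet."""
    spikes: Dict[int, np.ndarray] = {}
    for e in range(grid.n_electrodes):
        chunks: List[np.ndarray] = []
        for p in parts:
            x = p[e]
            if isinstance(x, list):
                chunks.extend(a for a in x if a.size)
            elif x.size:
                chunks.append(x)
        if not chunks:
            continue
        t = np.concatenate(chunks)
        t = t[(t >= 0) & (t < duration)]
        if t.size == 0:
            continue
        spikes[e] = np.unique(t)  # sorted, exact duplicates dropped
    return SpikeTrainSet(spikes=spikes, duration=duration, grid=grid, metadata=metadata)


def simulate_spontaneous(
    cfg: SimulationConfig,
    grid: ElectrodeGrid = ElectrodeGrid(),
    rate_per_min: float | None = None,
    extra_sites: Sequence[Tuple[int, int]] = (),
    new_pattern_sites: frozenset = frozenset(),
    phase: str = "before",
) -> SimulationResult:
    """Spontaneous recording: Poisson background plus annotated network bursts."""
    for rc in cfg.burst_sites:
        grid.index(*rc)  # validates
    rng_bg, rng_bu, _ = _streams(cfg.seed)
    bg = _background(rng_bg, grid, cfg.background_rate, cfg.duration)
    sites = tuple(cfg.burst_sites) + tuple(extra_sites)
    rate = cfg.eff_burst_rate if rate_per_min is None else rate_per_min
    burst_spikes, annotations = _add_bursts(
        rng_bu, grid, cfg, cfg.duration, rate, sites, new_pattern_sites=new_pattern_sites
    )
    meta = {"phase": phase, "seed": cfg.seed, "bicuculline": cfg.bicuculline_mode}
    s = _assemble(grid, cfg.duration, [bg, burst_spikes], meta)
    return SimulationResult(spike_set=s, bursts=annotations)


def simulate_post_learning(
    cfg: SimulationConfig, grid: ElectrodeGrid, hub_sites: Sequence[int]
) -> SimulationResult:
    """Post-learning spontaneous regime: burst sites augmented with learning
    hubs and the post-learning burst rate; hub-initiated bursts are annotated
    as new patterns."""
    hub_rc = tuple(grid.rc(int(e)) for e in hub_sites)
    if not hub_rc:
        warnings.warn("no hub sites supplied; falling back to pre-learning sites", stacklevel=2)
    rate = cfg.post_burst_rate * (2.0 if cfg.bicuculline_mode else 1.0)
    return simulate_spontaneous(
        cfg, grid, rate_per_min=rate, extra_sites=hub_rc,
        new_pattern_sites=frozenset(hub_rc), phase="after",
    )


def simulate_learning_phase(
    cfg: SimulationConfig,
    protocol: StimulationProtocol = StimulationProtocol(),
    grid: ElectrodeGrid = ElectrodeGrid(),
) -> SimulationResult:
    """Stimulation recording with planted learning structure.

    Learning electrodes respond to each stimulus with probability
    interpolated linearly from ``rs_start`` (first trial) to ``rs_end`` (last
    trial); a response is a three-spike volley whose leading latency is drawn
    around the trial-interpolated RT mean, truncated to the analysis window.
    Non-learning electrodes respond with constant probability and latency.
    """
    if not cfg.learning_set:
        raise ConfigError("learning_set must be non-empty for a learning-phase simulation")
    learning = np.asarray(sorted({grid.check_index(e) for e in cfg.learning_set}), dtype=int)
    log = build_schedule(protocol)
    times = log.times
    duration = float(times[-1] + 1000.0)
    rng_bg, _, rng_re = _streams(cfg.seed)
    bg = _background(rng_bg, grid, cfg.background_rate, duration)

    n = grid.n_electrodes
    n_trials = protocol.n_trials
    trial_of_stim = log.global_trials
    mask = np.zeros(n, dtype=bool)
    mask[learning] = True

    p_vec = np.full(n, cfg.nonlearning_response_prob)
    rt_vec = np.full(n, cfg.nonlearning_latency)
    evoked: List[List[np.ndarray]] = [[] for _ in range(n)]
    denom = max(n_trials - 1, 1)
    for s_idx, t_stim in enumerate(times):
        g = trial_of_stim[s_idx]
        frac = g / denom
        p_vec[mask] = cfg.rs_start + (cfg.rs_end - cfg.rs_start) * frac
        rt_vec[mask] = cfg.rt_start + (cfg.rt_end - cfg.rt_start) * frac
        responds = rng_re.random(n) < p_vec
        lat = rng_re.normal(rt_vec, cfg.latency_jitter_sd, size=n)
        lat = np.clip(lat, 12.0, 190.0)
        for e in np.flatnonzero(responds):
            l0 = lat[e]
            volley = t_stim + np.array([l0, min(l0 + 3.0, 197.0), min(l0 + 6.0, 199.0)])
            evoked[e].append(volley)

    meta = {"phase": "learning", "seed": cfg.seed}
    s = _assemble(grid, duration, [bg, evoked], meta)
    return SimulationResult(spike_set=s, stimulus_log=log, learning_mask=mask)


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(cfg, seed=seed)
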