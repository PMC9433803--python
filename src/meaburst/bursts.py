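"""Network-burst detection from binned population participation.

A time bin is supra-threshold when the number of *distinct* active electrodes
spiking in it strictly exceeds ``fraction_threshold x |active|`` (for the
default quarter fraction on a fully active 4,096-electrode array the strict
threshold is 1,024 electrodes).  Maximal runs of supra-threshold bins, with
short gaps merged, form network bursts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Set

import numpy as np
import pandas as pd

from .core import ActiveElectrodeSet, SpikeTrainSet
from .errors import ConfigError

__all__ = [
    "BurstDetectionConfig",
    "NetworkBurst",
    "participation_threshold",
    "detect_bursts",
    "burst_rate",
    "burst_summary",
    "bursts_to_frame",
]


@dataclass(frozen=True)
class BurstDetectionConfig:
    bin_width: float = 25.0  # ms
    fraction_threshold: float = 0.25
    merge_gap: float = 100.0  # ms
    min_duration: float = 25.0  # ms
    # The strict participation threshold triggers well into a propagating
    # burst; to let rank-order maps see the onset ramp, the window start is
    # walked back over contiguous bins whose participation still exceeds
    # onset_fraction (set to None to disable).
    onset_fraction: float | None = 0.05
    onset_max_extension: float = 250.0  # ms

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        if not 0 < self.fraction_threshold < 1:
            raise ConfigError("fraction_threshold must be in (0, 1)")
        if self.merge_gap < 0 or self.min_duration < 0:
            raise ConfigError("merge_gap and min_duration must be non-negative")
        if self.onset_fraction is not None and not 0 <= self.onset_fraction < self.fraction_threshold:
            raise ConfigError("onset_fraction must be in [0, fraction_threshold)")


@dataclass
class NetworkBurst:
    t_start: float
    t_end: float
    participating_electrodes: Set[int]
    first_spike_time: Dict[int, float]
    peak_bin_count: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_electrodes(self) -> int:
        return len(self.participating_electrodes)


def participation_threshold(n_active: int, fraction_threshold: float = 0.25) -> float:
    """Electrode count that a bin must strictly exceed to be supra-threshold."""
    return fraction_threshold * n_active


def detect_bursts(
    s: SpikeTrainSet, active: ActiveElectrodeSet, cfg: BurstDetectionConfig = BurstDetectionConfig()
) -> List[NetworkBurst]:
    if len(active) < 1:
        raise ConfigError("need at least one active electrode")
    if cfg.bin_width >= s.duration:
        raise ConfigError("bin_width must be smaller than the recording duration")

    n_bins = int(np.ceil(s.duration / cfg.bin_width))
    counts = np.zeros(n_bins, dtype=np.int64)
    actives = active.sorted
    for e in actives:
        t = s.spikes.get(e)
        if t is None or t.size == 0:
            continue
        bins = np.unique((t // cfg.bin_width).astype(np.int64))
        counts[bins] += 1

    thr = participation_threshold(len(active), cfg.fraction_threshold)
    supra = counts > thr  # strict
    if not supra.any():
        return []

    # Runs of supra bins, then merge runs separated by <= merge_gap.
    idx = np.flatnonzero(supra)
    run_breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[run_breaks + 1]])
    stops = np.concatenate([idx[run_breaks], [idx[-1]]])  # inclusive bin index
    merged = [[starts[0], stops[0]]]
    for b0, b1 in zip(starts[1:], stops[1:]):
        gap_ms = (b0 - merged[-1][1] - 1) * cfg.bin_width
        if gap_ms <= cfg.merge_gap:
            merged[-1][1] = b1
        else:
            merged.append([b0, b1])

    if cfg.onset_fraction is not None:
        onset_thr = cfg.onset_fraction * len(active)
        max_back = int(cfg.onset_max_extension // cfg.bin_width)
        prev_end = -1
        for run in merged:
            b0 = run[0]
            limit = max(b0 - max_back, prev_end + 1, 0)
            while b0 > limit and counts[b0 - 1] > onset_thr:
                b0 -= 1
            run[0] = b0
            prev_end = run[1]

    bursts: List[NetworkBurst] = []
    for b0, b1 in merged:
        t_start = b0 * cfg.bin_width
        t_end = min((b1 + 1) * cfg.bin_width, s.duration)
        if t_end - t_start < cfg.min_duration:
            continue
        first: Dict[int, float] = {}
        for e in actives:
            t = s.spikes.get(e)
            if t is None or t.size == 0:
                continue
            i = np.searchsorted(t, t_start, side="left")
            if i < t.size and t[i] < t_end:
                first[e] = float(t[i])
        bursts.append(
            NetworkBurst(
                t_start=float(t_start),
                t_end=float(t_end),
                participating_electrodes=set(first),
                first_spike_time=first,
                peak_bin_count=int(counts[b0 : b1 + 1].max()),
            )
        )
    return bursts


def burst_rate(bursts: List[NetworkBurst], duration: float) -> float:
    """Bursts per minute."""
    if duration <= 0:
        raise ConfigError("duration must be positive")
    return len(bursts) / (duration / 60000.0)


def burst_summary(bursts: List[NetworkBurst]) -> dict:
    if not bursts:
        return {"n_bursts": 0, "mean_electrodes": None, "mean_duration_ms": None}
    return {
        "n_bursts": len(bursts),
        "mean_electrodes": float(np.mean([b.n_electrodes for b in bursts])),
        "mean_duration_ms": float(np.mean([b.duration for b in bursts])),
    }


def bursts_to_frame(bursts: List[NetworkBurst]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "burst_id": range(len(bursts)),
            "t_start_ms": [b.t_start for b in bursts],
            "t_end_ms": [b.t_end for b in bursts],
            "duration_ms": [b.duration for b in bursts],
            "n_electrodes": [b.n_electrodes for b in bursts],
            "peak_count": [b.peak_bin_count for b in bursts],
        }
    )
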