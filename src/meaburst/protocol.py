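"""Stimulation paradigm: schedule construction and post-stimulus windowing.

The learning paradigm is organised as cycles of trials; each trial delivers a
fixed count of stimuli at a fixed frequency and is followed by a rest period,
with a longer rest after each cycle.  Counts are authoritative; rest durations
only shift event times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, NamedTuple

import numpy as np
import pandas as pd

from .core import SpikeTrainSet
from .errors import ConfigError

__all__ = [
    "StimulationProtocol",
    "StimulusEvent",
    "StimulusLog",
    "ResponseWindow",
    "build_schedule",
    "evoked_spikes",
    "effective_window_ends",
]


@dataclass(frozen=True)
class StimulationProtocol:
    n_cycles: int = 8
    trials_per_cycle: int = 4
    stimuli_per_trial: int = 10
    stimulus_frequency: float = 1.0  # Hz
    rest_after_trial: float = 20.0  # s
    rest_after_cycle: float = 60.0  # s
    stim_electrode_pair: tuple = ("(3,3)", "(2,2)")
    # Pulse description is metadata only; it does not affect scheduling.
    pulse: dict = field(
        default_factory=lambda: {
            "shape": "biphasic_negative_first",
            "phase_duration_us": 200.0,
            "amplitude_ua": 15.0,
        }
    )

    def __post_init__(self) -> None:
        if min(self.n_cycles, self.trials_per_cycle, self.stimuli_per_trial) < 1:
            raise ConfigError("protocol counts must all be >= 1")
        if self.stimulus_frequency <= 0:
            raise ConfigError("stimulus_frequency must be positive")
        if min(self.rest_after_trial, self.rest_after_cycle) < 0:
            raise ConfigError("rest durations must be non-negative")

    @property
    def n_stimuli(self) -> int:
        return self.n_cycles * self.trials_per_cycle * self.stimuli_per_trial

    @property
    def n_trials(self) -> int:
        return self.n_cycles * self.trials_per_cycle


class StimulusEvent(NamedTuple):
    time_ms: float
    cycle: int
    trial: int
    stim: int


@dataclass
class StimulusLog:
    events: List[StimulusEvent]
    trials_per_cycle: int = 4

    def __post_init__(self) -> None:
        self.events = [ev if isinstance(ev, StimulusEvent) else StimulusEvent(*ev) for ev in self.events]
        times = self.times
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ConfigError("stimulus times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([ev.time_ms for ev in self.events], dtype=float)

    @property
    def global_trials(self) -> np.ndarray:
        """0-based global trial index (cycle * trials_per_cycle + trial) per event."""
        return np.array([ev.cycle * self.trials_per_cycle + ev.trial for ev in self.events], dtype=int)

    @property
    def n_trials(self) -> int:
        return len({(ev.cycle, ev.trial) for ev in self.events})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["time_ms", "cycle", "trial", "stim"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, trials_per_cycle: int = 4) -> "StimulusLog":
        df = pd.read_csv(path)
        events = [
            StimulusEvent(float(t), int(c), int(tr), int(s))
            for t, c, tr, s in zip(df["time_ms"], df["cycle"], df["trial"], df["stim"])
        ]
        return cls(events=events, trials_per_cycle=trials_per_cycle)


@dataclass(frozen=True)
class ResponseWindow:
    artifact_blank: float = 10.0  # ms discarded after each stimulus
    window_end: float = 200.0  # ms

    def __post_init__(self) -> None:
        if not 0 < self.artifact_blank < self.window_end:
            raise ConfigError("require 0 < artifact_blank < window_end")


def build_schedule(p: StimulationProtocol) -> StimulusLog:
    """Deterministic stimulus times for one full learning phase, starting at 0 ms."""
    isi = 1000.0 / p.stimulus_frequency
    events: List[StimulusEvent] = []
    t = 0.0
    for cycle in range(p.n_cycles):
        for trial in range(p.trials_per_cycle):
            for stim in range(p.stimuli_per_trial):
                events.append(StimulusEvent(t + stim * isi, cycle, trial, stim))
            t += p.stimuli_per_trial * isi + p.rest_after_trial * 1000.0
        t += p.rest_after_cycle * 1000.0
    return StimulusLog(events=events, trials_per_cycle=p.trials_per_cycle)


def effective_window_ends(log: StimulusLog, w: ResponseWindow) -> np.ndarray:
    """Per-stimulus analysis-window end (ms after the stimulus).

    When consecutive stimuli are closer than ``window_end`` the windows are
    truncated at the next stimulus, with a warning.
    """
    times = log.times
    ends = np.full(times.size, w.window_end)
    if times.size > 1:
        gaps = np.diff(times)
        clipped = gaps < w.window_end
        if np.any(clipped):
            warnings.warn(
                "stimulus spacing shorter than analysis window; truncating at the next stimulus",
                stacklevel=2,
            )
            ends[:-1][clipped] = gaps[clipped]
    return ends


def evoked_spikes(s: SpikeTrainSet, log: StimulusLog, w: ResponseWindow, electrode: int) -> list[np.ndarray]:
    """Per-stimulus latencies (ms, relative to stimulus) of one electrode.

    Only spikes with latency in ``(artifact_blank, window_end]`` are returned;
    windows are truncated at the next stimulus when they would overlap.
    """
    times = log.times
    if times.size and times[-1] >= s.duration:
        raise ConfigError("stimulus times extend beyond the recording")
    ends = effective_window_ends(log, w)
    train = s.train(electrode)
    lo = np.searchsorted(train, times + w.artifact_blank, side="right")
    hi = np.searchsorted(train, times + ends, side="right")
    return [train[a:b] - t for a, b, t in zip(lo, hi, times)]
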