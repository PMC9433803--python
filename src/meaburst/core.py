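"""Electrode-grid geometry and the spike-train data model.

Electrodes are addressed by a single flat integer index ``e = row * n_cols +
col``.  Electrode centers live on a square lattice with configurable pitch;
electrode (0, 0) is centered at the spatial origin and position units are
micrometres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable

import numpy as np

from .errors import ConfigError

__all__ = [
    "ElectrodeGrid",
    "SpikeTrainSet",
    "ActiveElectrodeSet",
    "electrode_distance",
    "active_electrodes",
]


@dataclass(frozen=True)
class ElectrodeGrid:
    """Square recording array: ``n_rows x n_cols`` electrodes at ``pitch`` μm."""

    n_rows: int = 64
    n_cols: int = 64
    pitch: float = 81.0
    electrode_size: float = 21.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigError("grid dimensions must be >= 1")
        if self.pitch <= 0:
            raise ConfigError("pitch must be positive")

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    def check_index(self, e: int) -> int:
        e = int(e)
        if not 0 <= e < self.n_electrodes:
            raise IndexError(f"electrode index {e} outside grid of {self.n_electrodes}")
        return e

    def index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"electrode (row={row}, col={col}) outside {self.n_rows}x{self.n_cols} grid")
        return int(row) * self.n_cols + int(col)

    def rc(self, e: int) -> tuple[int, int]:
        e = self.check_index(e)
        return divmod(e, self.n_cols)

    def position(self, e: int) -> np.ndarray:
        """Center position (x, y) in μm of electrode ``e``; x grows with column."""
        r, c = self.rc(e)
        return np.array([c * self.pitch, r * self.pitch], dtype=float)

    def positions(self, electrodes: Iterable[int] | None = None) -> np.ndarray:
        """(N, 2) array of center positions; all electrodes when unspecified."""
        if electrodes is None:
            idx = np.arange(self.n_electrodes)
        else:
            idx = np.asarray([self.check_index(e) for e in electrodes], dtype=int)
        r, c = np.divmod(idx, self.n_cols)
        return np.column_stack([c * self.pitch, r * self.pitch]).astype(float)


def electrode_distance(a: int, b: int, grid: ElectrodeGrid) -> float:
    """Euclidean center-to-center distance in μm between electrodes a and b."""
    pa = grid.position(a)
    pb = grid.position(b)
    return float(np.hypot(*(pa - pb)))


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike timestamps (ms) over a half-open recording
    window ``[0, duration)``.

    ``spikes`` maps the flat electrode index to a strictly increasing float64
    array of timestamps.  Electrodes without spikes may simply be absent.
    """

    spikes: Dict[int, np.ndarray]
    duration: float
    grid: ElectrodeGrid = field(default_factory=ElectrodeGrid)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        clean: Dict[int, np.ndarray] = {}
        for e, t in self.spikes.items():
            e = self.grid.check_index(e)
            arr = np.asarray(t, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"electrode {e}: spike train must be 1-D")
            if arr.size:
                if arr[0] < 0 or arr[-1] >= self.duration:
                    raise ValueError(
                        f"electrode {e}: timestamps must satisfy 0 <= t < duration ({self.duration})"
                    )
                if arr.size > 1 and not np.all(np.diff(arr) > 0):
                    raise ValueError(f"electrode {e}: timestamps must be strictly increasing")
            clean[e] = arr
        self.spikes = clean

    def train(self, e: int) -> np.ndarray:
        return self.spikes.get(self.grid.check_index(e), np.empty(0))

    def n_spikes(self, e: int) -> int:
        return int(self.train(e).size)

    @property
    def total_spikes(self) -> int:
        return int(sum(a.size for a in self.spikes.values()))

    @property
    def electrodes(self) -> list[int]:
        return sorted(self.spikes)

    def firing_rate(self, e: int) -> float:
        """Mean firing rate of electrode ``e`` in Hz."""
        return self.n_spikes(e) / (self.duration / 1000.0)


@dataclass(frozen=True)
class ActiveElectrodeSet:
    indices: frozenset
    criterion: str

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, e: int) -> bool:
        return e in self.indices

    def __iter__(self):
        return iter(self.sorted)

    @property
    def sorted(self) -> list[int]:
        return sorted(self.indices)


def active_electrodes(s: SpikeTrainSet, min_spikes: int = 1) -> ActiveElectrodeSet:
    """Electrodes with at least ``min_spikes`` spikes over the full recording."""
    if min_spikes < 1:
        raise ConfigError("min_spikes must be >= 1")
    idx = frozenset(e for e, t in s.spikes.items() if t.size >= min_spikes)
    return ActiveElectrodeSet(indices=idx, criterion=f">= {min_spikes} spikes in recording")
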