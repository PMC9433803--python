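"""Plain-text file I/O for spike trains and stimulus logs.

Spike-event files are UTF-8 CSV with header ``electrode,row,col,time_ms``
plus a JSON metadata sidecar (same path with a ``.meta.json`` suffix) holding
``duration_ms``, grid geometry and free-form metadata.  Timestamps are written
with ``repr`` so the read/write round trip is bit exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ElectrodeGrid, SpikeTrainSet
from .errors import FormatError

__all__ = ["write_spike_trains", "read_spike_trains", "sidecar_path"]

_HEADER = ["electrode", "row", "col", "time_ms"]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".meta.json")


def write_spike_trains(s: SpikeTrainSet, path) -> Path:
    """Write a spike-event CSV plus its JSON metadata sidecar.

    Returns the sidecar path.  Rows are ordered by electrode index then time,
    so output bytes are a pure function of the spike-train content.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_HEADER) + "\n")
        for e in sorted(s.spikes):
            r, c = s.grid.rc(e)
            for t in s.spikes[e]:
                fh.write(f"{e},{r},{c},{float(t)!r}\n")
    meta = {
        "duration_ms": s.duration,
        "n_rows": s.grid.n_rows,
        "n_cols": s.grid.n_cols,
        "pitch_um": s.grid.pitch,
        "electrode_size_um": s.grid.electrode_size,
        "metadata": s.metadata,
    }
    mp = sidecar_path(path)
    with open(mp, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return mp


def read_spike_trains(path, meta_path=None) -> SpikeTrainSet:
    """Read a spike-event CSV written by :func:`write_spike_trains`.

    Malformed records are rejected with a :class:`FormatError` naming the
    1-based CSV line of the first offending row.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else sidecar_path(path)
    if not meta_path.exists():
        raise FormatError("missing metadata sidecar", path=meta_path)
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    try:
        grid = ElectrodeGrid(
            n_rows=int(meta["n_rows"]),
            n_cols=int(meta["n_cols"]),
            pitch=float(meta["pitch_um"]),
            electrode_size=float(meta.get("electrode_size_um", 21.0)),
        )
        duration = float(meta["duration_ms"])
    except KeyError as exc:  # pragma: no cover - defensive
        raise FormatError(f"metadata missing key {exc}", path=meta_path) from exc

    try:
        df = pd.read_csv(
            path,
            dtype={"electrode": "int64", "row": "int64", "col": "int64", "time_ms": "float64"},
            float_precision="round_trip",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"unparseable spike-event file: {exc}", path=path) from exc
    if list(df.columns) != _HEADER:
        raise FormatError(f"expected header {','.join(_HEADER)}, found {','.join(df.columns)}", path=path, line=1)

    e = df["electrode"].to_numpy()
    t = df["time_ms"].to_numpy()
    # CSV line numbers: +2 for the header row and 1-based counting.
    bad = np.flatnonzero((e < 0) | (e >= grid.n_electrodes))
    if bad.size:
        raise FormatError(f"electrode index {e[bad[0]]} out of range", path=path, line=int(bad[0]) + 2)
    r_expect, c_expect = np.divmod(e, grid.n_cols)
    bad = np.flatnonzero((df["row"].to_numpy() != r_expect) | (df["col"].to_numpy() != c_expect))
    if bad.size:
        raise FormatError("row/col inconsistent with electrode index", path=path, line=int(bad[0]) + 2)
    bad = np.flatnonzero((t < 0) | (t >= duration))
    if bad.size:
        raise FormatError(
            f"timestamp {t[bad[0]]} outside [0, {duration})", path=path, line=int(bad[0]) + 2
        )
    # Per-electrode monotonicity in file order.
    same = np.flatnonzero((e[1:] == e[:-1]) & (t[1:] <= t[:-1]))
    if same.size:
        raise FormatError(
            f"non-increasing timestamps on electrode {e[same[0] + 1]}", path=path, line=int(same[0]) + 3
        )

    order = np.argsort(e, kind="stable")
    e_sorted, t_sorted = e[order], t[order]
    spikes: dict[int, np.ndarray] = {}
    if e_sorted.size:
        bounds = np.flatnonzero(np.diff(e_sorted)) + 1
        for chunk_e, chunk_t in zip(np.split(e_sorted, bounds), np.split(t_sorted, bounds)):
            spikes[int(chunk_e[0])] = chunk_t
    return SpikeTrainSet(spikes=spikes, duration=duration, grid=grid, metadata=dict(meta.get("metadata", {})))
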