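"""Localization of learning populations from stimulus-evoked responses.

Per (electrode, trial) the response/stimulus (R/S) ratio is the fraction of
the trial's stimuli whose evoked spike count strictly exceeds the network-mean
count for that stimulus, and the response time (RT) is the trial mean of the
average latency of the first three post-stimulus spikes inside the analysis
window.  Electrodes whose R/S trend slope over the learning-phase trials is
positive and whose RT trend slope is negative form the learning population.
Marginal inter-spike-interval (ISI) entropy quantifies the information share
carried by that population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import ActiveElectrodeSet, SpikeTrainSet
from .errors import ConfigError
from .protocol import ResponseWindow, StimulusLog, effective_window_ends

__all__ = [
    "TrialResponseTable",
    "TrendFit",
    "LearningPopulationMap",
    "EntropyEntry",
    "response_flag",
    "response_time",
    "build_trial_response_table",
    "fit_trial_trend",
    "localize",
    "isi_entropy",
    "isi_entropy_map",
    "entropy_ratio",
]


def response_flag(spike_count: float, network_mean_count: float) -> bool:
    """True iff the electrode's count strictly exceeds the network mean."""
    return spike_count > network_mean_count


def response_time(latencies) -> Optional[float]:
    """Mean of the first up-to-three latencies; None for an empty window."""
    lat = np.asarray(latencies, dtype=float)
    if lat.size == 0:
        return None
    return float(lat[: min(3, lat.size)].mean())


@dataclass
class TrialResponseTable:
    electrodes: np.ndarray  # (E,) flat indices, sorted
    counts: np.ndarray  # (E, S) spikes per stimulus window
    flags: np.ndarray  # (E, S) bool, count > network mean
    stim_rt: np.ndarray  # (E, S) RT per stimulus, NaN when no spike
    network_mean: np.ndarray  # (S,)
    trial_of_stim: np.ndarray  # (S,) 0-based global trial index
    n_trials: int
    rs: np.ndarray  # (E, T)
    mean_rt: np.ndarray  # (E, T), NaN when undefined


def build_trial_response_table(
    s: SpikeTrainSet,
    log: StimulusLog,
    w: ResponseWindow = ResponseWindow(),
    active: ActiveElectrodeSet | None = None,
) -> TrialResponseTable:
    """Evoked counts, response flags, per-stimulus RT and per-trial summaries."""
    if active is None:
        from .core import active_electrodes

        active = active_electrodes(s)
    electrodes = np.array(active.sorted, dtype=int)
    if electrodes.size == 0:
        raise ConfigError("no active electrodes")
    times = log.times
    ends = effective_window_ends(log, w)
    S = times.size
    E = electrodes.size

    counts = np.zeros((E, S), dtype=np.int64)
    stim_rt = np.full((E, S), np.nan)
    lo_b = times + w.artifact_blank
    hi_b = times + ends
    for i, e in enumerate(electrodes):
        t = s.spikes.get(int(e))
        if t is None or t.size == 0:
            continue
        lo = np.searchsorted(t, lo_b, side="right")
        hi = np.searchsorted(t, hi_b, side="right")
        c = hi - lo
        counts[i] = c
        # Mean of the first min(3, c) latencies, vectorized over stimuli.
        pad = np.concatenate([t, [np.nan, np.nan, np.nan]])
        firsts = np.stack([pad[np.minimum(lo + k, t.size + k)] for k in range(3)])
        k_used = np.minimum(c, 3)
        with np.errstate(invalid="ignore"):
            take = np.where(np.arange(3)[:, None] < k_used[None, :], firsts, 0.0)
            sums = take.sum(axis=0)
            rt = np.where(k_used > 0, sums / np.maximum(k_used, 1) - times, np.nan)
        stim_rt[i] = rt

    network_mean = counts.mean(axis=0)
    flags = counts > network_mean[None, :]

    trial_of_stim = log.global_trials
    n_trials = int(trial_of_stim.max()) + 1
    rs = np.zeros((E, n_trials))
    mean_rt = np.full((E, n_trials), np.nan)
    for tr in range(n_trials):
        cols = trial_of_stim == tr
        n_stim = int(cols.sum())
        rs[:, tr] = flags[:, cols].sum(axis=1) / n_stim
        block = stim_rt[:, cols]
        defined = ~np.isnan(block)
        n_def = defined.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean_rt[:, tr] = np.where(n_def > 0, np.nansum(block, axis=1) / np.maximum(n_def, 1), np.nan)

    return TrialResponseTable(
        electrodes=electrodes,
        counts=counts,
        flags=flags,
        stim_rt=stim_rt,
        network_mean=network_mean,
        trial_of_stim=trial_of_stim,
        n_trials=n_trials,
        rs=rs,
        mean_rt=mean_rt,
    )


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r: float
    r2: float
    p: float
    n: int


def fit_trial_trend(values, min_defined_trials: int = 8) -> Optional[TrendFit]:
    """OLS of a per-trial series against the 1-based trial index.

    NaN entries are skipped; returns None when fewer than
    ``min_defined_trials`` values are defined.
    """
    y = np.asarray(values, dtype=float)
    x = np.arange(1, y.size + 1, dtype=float)
    ok = ~np.isnan(y)
    n = int(ok.sum())
    if n < max(min_defined_trials, 2):
        return None
    x, y = x[ok], y[ok]
    mx, my = x.mean(), y.mean()
    dx, dy = x - mx, y - my
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    sxy = float(dx @ dy)
    slope = sxy / sxx
    intercept = my - slope * mx
    if syy == 0.0:
        r = 0.0
    else:
        r = sxy / np.sqrt(sxx * syy)
    r2 = r * r
    if n > 2 and r2 < 1.0:
        t = r * np.sqrt((n - 2) / (1.0 - r2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    elif r2 >= 1.0:
        p = 0.0
    else:
        p = float("nan")
    return TrendFit(slope=float(slope), intercept=float(intercept), r=float(r), r2=float(r2), p=p, n=n)


@dataclass
class LearningPopulationMap:
    electrodes: np.ndarray
    rs_slope: np.ndarray
    rs_r2: np.ndarray
    rs_p: np.ndarray
    rt_slope: np.ndarray  # NaN where undefined
    rt_r2: np.ndarray
    rt_p: np.ndarray
    rt_n_defined: np.ndarray
    rs_mask: np.ndarray  # rising R/S criterion
    rt_mask: np.ndarray  # falling RT criterion
    learning_mask: np.ndarray  # intersection

    def learning_electrodes(self) -> list[int]:
        return [int(e) for e in self.electrodes[self.learning_mask]]

    def to_frame(self, grid) -> pd.DataFrame:
        rows, cols = zip(*(grid.rc(int(e)) for e in self.electrodes))
        return pd.DataFrame(
            {
                "electrode": self.electrodes,
                "row": rows,
                "col": cols,
                "rs_slope": self.rs_slope,
                "rt_slope": self.rt_slope,
                "rs_r2": self.rs_r2,
                "rt_r2": self.rt_r2,
                "is_learning": self.learning_mask.astype(int),
            }
        )


def localize(
    table: TrialResponseTable,
    min_defined_trials: int = 8,
    significance_alpha: float | None = None,
) -> LearningPopulationMap:
    """Intersect the rising-R/S and falling-RT criteria per electrode.

    The default criterion is the slope sign alone; ``significance_alpha``
    optionally additionally requires the two-sided slope p-value of both fits
    to fall below the given level.
    """
    E = table.electrodes.size
    rs_slope = np.full(E, np.nan)
    rs_r2 = np.full(E, np.nan)
    rs_p = np.full(E, np.nan)
    rt_slope = np.full(E, np.nan)
    rt_r2 = np.full(E, np.nan)
    rt_p = np.full(E, np.nan)
    rt_n = np.zeros(E, dtype=int)
    rs_mask = np.zeros(E, dtype=bool)
    rt_mask = np.zeros(E, dtype=bool)
    for i in range(E):
        f_rs = fit_trial_trend(table.rs[i], min_defined_trials=min_defined_trials)
        if f_rs is not None:
            rs_slope[i], rs_r2[i], rs_p[i] = f_rs.slope, f_rs.r2, f_rs.p
            rs_mask[i] = f_rs.slope > 0
            if significance_alpha is not None:
                rs_mask[i] &= np.isfinite(f_rs.p) and f_rs.p < significance_alpha
        f_rt = fit_trial_trend(table.mean_rt[i], min_defined_trials=min_defined_trials)
        rt_n[i] = int(np.sum(~np.isnan(table.mean_rt[i])))
        if f_rt is not None:
            rt_slope[i], rt_r2[i], rt_p[i] = f_rt.slope, f_rt.r2, f_rt.p
            rt_mask[i] = f_rt.slope < 0
            if significance_alpha is not None:
                rt_mask[i] &= np.isfinite(f_rt.p) and f_rt.p < significance_alpha
    return LearningPopulationMap(
        electrodes=table.electrodes,
        rs_slope=rs_slope,
        rs_r2=rs_r2,
        rs_p=rs_p,
        rt_slope=rt_slope,
        rt_r2=rt_r2,
        rt_p=rt_p,
        rt_n_defined=rt_n,
        rs_mask=rs_mask,
        rt_mask=rt_mask,
        learning_mask=rs_mask & rt_mask,
    )


@dataclass(frozen=True)
class EntropyEntry:
    entropy: float  # bits
    probs: np.ndarray  # includes the overflow bin; sums to 1
    n_bins: int


def isi_entropy(spikes, bin_width: float = 10.0, max_isi: float = 1000.0) -> Optional[EntropyEntry]:
    """Shannon entropy (bits) of the binned ISI distribution of one train.

    ISIs are histogrammed on ``[0, max_isi)`` at ``bin_width`` with a single
    overflow bin for ISIs >= ``max_isi``; ``0 * log2(0) := 0``.  None when the
    train has fewer than two spikes.
    """
    if bin_width <= 0 or max_isi <= bin_width:
        raise ConfigError("require bin_width > 0 and max_isi > bin_width")
    t = np.asarray(spikes, dtype=float)
    if t.size < 2:
        return None
    isi = np.diff(t)
    n_regular = int(np.ceil(max_isi / bin_width))
    idx = np.minimum((isi // bin_width).astype(int), n_regular)
    probs = np.bincount(idx, minlength=n_regular + 1).astype(float)
    probs /= probs.sum()
    nz = probs[probs > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return EntropyEntry(entropy=entropy, probs=probs, n_bins=n_regular + 1)


def isi_entropy_map(
    s: SpikeTrainSet, active: ActiveElectrodeSet, bin_width: float = 10.0, max_isi: float = 1000.0
) -> Dict[int, float]:
    """Per-electrode ISI entropy over the active set; undefined electrodes omitted."""
    out: Dict[int, float] = {}
    for e in active.sorted:
        entry = isi_entropy(s.train(e), bin_width=bin_width, max_isi=max_isi)
        if entry is not None:
            out[e] = entry.entropy
    return out


def entropy_ratio(learning_electrodes, entropies: Dict[int, float], mode: str = "sum") -> Optional[float]:
    """Share of population ISI entropy carried by the learning electrodes.

    ``mode='sum'`` (headline) uses sums of per-electrode entropies; ``'mean'``
    uses the ratio of means.  Returns None when the global aggregate is zero.
    """
    if mode not in {"sum", "mean"}:
        raise ConfigError("mode must be 'sum' or 'mean'")
    if not entropies:
        return None
    learn = [entropies[e] for e in learning_electrodes if e in entropies]
    total = list(entropies.values())
    if mode == "sum":
        denom = float(np.sum(total))
        num = float(np.sum(learn)) if learn else 0.0
    else:
        denom = float(np.mean(total))
        num = float(np.mean(learn)) if learn else 0.0
    if denom == 0.0:
        return None
    return num / denom
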