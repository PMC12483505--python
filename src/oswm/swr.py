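"""Population-burst-event (PBE) detection from CA1 multiunit activity.

Sharp-wave ripples are detected as population bursts: all CA1 spikes are
binned at 10 ms, smoothed with a Gaussian kernel (sigma = 2 bins), min-max
standardised to [0, 1] over the session, and a burst is any period whose
standardised peak reaches 0.35 with both edges above 0.15. Bursts separated
by less than 30 ms are merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .intervals import IntervalSet

__all__ = [
    "MuaTrace",
    "PbeEvent",
    "bin_mua",
    "smooth_standardize",
    "detect_pbes",
    "restrict_events",
]


@dataclass
class MuaTrace:
    """Binned multiunit spike counts (raw or smoothed/standardised)."""

    bin_centers: np.ndarray
    values: np.ndarray
    bin_width: float
    standardized: bool = False

    @property
    def bin_edges(self) -> np.ndarray:
        return np.append(
            self.bin_centers - self.bin_width / 2,
            self.bin_centers[-1] + self.bin_width / 2,
        )


@dataclass
class PbeEvent:
    """One population burst: half-open [start, end) plus its peak."""

    start: float
    end: float
    peak_time: float
    peak_value: float


def bin_mua(ca1_spike_trains, bin: float = 0.010, t_start: float = None,
            t_end: float = None) -> MuaTrace:
    """Total CA1 spike counts per 10 ms bin over the session span.

    Bins are half-open, so a spike exactly on an edge lands in the later bin.
    """
    trains = list(ca1_spike_trains)
    if not trains:
        raise ValueError("need at least one CA1 unit")
    all_t = [u.spike_times for u in trains if u.n_spikes]
    if not all_t:
        warnings.warn("no CA1 spikes; returning an all-zero trace")
        edges = np.arange(0.0, bin * 2, bin)
        centers = (edges[:-1] + edges[1:]) / 2
        return MuaTrace(centers, np.zeros(len(centers)), bin)
    t = np.concatenate(all_t)
    lo = 0.0 if t_start is None else t_start
    hi = (float(t.max()) + bin) if t_end is None else t_end
    n_bins = int(np.ceil((hi - lo) / bin))
    edges = lo + np.arange(n_bins + 1) * bin
    counts, _ = np.histogram(t, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return MuaTrace(centers, counts.astype(float), bin)


def smooth_standardize(trace: MuaTrace, sigma_bins: float = 2.0) -> MuaTrace:
    """Gaussian-smooth (sigma in bins, truncated at 4 sigma) then min-max scale.

    The kernel is renormalised at the edges (reflect-free 'constant' padding
    with explicit normalisation), and the smoothed trace is scaled so its
    session-wide minimum maps to 0 and maximum to 1. A constant trace scales
    to all zeros with a warning.
    """
    v = np.asarray(trace.values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty trace")
    sm = gaussian_filter1d(v, sigma_bins, mode="constant", cval=0.0, truncate=4.0)
    norm = gaussian_filter1d(
        np.ones_like(v), sigma_bins, mode="constant", cval=0.0, truncate=4.0
    )
    sm = sm / norm
    lo, hi = float(sm.min()), float(sm.max())
    if hi - lo <= 1e-12 * max(1.0, abs(hi)):
        warnings.warn("constant MUA trace; standardized trace is all zeros")
        out = np.zeros_like(sm)
    else:
        out = (sm - lo) / (hi - lo)
    return MuaTrace(trace.bin_centers, out, trace.bin_width, standardized=True)


def detect_pbes(trace: MuaTrace, peak_thr: float = 0.35, edge_thr: float = 0.15,
                merge_gap: float = 0.030) -> list:
    """Population bursts from a standardised MUA trace.

    A burst is a maximal run of bins with value >= ``edge_thr`` containing at
    least one bin >= ``peak_thr``; bursts whose gap is < ``merge_gap`` are
    merged (the merged peak is the max of the members). Event bounds are the
    outer bin edges of the run, half-open.
    """
    if not trace.standardized:
        raise ValueError("detect_pbes needs a standardised trace")
    v = trace.values
    above = v >= edge_thr
    if not np.any(above):
        return []
    # run boundaries of the above-edge mask
    d = np.diff(above.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)  # exclusive bin index
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(v))
    half = trace.bin_width / 2
    events = []
    for s, e in zip(starts, ends):
        seg = v[s:e]
        pk = int(np.argmax(seg))
        if seg[pk] >= peak_thr:
            events.append(
                PbeEvent(
                    start=trace.bin_centers[s] - half,
                    end=trace.bin_centers[e - 1] + half,
                    peak_time=float(trace.bin_centers[s + pk]),
                    peak_value=float(seg[pk]),
                )
            )
    # merge close events
    merged = []
    for ev in events:
        if merged and ev.start - merged[-1].end < merge_gap:
            prev = merged[-1]
            if ev.peak_value > prev.peak_value:
                pk_t, pk_v = ev.peak_time, ev.peak_value
            else:
                pk_t, pk_v = prev.peak_time, prev.peak_value
            merged[-1] = PbeEvent(prev.start, ev.end, pk_t, pk_v)
        else:
            merged.append(ev)
    return merged


def restrict_events(events, intervals: IntervalSet) -> list:
    """Keep events whose peak time falls inside the interval set (half-open)."""
    if len(intervals) == 0:
        return []
    peaks = np.array([ev.peak_time for ev in events])
    if len(peaks) == 0:
        return []
    keep = intervals.contains(peaks)
    return [ev for ev, k in zip(events, keep) if k]
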