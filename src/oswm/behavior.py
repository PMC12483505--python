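"""Behavioural quantification: stop masks, delay periods, poke curves.

The delay period of a trial is the 2 s before the observer's first rewarded
poke in the box. Stop periods (speed < 5 cm/s sustained > 3 s) are excluded
from all running-rate computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import PositionSeries, TrialRecord
from .intervals import IntervalSet

__all__ = [
    "stop_mask",
    "delay_period",
    "poke_performance_curve",
    "maze_performance",
    "PokeCurve",
]


@dataclass
class PokeCurve:
    """Normalised poke rate vs time relative to the demonstrator's maze poke."""

    bin_centers: np.ndarray  # s, relative to the Demo poke (time 0)
    values: np.ndarray       # normalised rate per 0.25 s bin
    n_trials: int


def stop_mask(position: PositionSeries, v_thresh: float = 5.0,
              min_dur: float = 3.0) -> IntervalSet:
    """Maximal intervals where speed stays below ``v_thresh`` for > ``min_dur``.

    Intervals run from the first slow sample to the first fast sample after
    the run (half-open); a run still slow at the end of the series closes at
    the last sample time.
    """
    t = position.t
    if len(t) == 0:
        return IntervalSet()
    slow = position.speed < v_thresh
    out = []
    i = 0
    n = len(t)
    while i < n:
        if slow[i]:
            j = i
            while j + 1 < n and slow[j + 1]:
                j += 1
            end = t[j + 1] if j + 1 < n else t[j]
            if end - t[i] > min_dur:
                out.append((t[i], end))
            i = j + 1
        else:
            i += 1
    return IntervalSet(out)


def delay_period(trial: TrialRecord, duration: float = 2.0):
    """The ``[t_ob_poke - duration, t_ob_poke)`` observation-delay window."""
    if trial.t_ob_poke is None:
        raise ValueError(f"trial {trial.trial_id} has no t_ob_poke")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return (trial.t_ob_poke - duration, trial.t_ob_poke)


def poke_performance_curve(ob_pokes, demo_poke_times, bin: float = 0.25,
                           window=(-10.0, 10.0), per_trial: bool = False) -> PokeCurve:
    """Histogram of observer poke times aligned to the Demo poke (time 0).

    ``ob_pokes`` is a sequence of per-trial poke-time arrays; each trial is
    aligned by its own ``demo_poke_times`` entry. The curve is normalised to
    sum to 1 over the window; with ``per_trial=True`` each trial's histogram
    is normalised before averaging instead.
    """
    if len(ob_pokes) == 0:
        raise ValueError("need at least one trial")
    if len(ob_pokes) != len(demo_poke_times):
        raise ValueError("ob_pokes and demo_poke_times must align per trial")
    edges = np.arange(window[0], window[1] + bin / 2, bin)
    centers = (edges[:-1] + edges[1:]) / 2.0
    per = np.zeros((len(ob_pokes), len(centers)))
    for i, (pokes, t0) in enumerate(zip(ob_pokes, demo_poke_times)):
        rel = np.asarray(pokes, dtype=float) - t0
        per[i], _ = np.histogram(rel, bins=edges)
    if per_trial:
        sums = per.sum(axis=1, keepdims=True)
        ok = sums[:, 0] > 0
        if not np.any(ok):
            warnings.warn("no pokes in window; returning all-zero curve")
            return PokeCurve(centers, np.zeros(len(centers)), len(ob_pokes))
        values = np.mean(per[ok] / sums[ok], axis=0)
    else:
        total = per.sum()
        if total == 0:
            warnings.warn("no pokes in window; returning all-zero curve")
            return PokeCurve(centers, np.zeros(len(centers)), len(ob_pokes))
        values = per.sum(axis=0) / total
    return PokeCurve(centers, values, len(ob_pokes))


def maze_performance(trials) -> float:
    """Fraction of correct trials in the session."""
    trials = list(trials)
    if not trials:
        raise ValueError("need at least one trial")
    return sum(tr.correct for tr in trials) / len(trials)
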