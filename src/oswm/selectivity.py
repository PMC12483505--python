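"""Side-selectivity of single units: rates, SI/DI, permutation nulls.

The selectivity index of a unit with mean rates ``FR_left`` and ``FR_right``
is ``SI = (FR_right - FR_left) / (FR_right + FR_left)``, bounded in [-1, 1].
A unit is *selective* when its per-trial left and right rates differ by a
two-sided two-sample t-test at alpha. The same functional form applied to
correct- vs error-trial rates gives the difference index DI.

Population-level chance of same/opposite-side selectivity is assessed by
permuting each cell's delay-period rates across trials, re-classifying, and
z-scoring the observed fraction against 1000 reshuffled fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .behavior import delay_period, stop_mask
from .data_model import SessionData, other_side
from .intervals import IntervalSet

__all__ = [
    "lap_rate",
    "selectivity_index",
    "difference_index",
    "classify_selectivity",
    "same_side_fraction",
    "shuffle_selectivity_null",
    "correct_error_analysis",
    "maze_trial_rates",
    "delay_trial_rates",
    "SelectivityResult",
    "DifferenceResult",
    "PermutationNull",
    "CellRates",
]


@dataclass
class SelectivityResult:
    unit_id: str
    context: str  # 'maze' or 'box'
    fr_left: np.ndarray
    fr_right: np.ndarray
    mean_left: float
    mean_right: float
    si: float
    p_value: float
    label: str  # 'left' | 'right' | 'nonselective'
    flag: str = ""

    @property
    def selective(self) -> bool:
        return self.label != "nonselective"


@dataclass
class DifferenceResult:
    unit_id: str
    mean_correct: float
    mean_error: float
    di: float
    n_error: int
    p_value: float


@dataclass
class PermutationNull:
    observed: float
    null: np.ndarray
    z: float
    p: float
    flag: str = ""


@dataclass
class CellRates:
    """Per-trial delay (or lap) rates of one cell, with trial labels."""

    unit_id: str
    rates: np.ndarray        # Hz, one per trial
    sides: np.ndarray        # 'left'/'right' per trial
    correct: np.ndarray      # bool per trial
    maze_label: str = ""     # the cell's maze selectivity label
    pref_side: str = ""      # alias of maze_label for error analyses


def lap_rate(spike_times, laps: IntervalSet, stops: Optional[IntervalSet] = None) -> float:
    """Mean rate over lap intervals with stop periods excluded."""
    run = laps.subtract(stops) if stops is not None and len(stops) else laps
    dur = run.total_duration()
    if dur <= 0:
        raise ValueError("no running time left after stop exclusion")
    return run.count(np.asarray(spike_times, dtype=float)) / dur


def selectivity_index(fr_left: float, fr_right: float) -> float:
    """(FR_right - FR_left) / (FR_right + FR_left); NaN when both are 0."""
    if fr_left < 0 or fr_right < 0:
        raise ValueError("rates must be >= 0")
    tot = fr_left + fr_right
    if tot == 0:
        return float("nan")
    return (fr_right - fr_left) / tot


def difference_index(rate_correct: float, rate_error: float) -> float:
    """(correct - error) / (correct + error); NaN when both are 0."""
    if rate_correct < 0 or rate_error < 0:
        raise ValueError("rates must be >= 0")
    tot = rate_correct + rate_error
    if tot == 0:
        return float("nan")
    return (rate_correct - rate_error) / tot


def classify_selectivity(left_rates, right_rates, alpha: float = 0.05,
                         unit_id: str = "", context: str = "maze",
                         equal_var: bool = True) -> SelectivityResult:
    """Two-sided two-sample t-test on per-trial rates; label the higher side.

    With fewer than two trials on a side the cell is returned nonselective
    with an ``insufficient_data`` flag rather than raising.
    """
    lr = np.asarray(left_rates, dtype=float)
    rr = np.asarray(right_rates, dtype=float)
    ml = float(np.mean(lr)) if len(lr) else float("nan")
    mr = float(np.mean(rr)) if len(rr) else float("nan")
    si = selectivity_index(ml, mr) if len(lr) and len(rr) else float("nan")
    if len(lr) < 2 or len(rr) < 2:
        return SelectivityResult(
            unit_id, context, lr, rr, ml, mr, si, float("nan"),
            "nonselective", flag="insufficient_data",
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(lr, rr, equal_var=equal_var)
    if not np.isfinite(p):  # zero variance in both groups
        p = 1.0 if ml == mr else 0.0
    label = "nonselective"
    if p < alpha:
        label = "right" if mr > ml else "left"
    return SelectivityResult(unit_id, context, lr, rr, ml, mr, si, float(p), label)


# ----------------------------------------------------------------------
# session-level rate extraction
# ----------------------------------------------------------------------


def maze_trial_rates(session: SessionData, unit, stops: Optional[IntervalSet] = None,
                     correct_only: bool = True):
    """Per-trial running rates on the left and right maze sides.

    Each trial contributes one rate on the side the observer actually ran
    (outbound and inbound laps combined, stop periods excluded).
    """
    if stops is None:
        stops = stop_mask(session.position)
    left, right = [], []
    for tr in session.trials:
        if correct_only and not tr.correct:
            continue
        laps = IntervalSet()
        for traj, ivs in tr.maze_laps.items():
            if traj.startswith(tr.run_side):
                laps = laps.union(ivs)
        if len(laps) == 0:
            continue
        try:
            r = lap_rate(unit.spike_times, laps, stops)
        except ValueError:
            continue
        (left if tr.run_side == "left" else right).append(r)
    return np.asarray(left), np.asarray(right)


def delay_trial_rates(session: SessionData, unit, duration: float = 2.0) -> CellRates:
    """Per-trial firing rates in the delay window before the rewarded poke."""
    rates, sides, correct = [], [], []
    for tr in session.trials:
        if tr.t_ob_poke is None:
            continue
        d0, d1 = delay_period(tr, duration)
        n = np.count_nonzero(
            (unit.spike_times >= d0) & (unit.spike_times < d1)
        )
        rates.append(n / duration)
        sides.append(tr.side)
        correct.append(tr.correct)
    return CellRates(
        unit.unit_id,
        np.asarray(rates, dtype=float),
        np.asarray(sides, dtype=object),
        np.asarray(correct, dtype=bool),
    )


# ----------------------------------------------------------------------
# same/opposite-side statistics
# ----------------------------------------------------------------------


def same_side_fraction(maze_results, box_results):
    """Same/opposite-side fractions over maze-selective cells, plus SI r.

    Returns a dict with counts, fractions, and the Pearson correlation of
    (maze SI, box SI) over the maze-selective cells.
    """
    box_by_id = {r.unit_id: r for r in box_results}
    sel = [r for r in maze_results if r.selective]
    n_same = n_opp = 0
    si_pairs = []
    for r in sel:
        b = box_by_id.get(r.unit_id)
        if b is None:
            raise ValueError(f"no box result for maze-selective cell {r.unit_id}")
        if np.isfinite(r.si) and np.isfinite(b.si):
            si_pairs.append((r.si, b.si))
        if not b.selective:
            continue
        if b.label == r.label:
            n_same += 1
        else:
            n_opp += 1
    n_sel = len(sel)
    out = {
        "n_selective": n_sel,
        "n_same": n_same,
        "n_opposite": n_opp,
        "frac_same": n_same / n_sel if n_sel else float("nan"),
        "frac_opposite": n_opp / n_sel if n_sel else float("nan"),
        "si_r": float("nan"),
        "si_p": float("nan"),
    }
    if len(si_pairs) >= 3:
        arr = np.asarray(si_pairs)
        if np.std(arr[:, 0]) > 0 and np.std(arr[:, 1]) > 0:
            r, p = stats.pearsonr(arr[:, 0], arr[:, 1])
            out["si_r"], out["si_p"] = float(r), float(p)
    else:
        warnings.warn("fewer than 3 selective cells; SI correlation skipped")
    return out


def _student_t_p(sum_l, sumsq_l, n_l, sum_r, sumsq_r, n_r):
    """Vectorised equal-variance two-sample t-test (two-sided p)."""
    ml = sum_l / n_l
    mr = sum_r / n_r
    ssl = sumsq_l - n_l * ml**2
    ssr = sumsq_r - n_r * mr**2
    df = n_l + n_r - 2
    sp2 = (ssl + ssr) / df
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mr - ml) / np.sqrt(sp2 * (1.0 / n_l + 1.0 / n_r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(p), p, np.where(mr == ml, 1.0, 0.0))
    return mr - ml, p


def shuffle_selectivity_null(cells, n_shuffles: int = 1000, rng=None,
                             relation: str = "same", alpha: float = 0.05,
                             correct_only: bool = True) -> PermutationNull:
    """Chance level of the same(/opposite)-side selective fraction.

    ``cells`` are :class:`CellRates` for every maze-selective cell (delay
    rates, trial sides, and the cell's maze label). Each shuffle permutes
    every cell's delay rates across the pooled left+right trials,
    re-classifies box selectivity, and recounts the fraction whose box label
    matches (``relation='same'``) or opposes the maze label. The observed
    fraction is z-scored against the null; p is the one-sided normal tail.
    """
    if rng is None:
        rng = np.random.default_rng()
    if relation not in ("same", "opposite"):
        raise ValueError("relation must be 'same' or 'opposite'")
    n_cells = len(cells)
    if n_cells == 0:
        raise ValueError("no cells supplied")
    hits_obs = 0
    null_hits = np.zeros(n_shuffles)
    for cell in cells:
        keep = cell.correct if correct_only else np.ones(len(cell.rates), bool)
        r = cell.rates[keep]
        sides = cell.sides[keep]
        n_l = int(np.sum(sides == "left"))
        n_r = int(np.sum(sides == "right"))
        if n_l < 2 or n_r < 2:
            continue
        want = cell.maze_label if relation == "same" else other_side(cell.maze_label)
        # observed box classification
        res = classify_selectivity(r[sides == "left"], r[sides == "right"], alpha)
        if res.selective and res.label == want:
            hits_obs += 1
        # permutations: left group = first n_l entries of each permuted row
        perm = rng.permuted(
            np.broadcast_to(r, (n_shuffles, len(r))).copy(), axis=1
        )
        lpart, rpart = perm[:, :n_l], perm[:, n_l:]
        diff, p = _student_t_p(
            lpart.sum(1), (lpart**2).sum(1), n_l,
            rpart.sum(1), (rpart**2).sum(1), n_r,
        )
        sig = p < alpha
        label_right = diff > 0
        hit = sig & (label_right if want == "right" else ~label_right)
        null_hits += hit
    observed = hits_obs / n_cells
    null = null_hits / n_cells
    sd = float(np.std(null))
    flag = ""
    if sd == 0:
        p_val = (1.0 + np.sum(null >= observed)) / (n_shuffles + 1.0)
        z = float("nan")
        flag = "degenerate_null_sd_zero"
        warnings.warn("null distribution has zero sd; using empirical rank p")
    else:
        z = (observed - float(np.mean(null))) / sd
        p_val = float(stats.norm.sf(z))
    return PermutationNull(observed, null, z, float(p_val), flag)


# ----------------------------------------------------------------------
# correct vs error trials
# ----------------------------------------------------------------------


@dataclass
class ErrorAnalysis:
    results: list               # DifferenceResult per analysable cell
    mean_di: float
    t: float
    p: float                    # two-sided one-sample t-test of DI vs 0
    frac_sig_positive: float
    null: Optional[PermutationNull] = None
    excluded: list = field(default_factory=list)


def correct_error_analysis(cells, min_errors: int = 3, side: str = "preferred",
                           alpha: float = 0.05, n_shuffles: int = 1000,
                           rng=None) -> ErrorAnalysis:
    """Correct-vs-error delay-rate difference for same-side selective cells.

    For each cell, delay rates on its preferred (or non-preferred) side are
    split by trial outcome; cells whose session has fewer than ``min_errors``
    error trials on that side are excluded. Reports per-cell DI and t-test,
    the population mean DI with a two-sided one-sample t-test against 0, and
    the fraction of individually significant positive-DI cells against a
    correct/error label-permutation null.
    """
    if rng is None:
        rng = np.random.default_rng()
    results, excluded = [], []
    per_cell_rates = []
    for cell in cells:
        pref = cell.pref_side or cell.maze_label
        use_side = pref if side == "preferred" else other_side(pref)
        m = cell.sides == use_side
        rates = cell.rates[m]
        corr = cell.correct[m]
        n_err = int(np.sum(~corr))
        if n_err < min_errors or np.sum(corr) < 2:
            excluded.append((cell.unit_id, f"n_error={n_err}"))
            continue
        rc, re = rates[corr], rates[~corr]
        di = difference_index(float(np.mean(rc)), float(np.mean(re)))
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(rc, re)
        if not np.isfinite(p):
            p = 1.0
        results.append(
            DifferenceResult(
                cell.unit_id, float(np.mean(rc)), float(np.mean(re)),
                di, n_err, float(p),
            )
        )
        per_cell_rates.append((rates, int(np.sum(corr))))
    dis = np.array([r.di for r in results if np.isfinite(r.di)])
    if len(dis) >= 2 and np.std(dis) > 0:
        t_pop, p_pop = stats.ttest_1samp(dis, 0.0)
    else:
        t_pop, p_pop = float("nan"), float("nan")
    n_res = len(results)
    frac_sig = (
        sum(1 for r in results if r.p_value < alpha and r.di > 0) / n_res
        if n_res
        else float("nan")
    )
    null = None
    if n_res:
        null_hits = np.zeros(n_shuffles)
        for rates, n_corr in per_cell_rates:
            perm = rng.permuted(
                np.broadcast_to(rates, (n_shuffles, len(rates))).copy(), axis=1
            )
            cpart, epart = perm[:, :n_corr], perm[:, n_corr:]
            n_e = len(rates) - n_corr
            diff, p = _student_t_p(
                epart.sum(1), (epart**2).sum(1), n_e,
                cpart.sum(1), (cpart**2).sum(1), n_corr,
            )
            null_hits += (p < alpha) & (diff > 0)  # diff = correct - error
        null_frac = null_hits / n_res
        sd = float(np.std(null_frac))
        if sd == 0:
            pz = (1.0 + np.sum(null_frac >= frac_sig)) / (n_shuffles + 1.0)
            null = PermutationNull(frac_sig, null_frac, float("nan"), pz,
                                   "degenerate_null_sd_zero")
        else:
            z = (frac_sig - float(np.mean(null_frac))) / sd
            null = PermutationNull(frac_sig, null_frac, z,
                                   float(stats.norm.sf(z)))
    mean_di = float(np.mean(dis)) if len(dis) else float("nan")
    return ErrorAnalysis(results, mean_di, float(t_pop), float(p_pop),
                         frac_sig, null, excluded)
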