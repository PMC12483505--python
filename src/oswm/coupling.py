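"""ACC-CA1 interaction statistics.

Couples each side-selective ACC cell with the CA1 ensemble on the same or
opposite side of its maze selectivity:

- lag-resolved cross-correlation of 200 ms binned rates within delay
  periods (the lag-0 value is the cell's statistic);
- trial-by-trial Pearson correlation of the ACC water-period rate with the
  ensemble's in-burst rate during the same water period;
- trial-by-trial correlation of the ACC delay rate with the ensemble's
  in-burst water rate, with per-trial replay counts, and with the cell's own
  water rate (self-continuation).

Population summaries are one-sample t-tests of the per-cell statistics
against 0 and paired t-tests of same vs opposite side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SessionData, other_side
from .selectivity import delay_trial_rates

__all__ = [
    "binned_rates",
    "ensemble_spike_times",
    "delay_crosscorr",
    "swr_rate_per_trial",
    "trial_correlation",
    "coupling_battery",
    "CouplingResult",
]

# sidedness of the population test for each analysis, as reported per figure
ANALYSIS_SIDEDNESS = {
    "delay_xcorr_lag0": "two",
    "water_swr_trial_corr": "one",
    "delay_to_swr_trial_corr": "two",
    "delay_to_replay_count_in": "one",
    "delay_to_replay_count_out": "one",
    "delay_to_water_self": "two",
}


@dataclass
class CouplingResult:
    acc_unit_id: str
    relation: str   # 'same' | 'opposite' | 'self'
    analysis: str
    r: float
    n: int


def binned_rates(spike_times, interval, bin: float = 0.200) -> np.ndarray:
    """Spike counts per half-open bin tiling the interval.

    Only whole bins are used; the interval must cover at least one bin.
    For an ensemble, pass the aggregated spike times of all members.
    """
    s, e = float(interval[0]), float(interval[1])
    n_bins = int(np.floor((e - s) / bin + 1e-9))
    if n_bins < 1:
        raise ValueError("interval shorter than one bin")
    st = np.asarray(spike_times, dtype=float)
    edges = s + np.arange(n_bins + 1) * bin
    counts, _ = np.histogram(st, bins=edges)
    return counts.astype(float)


def ensemble_spike_times(session: SessionData, ensemble) -> np.ndarray:
    """Aggregated, sorted spike times of every ensemble member."""
    parts = [session.unit(uid).spike_times for uid in ensemble.unit_ids]
    if not parts:
        return np.empty(0)
    return np.sort(np.concatenate(parts))


def _corr(a: np.ndarray, b: np.ndarray):
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return None
    am = a - a.mean()
    bm = b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


def delay_crosscorr(acc_rates_per_trial, ens_rates_per_trial,
                    max_lag_bins: int = 5, mode: str = "per_trial"):
    """Cross-correlation of binned rates at lags -max..+max bins.

    Positive lag means the ensemble trace is shifted later: a peak at +1
    indicates the ensemble follows the ACC cell by one bin. ``per_trial``
    correlates within each trial and averages across trials (trials with a
    constant vector at a lag are skipped); ``concatenated`` pools the
    overlapping segments of all trials into one correlation per lag.

    Returns ``(lags, curve, lag0, n_trials_used)``.
    """
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    pairs = [
        (np.asarray(a, float), np.asarray(b, float))
        for a, b in zip(acc_rates_per_trial, ens_rates_per_trial)
    ]
    curve = np.full(len(lags), np.nan)
    used = 0
    for li, lag in enumerate(lags):
        seg_a, seg_b, rs = [], [], []
        for a, b in pairs:
            n = min(len(a), len(b))
            a, b = a[:n], b[:n]
            if lag >= 0:
                aa, bb = a[: n - lag] if lag else a, b[lag:]
            else:
                aa, bb = a[-lag:], b[: n + lag]
            if len(aa) < 3:
                continue
            if mode == "per_trial":
                r = _corr(aa, bb)
                if r is not None:
                    rs.append(r)
            else:
                seg_a.append(aa)
                seg_b.append(bb)
        if mode == "per_trial":
            if rs:
                curve[li] = float(np.mean(rs))
                if lag == 0:
                    used = len(rs)
        else:
            if seg_a:
                r = _corr(np.concatenate(seg_a), np.concatenate(seg_b))
                curve[li] = np.nan if r is None else r
                if lag == 0:
                    used = len(seg_a)
    lag0 = float(curve[max_lag_bins])
    return lags, curve, lag0, used


def swr_rate_per_trial(ens_spikes, pbes, water_interval):
    """Ensemble rate inside the water period's bursts (Hz), or None.

    Total ensemble spikes inside the trial's bursts divided by total burst
    duration; ``None`` when the trial's water period contains no burst.
    """
    ws, we = water_interval
    evs = [ev for ev in pbes if ws <= ev.peak_time < we]
    if not evs:
        return None
    total = 0
    dur = 0.0
    for ev in evs:
        i0, i1 = np.searchsorted(ens_spikes, [ev.start, ev.end])
        total += i1 - i0
        dur += ev.end - ev.start
    return total / dur


def trial_correlation(x, y, sidedness: str = "two"):
    """Pearson r over pairwise-complete trials with a one/two-sided p.

    The one-sided p tests for positive correlation. Returns ``(nan, nan)``
    with fewer than three complete pairs or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    if sidedness == "one":
        p = p / 2.0 if r > 0 else 1.0 - p / 2.0
    return float(r), float(p)


def _population_tests(df: pd.DataFrame) -> pd.DataFrame:
    """One-sample t vs 0 per (analysis, relation) and paired same-vs-opposite."""
    rows = []
    for analysis, sub in df.groupby("analysis"):
        sided = ANALYSIS_SIDEDNESS.get(analysis, "two")
        for relation, grp in sub.groupby("relation"):
            vals = grp["r"].to_numpy()
            vals = vals[np.isfinite(vals)]
            if len(vals) < 2 or np.std(vals) == 0:
                continue
            t, p = stats.ttest_1samp(vals, 0.0)
            if sided == "one":
                p = p / 2.0 if t > 0 else 1.0 - p / 2.0
            rows.append(
                dict(analysis=analysis, comparison=f"{relation}_vs_0",
                     mean=float(np.mean(vals)),
                     sem=float(stats.sem(vals)), t=float(t), p=float(p),
                     sidedness=sided, n=len(vals))
            )
        same = sub[sub.relation == "same"].set_index("acc_unit_id")["r"]
        opp = sub[sub.relation == "opposite"].set_index("acc_unit_id")["r"]
        common = same.index.intersection(opp.index)
        a = same.loc[common].to_numpy()
        b = opp.loc[common].to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        if np.sum(ok) >= 2 and np.std(a[ok] - b[ok]) > 0:
            t, p = stats.ttest_rel(a[ok], b[ok])
            rows.append(
                dict(analysis=analysis, comparison="same_vs_opposite_paired",
                     mean=float(np.mean(a[ok] - b[ok])),
                     sem=float(stats.sem(a[ok] - b[ok])), t=float(t),
                     p=float(p), sidedness="two", n=int(np.sum(ok)))
            )
    return pd.DataFrame(
        rows,
        columns=["analysis", "comparison", "mean", "sem", "t", "p",
                 "sidedness", "n"],
    )


def coupling_battery(session: SessionData, maze_results, ensembles,
                     pbes, replay_counts=None, delay_duration: float = 2.0,
                     bin: float = 0.200, max_lag_bins: int = 5,
                     xcorr_mode: str = "per_trial", analyses=None):
    """All ACC-CA1 coupling statistics for the session's selective cells.

    ``maze_results`` are the ACC maze :class:`SelectivityResult`s,
    ``ensembles`` the ``(left, right)`` CA1 ensembles, ``pbes`` the detected
    bursts, and ``replay_counts`` the optional per-trial replay-count table.
    ``analyses`` optionally restricts computation to a subset of the
    analysis names. Returns ``(per_cell_df, population_df)``.
    """
    def want(name):
        return analyses is None or name in analyses

    left_ens, right_ens = ensembles
    ens_by_side = {"left": left_ens, "right": right_ens}
    ens_spk = {
        s: ensemble_spike_times(session, e) for s, e in ens_by_side.items()
    }
    trials = [tr for tr in session.trials if tr.t_ob_poke is not None]
    water_trials = [tr for tr in trials if tr.water_interval is not None]

    # per-trial ensemble in-burst rates (shared across ACC cells)
    swr_rate = {
        s: np.array(
            [
                np.nan
                if (r := swr_rate_per_trial(ens_spk[s], pbes, tr.water_interval))
                is None
                else r
                for tr in water_trials
            ]
        )
        for s in ("left", "right")
    }

    rows = []
    for res in maze_results:
        if not res.selective:
            continue
        unit = session.unit(res.unit_id)
        cell_rates = delay_trial_rates(session, unit, delay_duration)
        acc_delay = cell_rates.rates
        acc_water = np.array(
            [
                np.count_nonzero(
                    (unit.spike_times >= tr.water_interval[0])
                    & (unit.spike_times < tr.water_interval[1])
                )
                / (tr.water_interval[1] - tr.water_interval[0])
                for tr in water_trials
            ]
        )
        # delay rates aligned to the water-trial list
        poke_by_id = {tr.trial_id: i for i, tr in enumerate(trials)}
        acc_delay_w = np.array(
            [acc_delay[poke_by_id[tr.trial_id]] for tr in water_trials]
        )
        for relation in ("same", "opposite"):
            side = res.label if relation == "same" else other_side(res.label)
            # (a) lag-0 cross-correlation within delay periods
            if want("delay_xcorr_lag0"):
                acc_bins, ens_bins = [], []
                for tr in trials:
                    d0, d1 = tr.t_ob_poke - delay_duration, tr.t_ob_poke
                    if d1 - d0 < bin:
                        continue
                    acc_bins.append(
                        binned_rates(unit.spike_times, (d0, d1), bin)
                    )
                    ens_bins.append(binned_rates(ens_spk[side], (d0, d1), bin))
                _, _, lag0, n_used = delay_crosscorr(
                    acc_bins, ens_bins, max_lag_bins, xcorr_mode
                )
                rows.append(CouplingResult(res.unit_id, relation,
                                           "delay_xcorr_lag0", lag0, n_used))
            # (b) water ACC rate vs ensemble in-burst rate, per trial
            if want("water_swr_trial_corr"):
                r, _ = trial_correlation(acc_water, swr_rate[side])
                rows.append(
                    CouplingResult(
                        res.unit_id, relation, "water_swr_trial_corr", r,
                        int(np.sum(np.isfinite(swr_rate[side]))))
                )
            # (c) delay ACC rate vs ensemble in-burst water rate
            if want("delay_to_swr_trial_corr"):
                r, _ = trial_correlation(acc_delay_w, swr_rate[side])
                rows.append(
                    CouplingResult(res.unit_id, relation,
                                   "delay_to_swr_trial_corr", r,
                                   int(np.sum(np.isfinite(swr_rate[side]))))
                )
            # (d) delay ACC rate vs per-trial replay counts (in/out templates)
            if replay_counts is not None:
                for inout in ("in", "out"):
                    if not want(f"delay_to_replay_count_{inout}"):
                        continue
                    col = f"{side}_{inout}"
                    cnts = np.array(
                        [
                            replay_counts.loc[tr.trial_id, col]
                            if tr.trial_id in replay_counts.index
                            else np.nan
                            for tr in water_trials
                        ],
                        dtype=float,
                    )
                    r, _ = trial_correlation(acc_delay_w, cnts)
                    rows.append(
                        CouplingResult(
                            res.unit_id, relation,
                            f"delay_to_replay_count_{inout}", r,
                            int(np.sum(np.isfinite(cnts))),
                        )
                    )
        # (e) self-continuation: delay rate vs own water rate
        if want("delay_to_water_self"):
            r, _ = trial_correlation(acc_delay_w, acc_water)
            rows.append(
                CouplingResult(res.unit_id, "self", "delay_to_water_self", r,
                               len(acc_water))
            )

    df = pd.DataFrame(
        [vars(c) for c in rows],
        columns=["acc_unit_id", "relation", "analysis", "r", "n"],
    )
    pop = _population_tests(df) if len(df) else pd.DataFrame(
        columns=["analysis", "comparison", "mean", "sem", "t", "p",
                 "sidedness", "n"]
    )
    return df, pop
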