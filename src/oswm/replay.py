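"""Place-cell templates and Bayesian replay decoding of population bursts.

For each of the four linearised trajectories (left/right x outbound/inbound)
every CA1 unit gets a spatial firing-rate curve f_i(x) (spikes per unit
occupancy during active running). Units whose curve peak reaches three
standard deviations above the curve mean form that trajectory's template;
the left/right ensembles are the unions of a side's two templates.

A population burst with at least four active template members is a candidate
event. It is decoded with a memoryless Poisson model in sliding 20 ms
windows (10 ms step): under independent Poisson spiking and a uniform
spatial prior,

    P(x | n) ~ prod_i (tau f_i(x))^(n_i) exp(-tau f_i(x)),

normalised per window (computed in the log domain). The decoded position is
the per-window posterior argmax; the Pearson correlation r of decoded
position against window index, compared with 1000 shuffles of the window
indices, gives the replay significance. Events with p < 0.05 are replays,
forward if r > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import logsumexp

from .behavior import stop_mask
from .data_model import TRAJECTORIES, SessionData, side_of
from .intervals import IntervalSet

__all__ = [
    "RateCurve",
    "Template",
    "Ensemble",
    "DecodedEvent",
    "linearized_rate_curve",
    "build_template",
    "build_all_templates",
    "build_ensembles",
    "find_candidates",
    "decode_event",
    "replay_significance",
    "replay_counts_per_trial",
    "traj_lap_intervals",
]


@dataclass
class RateCurve:
    """Spatial firing-rate curve of one unit on one trajectory."""

    unit_id: str
    traj_id: str
    bin_centers: np.ndarray   # cm
    rates: np.ndarray         # Hz; NaN where occupancy was zero

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.rates)

    @property
    def peak(self) -> float:
        v = self.rates[self.valid]
        return float(np.max(v)) if len(v) else float("nan")

    @property
    def mean(self) -> float:
        v = self.rates[self.valid]
        return float(np.mean(v)) if len(v) else float("nan")

    @property
    def sd(self) -> float:
        v = self.rates[self.valid]
        return float(np.std(v)) if len(v) else float("nan")


@dataclass
class Template:
    traj_id: str
    unit_ids: list
    curves: dict  # unit_id -> RateCurve

    def __len__(self):
        return len(self.unit_ids)

    @property
    def side(self) -> str:
        return side_of(self.traj_id)


@dataclass
class Ensemble:
    side: str
    unit_ids: list

    def __len__(self):
        return len(self.unit_ids)


@dataclass
class DecodedEvent:
    pbe_id: int
    traj_id: str
    start: float
    end: float
    peak_time: float
    window_starts: np.ndarray
    counts: np.ndarray          # members x windows
    posterior: np.ndarray       # space x windows (NaN columns for empty wins)
    decoded_pos: np.ndarray     # cm per window, NaN when excluded
    r: float = float("nan")
    p: float = float("nan")
    is_replay: bool = False
    direction: str = ""
    flag: str = ""

    @property
    def active_windows(self) -> np.ndarray:
        return np.isfinite(self.decoded_pos)


def traj_lap_intervals(session: SessionData, traj_id: str,
                       correct_only: bool = False) -> IntervalSet:
    """Union of all lap intervals of one trajectory across trials."""
    out = IntervalSet()
    for tr in session.trials:
        if correct_only and not tr.correct:
            continue
        ivs = tr.maze_laps.get(traj_id)
        if ivs is not None:
            out = out.union(ivs)
    return out


def _renorm_smooth(v: np.ndarray, sigma: float) -> np.ndarray:
    sm = gaussian_filter1d(v, sigma, mode="constant", cval=0.0, truncate=4.0)
    norm = gaussian_filter1d(
        np.ones_like(v), sigma, mode="constant", cval=0.0, truncate=4.0
    )
    return sm / norm


def linearized_rate_curve(unit, position, laps: IntervalSet, traj_id: str,
                          stops: Optional[IntervalSet] = None,
                          spatial_bin: float = 2.0, smooth_sigma: float = 2.0,
                          track_length: float = 200.0) -> RateCurve:
    """Spatial rate curve: spikes per occupancy per 2 cm bin, smoothed.

    Occupancy and spike counts are restricted to active running (lap
    intervals minus stop periods) on the given trajectory; both maps are
    smoothed with the same Gaussian (sigma in bins) before dividing. Bins
    never visited stay NaN.
    """
    run = laps.subtract(stops) if stops is not None and len(stops) else laps
    edges = np.arange(0.0, track_length + spatial_bin / 2, spatial_bin)
    centers = (edges[:-1] + edges[1:]) / 2.0
    m = (position.traj_id == traj_id) & run.contains(position.t)
    ts = position.t[m]
    xs = position.lin_pos[m]
    if len(ts) == 0:
        return RateCurve(unit.unit_id, traj_id, centers,
                         np.full(len(centers), np.nan))
    dt = float(np.median(np.diff(position.t))) if len(position.t) > 1 else 0.0
    occ, _ = np.histogram(xs, bins=edges)
    occ = occ * dt
    spk = unit.spike_times[run.contains(unit.spike_times)]
    if len(spk):
        # nearest tracked sample on this trajectory gives the spike position
        idx = np.clip(np.searchsorted(ts, spk), 1, len(ts) - 1)
        idx = np.where(spk - ts[idx - 1] <= ts[idx] - spk, idx - 1, idx)
        close = np.abs(ts[idx] - spk) <= 2.0 * dt
        sx = xs[idx[close]]
        cnt, _ = np.histogram(sx, bins=edges)
    else:
        cnt = np.zeros(len(centers))
    occ_s = _renorm_smooth(occ.astype(float), smooth_sigma)
    cnt_s = _renorm_smooth(cnt.astype(float), smooth_sigma)
    visited = _renorm_smooth((occ > 0).astype(float), smooth_sigma) > 1e-12
    rates = np.full(len(centers), np.nan)
    ok = visited & (occ_s > 0)
    rates[ok] = cnt_s[ok] / occ_s[ok]
    return RateCurve(unit.unit_id, traj_id, centers, rates)


def build_template(curves, n_sd: float = 3.0) -> Template:
    """Template of one trajectory: units whose curve peak clears mean + 3 sd.

    A degenerate (constant or all-invalid) curve never qualifies because the
    criterion additionally requires peak > mean.
    """
    members, kept = [], {}
    traj = curves[0].traj_id if curves else ""
    for c in curves:
        if not np.any(c.valid):
            continue
        if c.peak > c.mean and c.peak >= c.mean + n_sd * c.sd:
            members.append(c.unit_id)
            kept[c.unit_id] = c
    return Template(traj, members, kept)


def build_all_templates(session: SessionData, spatial_bin: float = 2.0,
                        smooth_sigma: float = 2.0, track_length: float = 200.0,
                        n_sd: float = 3.0, rate_band=(0.4, 10.0)) -> dict:
    """Rate curves and templates for the four trajectories.

    Only CA1 units active in the maze (mean running rate inside
    ``rate_band``, the putative-pyramidal inclusion band) are considered.
    """
    stops = stop_mask(session.position)
    all_laps = IntervalSet()
    for traj in TRAJECTORIES:
        all_laps = all_laps.union(traj_lap_intervals(session, traj))
    run = all_laps.subtract(stops)
    dur = run.total_duration()
    active = []
    for u in session.ca1_units:
        if dur <= 0:
            continue
        mean_rate = run.count(u.spike_times) / dur
        if rate_band[0] <= mean_rate <= rate_band[1]:
            active.append(u)
    templates = {}
    for traj in TRAJECTORIES:
        laps = traj_lap_intervals(session, traj)
        curves = [
            linearized_rate_curve(
                u, session.position, laps, traj, stops,
                spatial_bin, smooth_sigma, track_length,
            )
            for u in active
        ]
        templates[traj] = build_template(curves, n_sd)
    return templates


def build_ensembles(templates: dict):
    """Left/right ensembles: union of a side's inbound and outbound members."""
    out = {}
    for side in ("left", "right"):
        ids = sorted(
            set(templates[f"{side}_out"].unit_ids)
            | set(templates[f"{side}_in"].unit_ids)
        )
        out[side] = Ensemble(side, ids)
    return out["left"], out["right"]


def find_candidates(pbes, template: Template, spikes_by_unit: dict,
                    min_active: int = 4) -> list:
    """Bursts in which at least ``min_active`` template members fire."""
    out = []
    for ev in pbes:
        n_active = 0
        for uid in template.unit_ids:
            st = spikes_by_unit[uid]
            i0, i1 = np.searchsorted(st, [ev.start, ev.end])
            if i1 > i0:
                n_active += 1
                if n_active >= min_active:
                    break
        if n_active >= min_active:
            out.append(ev)
    return out


def _event_windows(start: float, end: float, tau: float, step: float):
    """Sliding windows tiling [start, end); trailing kept if >= tau/2."""
    starts, lengths = [], []
    k = 0
    while True:
        s = start + k * step
        if s >= end:
            break
        ln = min(tau, end - s)
        if ln < tau / 2:
            break
        starts.append(s)
        lengths.append(ln)
        k += 1
    return np.asarray(starts), np.asarray(lengths)


def decode_event(pbe, template: Template, spikes_by_unit: dict, pbe_id: int = 0,
                 tau: float = 0.020, step: float = 0.010,
                 include_empty: bool = False,
                 rate_floor: float = 0.01) -> DecodedEvent:
    """Poisson Bayesian posterior over template positions per sliding window.

    Computation is in the log domain; window posteriors are normalised to
    sum to 1. Windows with no member spikes carry no sequence information
    (their posterior only reflects exp(-tau f)) and are excluded from the
    decoded-position series unless ``include_empty``. Rates are floored at
    ``rate_floor`` Hz so an unvisited-looking bin cannot zero out a window.
    """
    if len(template) == 0:
        raise ValueError("empty template")
    wstarts, wlens = _event_windows(pbe.start, pbe.end, tau, step)
    n_w = len(wstarts)
    members = template.unit_ids
    curves = [template.curves[uid] for uid in members]
    valid = np.logical_and.reduce([c.valid for c in curves])
    if not np.any(valid):
        raise ValueError("template curves share no valid spatial bin")
    x = curves[0].bin_centers[valid]
    f = np.stack([np.maximum(c.rates[valid], rate_floor) for c in curves])
    log_f = np.log(f)                      # members x space
    sum_f = f.sum(axis=0)                  # space

    counts = np.zeros((len(members), n_w), dtype=int)
    for i, uid in enumerate(members):
        st = spikes_by_unit[uid]
        counts[i] = (
            np.searchsorted(st, wstarts + wlens) - np.searchsorted(st, wstarts)
        )
    # log L(x; window) = sum_i n_i log(tau_w f_i(x)) - tau_w sum_i f_i(x)
    log_post = counts.T @ log_f - np.outer(wlens, sum_f)
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    posterior = np.exp(log_post).T         # space x windows

    decoded = x[np.argmax(posterior, axis=0)].astype(float)
    empty = counts.sum(axis=0) == 0
    if not include_empty:
        decoded[empty] = np.nan
        posterior[:, empty] = np.nan
    flag = ""
    if np.all(empty):
        flag = "undecodable_no_spikes"
    return DecodedEvent(
        pbe_id=pbe_id,
        traj_id=template.traj_id,
        start=pbe.start,
        end=pbe.end,
        peak_time=pbe.peak_time,
        window_starts=wstarts,
        counts=counts,
        posterior=posterior,
        decoded_pos=decoded,
        flag=flag,
    )


def replay_significance(decoded: DecodedEvent, n_shuffles: int = 1000,
                        rng=None, alpha: float = 0.05,
                        mode: str = "two_sided") -> DecodedEvent:
    """Shuffle test of the decoded-position sequence; fills r/p/is_replay.

    r is the Pearson correlation of decoded positions against their window
    indices; the null permutes the window indices ``n_shuffles`` times. By
    default significance is two-sided on |r| (both replay directions are of
    interest); ``mode='one_sided'`` tests the tail in the direction of the
    observed r. p uses the (1 + hits) / (n + 1) estimator so it is never 0.
    """
    if rng is None:
        rng = np.random.default_rng()
    act = decoded.active_windows
    pos = decoded.decoded_pos[act]
    idx = np.nonzero(act)[0].astype(float)
    if len(pos) < 4:
        decoded.flag = (decoded.flag + ";" if decoded.flag else "") + \
            "insufficient_windows"
        decoded.is_replay = False
        return decoded
    if np.std(pos) == 0 or np.std(idx) == 0:
        decoded.flag = (decoded.flag + ";" if decoded.flag else "") + \
            "constant_positions"
        decoded.is_replay = False
        return decoded
    pc = pos - pos.mean()
    ic = idx - idx.mean()
    denom = np.sqrt((pc**2).sum() * (ic**2).sum())
    r = float((pc * ic).sum() / denom)
    perm = rng.permuted(
        np.broadcast_to(ic, (n_shuffles, len(ic))).copy(), axis=1
    )
    r_sh = perm @ pc / denom
    if mode == "two_sided":
        hits = np.sum(np.abs(r_sh) >= abs(r))
    elif mode == "one_sided":
        hits = np.sum(r_sh >= r) if r >= 0 else np.sum(r_sh <= r)
    else:
        raise ValueError(f"unknown mode: {mode}")
    p = (1.0 + hits) / (n_shuffles + 1.0)
    decoded.r = r
    decoded.p = float(p)
    decoded.is_replay = p < alpha
    decoded.direction = "forward" if r > 0 else "reverse"
    return decoded


def replay_counts_per_trial(trials, decoded_events) -> "pd.DataFrame":
    """Significant replays per (trial x template), counted in water periods.

    A burst significant for several templates increments each of them.
    """
    import pandas as pd

    counts = {
        tr.trial_id: {traj: 0 for traj in TRAJECTORIES} for tr in trials
    }
    for ev in decoded_events:
        if not ev.is_replay:
            continue
        for tr in trials:
            if tr.water_interval is None:
                continue
            ws, we = tr.water_interval
            if ws <= ev.peak_time < we:
                counts[tr.trial_id][ev.traj_id] += 1
                break
    df = pd.DataFrame.from_dict(counts, orient="index")
    df.index.name = "trial_id"
    return df[list(TRAJECTORIES)]
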