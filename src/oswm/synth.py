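"""Synthetic observational spatial working-memory sessions with ground truth.

The generator emulates the structure of an observer-rat session: ~40 trials,
each with a demonstrator maze run, a short (~2 s) observation delay ending at
the observer's first rewarded poke, a water-consumption period in the box,
and the observer's own out-and-back maze run on the chosen side. It plants:

- CA1 place cells with Gaussian fields on the linearised trajectories of one
  maze side (inhomogeneous Poisson spiking via thinning);
- ACC cells with side-selective rate steps during maze running and the delay
  window, attenuated on preferred-side error trials;
- sharp-wave-ripple-like population bursts during water consumption carrying
  time-compressed forward/reverse replay of a trajectory template, riding on
  a multiunit surge so a population-burst detector can find them;
- a trial-wise lognormal gain shared (with tunable correlation) between an
  ACC cell's delay/water rates and its same-side CA1 ensemble's in-burst
  rates, giving coupling analyses a known target.

Everything is driven by one seeded ``numpy.random.Generator``; identical
parameters and seed give byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    PositionSeries,
    SessionData,
    SpikeTrain,
    TrialRecord,
    other_side,
)
from .intervals import IntervalSet

__all__ = [
    "SynthParams",
    "GroundTruth",
    "generate_session",
    "place_field_rate",
    "simulate_inhomogeneous_poisson",
    "simulate_piecewise_constant",
    "embed_replay",
    "write_ground_truth",
    "load_ground_truth",
]


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic session generator.

    Defaults describe a typical session: 40 trials, half left, ~11% errors,
    2 s delay windows (plus an exponential tail), 64 s of self-running per
    trial, CA1 place cells in the 0.4-10 Hz mean-rate band, and about two
    population bursts per water period.
    """

    n_trials: int = 40
    p_left: float = 0.5
    p_error: float = 0.11
    delay_duration: float = 2.0       # s, the analysed delay window
    delay_jitter: float = 0.5         # s, exponential tail on the poke latency
    lap_duration: float = 64.0        # s of self-running per trial (out + in)
    water_duration: float = 10.0      # s of water consumption per trial
    track_length: float = 200.0       # cm, linearised trajectory length
    fs: float = 30.0                  # Hz, position sampling rate

    n_ca1: int = 30
    n_acc: int = 20
    field_width_sigma: float = 5.0    # cm, Gaussian place-field width
    field_peak_rate: float = 10.0     # Hz, in-field peak above baseline
    baseline_rate: float = 0.3        # Hz, CA1 baseline everywhere

    acc_base_rate: float = 1.0        # Hz, ACC outside task epochs
    acc_maze_rate: float = 2.0        # Hz, ACC on non-preferred maze side
    acc_box_rate: float = 3.0         # Hz, ACC delay rate, non-preferred side
    acc_water_rate: float = 3.0       # Hz, ACC during water consumption
    acc_selectivity_ratio: float = 3.0  # preferred/non-preferred rate ratio
    acc_error_attenuation: float = 0.5  # delay-rate factor on error trials

    swr_per_water_period: float = 2.0  # mean bursts per water period
    replay_bias: float = 0.8          # P(replay uses the trial's own side)
    replay_duration: float = 0.15     # s, compressed replay length
    replay_jitter_sd: float = 0.005   # s, jitter on member spike times
    replay_boost: float = 40.0        # fold gain on member fields in a burst
    surge_rate: float = 32.0          # Hz/unit non-member CA1 rate in bursts
    min_swr_separation: float = 0.5   # s between burst starts

    coupling_strength: float = 0.4    # latent corr. of ACC vs CA1 trial gains
    gain_sd: float = 0.6              # sigma of the lognormal trial gain
    gain_mix: float = 0.15            # damping of the gain on in-burst rates

    seed: int = 0

    @property
    def replay_compression(self) -> float:
        """Fold time-compression of a replay relative to a real lap."""
        return (self.lap_duration / 2.0) / self.replay_duration

    def validate(self) -> None:
        for name in ("p_left", "p_error", "replay_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "field_peak_rate",
            "baseline_rate",
            "acc_base_rate",
            "acc_maze_rate",
            "acc_box_rate",
            "acc_water_rate",
            "surge_rate",
            "replay_boost",
            "swr_per_water_period",
            "acc_error_attenuation",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.field_width_sigma <= 0:
            raise ValueError("field_width_sigma must be > 0")
        if self.replay_duration <= 0:
            raise ValueError("replay_duration must be > 0")
        if not -1.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must be in [-1, 1]")

    def replace(self, **kw) -> "SynthParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests.

    ``units``: unit_id, region, pref_side, field_center (CA1, outbound cm).
    ``replays``: event_id, trial_id, traj, direction, start, end.
    ``gains``: per trial, the ACC and CA1 lognormal gains for each side.
    """

    units: pd.DataFrame
    replays: pd.DataFrame
    gains: pd.DataFrame


def place_field_rate(lin_pos, center, sigma, peak, baseline):
    """Gaussian place-field tuning: baseline + peak * exp(-(x-c)^2 / 2 sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(lin_pos, dtype=float)
    return baseline + peak * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def simulate_inhomogeneous_poisson(rate_fn, interval, rate_max, rng):
    """Inhomogeneous Poisson spike times on ``[start, end)`` by thinning.

    ``rate_fn`` maps an array of times to instantaneous rates (Hz) and must
    be bounded by ``rate_max`` on the interval.
    """
    start, end = float(interval[0]), float(interval[1])
    if not np.isfinite(rate_max) or rate_max < 0:
        raise ValueError("rate_max must be finite and >= 0")
    if rate_max == 0 or end <= start:
        return np.empty(0)
    n = rng.poisson(rate_max * (end - start))
    if n == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(start, end, size=n))
    rates = np.asarray(rate_fn(cand), dtype=float)
    if np.any(rates > rate_max * (1 + 1e-9)):
        raise ValueError("rate_fn exceeds the stated rate_max")
    keep = rng.uniform(0.0, rate_max, size=n) < rates
    return cand[keep]


def simulate_piecewise_constant(segments, rng):
    """Poisson spike times for piecewise-constant rates.

    ``segments``: iterable of (start, end, rate_hz). Returns sorted times.
    """
    out = []
    for s, e, r in segments:
        if e <= s or r <= 0:
            continue
        n = rng.poisson(r * (e - s))
        if n:
            out.append(rng.uniform(s, e, size=n))
    if not out:
        return np.empty(0)
    return np.sort(np.concatenate(out))


def embed_replay(template_order, t0, duration, direction, jitter_sd, rng,
                 positions=None, track_length=200.0):
    """Spike times for one time-compressed replay of a template.

    ``template_order`` lists member unit ids in template position order.
    ``positions`` optionally gives each member's field position (cm) on the
    trajectory; spike times are laid along the compressed traversal at those
    positions (evenly spaced when omitted), reversed for ``direction ==
    'reverse'``, then jittered and clipped into ``[t0, t0 + duration)``.

    Returns ``(spikes, interval)`` where ``spikes`` maps unit_id -> array of
    times and ``interval`` is the burst window for ground-truth bookkeeping.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if len(template_order) < 4:
        raise ValueError("need >= 4 template members to form a candidate burst")
    if direction not in ("forward", "reverse"):
        raise ValueError(f"unknown direction: {direction}")
    m = len(template_order)
    if positions is None:
        frac = (np.arange(m) + 0.5) / m
    else:
        pos = np.asarray(positions, dtype=float)
        frac = np.clip(pos / track_length, 0.0, 1.0)
    if direction == "reverse":
        frac = 1.0 - frac
    # keep jittered spikes strictly inside the burst window
    times = t0 + frac * duration
    if jitter_sd > 0:
        times = times + rng.normal(0.0, jitter_sd, size=m)
    eps = 1e-6 * duration
    times = np.clip(times, t0, t0 + duration - eps)
    spikes = {uid: np.array([t]) for uid, t in zip(template_order, times)}
    return spikes, (t0, t0 + duration)


# ----------------------------------------------------------------------
# session assembly
# ----------------------------------------------------------------------


def _trial_timeline(params: SynthParams, rng) -> list:
    """Lay out trials sequentially; returns a list of per-trial dicts."""
    half_lap = params.lap_duration / 2.0
    trials = []
    t = 5.0
    for i in range(params.n_trials):
        side = "left" if rng.random() < params.p_left else "right"
        correct = rng.random() >= params.p_error
        t_demo_cp = t + 2.0
        demo_poke_time = t + 4.0
        gap = params.delay_duration + (
            rng.exponential(params.delay_jitter) if params.delay_jitter > 0 else 0.0
        )
        t_ob_poke = t_demo_cp + gap
        water = (t_ob_poke, t_ob_poke + params.water_duration)
        run_side = side if correct else other_side(side)
        out_start = water[1] + 1.0
        out_lap = (out_start, out_start + half_lap)
        in_lap = (out_lap[1], out_lap[1] + half_lap)
        trials.append(
            dict(
                trial_id=i,
                side=side,
                correct=correct,
                t_demo_cp=t_demo_cp,
                demo_poke_time=demo_poke_time,
                t_ob_poke=t_ob_poke,
                water=water,
                run_side=run_side,
                out_lap=out_lap,
                in_lap=in_lap,
            )
        )
        t = in_lap[1] + 2.0
    return trials


def _position_series(params: SynthParams, timeline, t_end) -> PositionSeries:
    L = params.track_length
    half_lap = params.lap_duration / 2.0
    v = L / half_lap
    t = np.arange(0.0, t_end, 1.0 / params.fs)
    x = np.zeros_like(t)
    y = np.full_like(t, 50.0)  # observation box
    traj = np.full(len(t), "none", dtype=object)
    lin = np.full_like(t, np.nan)
    speed = np.zeros_like(t)
    for tr in timeline:
        for lap_key, inout in (("out_lap", "out"), ("in_lap", "in")):
            s, e = tr[lap_key]
            m = (t >= s) & (t < e)
            d = v * (t[m] - s)
            lin[m] = d
            traj[m] = f"{tr['run_side']}_{inout}"
            sign = -1.0 if tr["run_side"] == "left" else 1.0
            x[m] = sign * (d if inout == "out" else L - d)
            y[m] = 0.0
            speed[m] = v
    return PositionSeries(t=t, x=x, y=y, traj_id=traj, lin_pos=lin, speed=speed)


def _draw_gains(params: SynthParams, rng):
    """Latent trial x side normals and the CA1 ensemble gains they drive.

    Each side's CA1 ensemble has one lognormal gain per trial. Every ACC
    cell later gets its own per-trial gain whose latent normal correlates
    with its side's ensemble normal at ``coupling_strength``, so the planted
    ACC-CA1 trial-wise coupling has a known latent correlation while cells
    remain conditionally independent.
    """
    sd = params.gain_sd
    z_side = rng.standard_normal((params.n_trials, 2))  # columns: left, right
    ca1 = np.exp(sd * z_side - sd**2 / 2.0)
    return z_side, ca1


def _burst_gain(params: SynthParams, g):
    """Damped affine gain applied to CA1 in-burst rates.

    An affine map of the lognormal gain preserves its Pearson correlation
    with the ACC gains while keeping burst amplitudes in a band the
    min-max-standardised burst detector can always see.
    """
    return 1.0 + params.gain_mix * (g - 1.0)


def _acc_cell_gain(params: SynthParams, z_side_col, rng):
    """Per-trial gain of one ACC cell, coupled to its side's latent normal."""
    rho = params.coupling_strength
    sd = params.gain_sd
    eps = rng.standard_normal(len(z_side_col))
    z = rho * z_side_col + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
    return np.exp(sd * z - sd**2 / 2.0)


def generate_session(params: SynthParams, rng=None):
    """Generate one synthetic session plus its ground truth.

    Returns ``(SessionData, GroundTruth)``. Reproducible: the same params
    (including seed) always give the same session.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    L = params.track_length
    timeline = _trial_timeline(params, rng)
    t_end = timeline[-1]["in_lap"][1] + 5.0
    half_lap = params.lap_duration / 2.0
    v = L / half_lap

    z_side, ca1_gain = _draw_gains(params, rng)
    side_col = {"left": 0, "right": 1}

    # --- CA1 place cells -------------------------------------------------
    ca1_ids = [f"ca1_{i:03d}" for i in range(params.n_ca1)]
    ca1_side = ["left" if i % 2 == 0 else "right" for i in range(params.n_ca1)]
    centers = np.empty(params.n_ca1)
    for s in ("left", "right"):
        idx = [i for i, sd_ in enumerate(ca1_side) if sd_ == s]
        k = len(idx)
        if k:
            # stratified centres so templates tile the track
            u = rng.uniform(0.2, 0.8, size=k)
            centers[idx] = 5.0 + (L - 10.0) * (np.arange(k) + u) / k

    # --- SWR/replay schedule --------------------------------------------
    replay_rows = []
    swr_per_trial: dict = {i: [] for i in range(params.n_trials)}
    event_id = 0
    for tr in timeline:
        ws, we = tr["water"]
        n_ev = rng.poisson(params.swr_per_water_period)
        span = we - ws - params.replay_duration
        if span <= 0:
            n_ev = 0
        starts = np.empty(0)
        for _ in range(200):
            if n_ev == 0:
                break
            cand = np.sort(rng.uniform(ws, ws + span, size=n_ev))
            if n_ev == 1 or np.all(np.diff(cand) >= params.min_swr_separation):
                starts = cand
                break
        else:
            starts = np.empty(0)
        for t0 in starts:
            same = rng.random() < params.replay_bias
            s = tr["side"] if same else other_side(tr["side"])
            traj = f"{s}_{'out' if rng.random() < 0.5 else 'in'}"
            direction = "forward" if rng.random() < 0.5 else "reverse"
            swr_per_trial[tr["trial_id"]].append(
                dict(
                    event_id=event_id,
                    t0=float(t0),
                    traj=traj,
                    direction=direction,
                    trial_id=tr["trial_id"],
                )
            )
            replay_rows.append(
                dict(
                    event_id=event_id,
                    trial_id=tr["trial_id"],
                    traj=traj,
                    direction=direction,
                    start=float(t0),
                    end=float(t0 + params.replay_duration),
                )
            )
            event_id += 1

    # --- spikes ----------------------------------------------------------
    units = []
    sigma = params.field_width_sigma
    peak = params.field_peak_rate

    # Replay spikes per unit. Template members fire one ordered spike each
    # (the planted sequence) plus extra Poisson spikes whose rate follows
    # their own field along the compressed virtual trajectory, so member
    # activity is sequence-consistent. Non-members of the burst's template
    # carry a uniform multiunit surge so the burst is visible in the MUA.
    member_spikes: dict = {uid: [] for uid in ca1_ids}
    for tid, evs in swr_per_trial.items():
        for ev in evs:
            s = ev["traj"].split("_")[0]
            inbound = ev["traj"].endswith("_in")
            members = [
                (ca1_ids[i], (L - centers[i]) if inbound else centers[i],
                 _burst_gain(params, ca1_gain[tid, side_col[s]]))
                for i in range(params.n_ca1)
                if ca1_side[i] == s
            ]
            members.sort(key=lambda uc: uc[1])
            if len(members) < 4:
                continue
            spikes, _ = embed_replay(
                [uc[0] for uc in members],
                ev["t0"],
                params.replay_duration,
                ev["direction"],
                params.replay_jitter_sd,
                rng,
                positions=[uc[1] for uc in members],
                track_length=L,
            )
            for uid, ts in spikes.items():
                member_spikes[uid].append(ts)
            # path-consistent extra spikes: rate = boost * field(x(t)) * gain
            t0, dur = ev["t0"], params.replay_duration
            vx = L / dur
            for uid, c, g in members:
                amp = params.replay_boost * peak * g

                def rate_fn(ts, _c=c, _amp=amp, _fwd=ev["direction"] == "forward"):
                    x = vx * (ts - t0) if _fwd else L - vx * (ts - t0)
                    return _amp * np.exp(-((x - _c) ** 2) / (2.0 * sigma**2))

                extra = simulate_inhomogeneous_poisson(
                    rate_fn, (t0, t0 + dur), amp, rng
                )
                if len(extra):
                    member_spikes[uid].append(extra)

    for i, uid in enumerate(ca1_ids):
        parts = []
        # baseline everywhere
        if params.baseline_rate > 0:
            parts.append(
                simulate_piecewise_constant([(0.0, t_end, params.baseline_rate)], rng)
            )
        # place field on own-side laps (thinning against the Gaussian bump)
        for tr in timeline:
            if tr["run_side"] != ca1_side[i]:
                continue
            for lap_key, inbound in (("out_lap", False), ("in_lap", True)):
                s, e = tr[lap_key]
                c = (L - centers[i]) if inbound else centers[i]

                def rate_fn(ts, _s=s, _c=c):
                    return peak * np.exp(
                        -((v * (ts - _s) - _c) ** 2) / (2.0 * sigma**2)
                    )

                parts.append(
                    simulate_inhomogeneous_poisson(rate_fn, (s, e), peak, rng)
                )
        # uniform surge inside bursts whose template this cell is not part of
        segs = []
        for tid, evs in swr_per_trial.items():
            h = _burst_gain(params, ca1_gain[tid, side_col[ca1_side[i]]])
            for ev in evs:
                if ev["traj"].split("_")[0] == ca1_side[i]:
                    continue
                segs.append(
                    (ev["t0"], ev["t0"] + params.replay_duration,
                     params.surge_rate * h)
                )
        parts.append(simulate_piecewise_constant(segs, rng))
        parts.extend(member_spikes[uid])
        ts = np.sort(np.concatenate(parts)) if parts else np.empty(0)
        ts = _dedupe(ts)
        units.append(SpikeTrain(uid, "CA1", ts))

    acc_ids = [f"acc_{i:03d}" for i in range(params.n_acc)]
    acc_side = ["left" if i % 2 == 0 else "right" for i in range(params.n_acc)]
    ratio = params.acc_selectivity_ratio
    acc_gain_rows = {}
    for i, uid in enumerate(acc_ids):
        pref = acc_side[i]
        cell_gain = _acc_cell_gain(params, z_side[:, side_col[pref]], rng)
        acc_gain_rows[uid] = cell_gain
        segs = [(0.0, t_end, params.acc_base_rate)]
        for tr in timeline:
            tid = tr["trial_id"]
            g = cell_gain[tid]
            maze_r = params.acc_maze_rate * (ratio if tr["run_side"] == pref else 1.0)
            for lap_key in ("out_lap", "in_lap"):
                s, e = tr[lap_key]
                segs.append((s, e, maze_r - params.acc_base_rate))
            # delay window: side-selective, attenuated on preferred-side errors
            d0 = tr["t_ob_poke"] - params.delay_duration
            delay_r = params.acc_box_rate * (ratio if tr["side"] == pref else 1.0)
            if not tr["correct"] and tr["side"] == pref:
                delay_r *= params.acc_error_attenuation
            segs.append((d0, tr["t_ob_poke"], delay_r * g - params.acc_base_rate))
            ws, we = tr["water"]
            segs.append((ws, we, params.acc_water_rate * g - params.acc_base_rate))
        segs = [(s, e, max(r, 0.0)) for s, e, r in segs]
        ts = _dedupe(simulate_piecewise_constant(segs, rng))
        units.append(SpikeTrain(uid, "ACC", ts))

    # --- assemble --------------------------------------------------------
    position = _position_series(params, timeline, t_end)
    trials = []
    for tr in timeline:
        laps = {
            f"{tr['run_side']}_out": IntervalSet([tr["out_lap"]]),
            f"{tr['run_side']}_in": IntervalSet([tr["in_lap"]]),
        }
        trials.append(
            TrialRecord(
                trial_id=tr["trial_id"],
                side=tr["side"],
                correct=tr["correct"],
                t_demo_cp=tr["t_demo_cp"],
                t_ob_poke=tr["t_ob_poke"],
                demo_poke_time=tr["demo_poke_time"],
                water_interval=tr["water"],
                maze_laps=laps,
            )
        )
    session = SessionData(
        condition="Demo",
        units=units,
        position=position,
        trials=trials,
        meta={"generator": "oswm.synth", "seed": params.seed},
    )

    units_df = pd.DataFrame(
        {
            "unit_id": ca1_ids + acc_ids,
            "region": ["CA1"] * params.n_ca1 + ["ACC"] * params.n_acc,
            "pref_side": ca1_side + acc_side,
            "field_center": list(centers) + [np.nan] * params.n_acc,
        }
    )
    replays_df = pd.DataFrame(
        replay_rows,
        columns=["event_id", "trial_id", "traj", "direction", "start", "end"],
    )
    gains_df = pd.DataFrame(
        {
            "trial_id": np.arange(params.n_trials),
            "ca1_gain_left": ca1_gain[:, 0],
            "ca1_gain_right": ca1_gain[:, 1],
            **{f"acc_gain_{uid}": g for uid, g in acc_gain_rows.items()},
        }
    )
    return session, GroundTruth(units=units_df, replays=replays_df, gains=gains_df)


def _dedupe(ts: np.ndarray) -> np.ndarray:
    """Enforce strictly ascending spike times (collisions get a tiny shift)."""
    if len(ts) < 2:
        return ts
    for _ in range(10):
        d = np.diff(ts)
        if np.all(d > 0):
            return ts
        ts = ts.copy()
        ts[1:][d <= 0] += 1e-7
        ts.sort()
    return np.unique(ts)


def write_ground_truth(gt: GroundTruth, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt.units.to_csv(out / "truth_units.csv", index=False, float_format="%.9g")
    gt.replays.to_csv(out / "truth_replays.csv", index=False, float_format="%.9g")
    gt.gains.to_csv(out / "truth_gains.csv", index=False, float_format="%.9g")


def load_ground_truth(in_dir) -> GroundTruth:
    p = Path(in_dir)
    return GroundTruth(
        units=pd.read_csv(p / "truth_units.csv"),
        replays=pd.read_csv(p / "truth_replays.csv"),
        gains=pd.read_csv(p / "truth_gains.csv"),
    )
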