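"""Rate curves, templates, and the Poisson Bayesian replay decoder."""

import itertools

import numpy as np
import pytest

from oswm.replay import (
    RateCurve,
    Template,
    build_all_templates,
    build_ensembles,
    build_template,
    decode_event,
    find_candidates,
    linearized_rate_curve,
    replay_counts_per_trial,
    replay_significance,
    traj_lap_intervals,
)
from oswm.swr import PbeEvent
from oswm.data_model import PositionSeries, TrialRecord
from oswm.intervals import IntervalSet


def gaussian_template(n_units=8, n_bins=100, spatial_bin=2.0, peak=12.0,
                      baseline=0.1, sigma=6.0, traj="left_out"):
    centers = (np.arange(n_bins) + 0.5) * spatial_bin
    curves = {}
    ids = []
    for i in range(n_units):
        mu = (i + 0.5) / n_units * n_bins * spatial_bin
        rates = baseline + peak * np.exp(-((centers - mu) ** 2) / (2 * sigma**2))
        uid = f"u{i}"
        ids.append(uid)
        curves[uid] = RateCurve(uid, traj, centers, rates)
    return Template(traj, ids, curves)


def sequence_spikes(template, t0=0.0, duration=0.2, reverse=False):
    """One spike per member, ordered along (or against) the field positions."""
    ids = template.unit_ids if not reverse else template.unit_ids[::-1]
    m = len(ids)
    return {uid: np.array([t0 + (k + 0.5) / m * duration])
            for k, uid in enumerate(ids)}


class TestRateCurve:
    def make_position(self, n_laps=20, lap_len=200.0, speed=20.0, fs=30.0):
        t_parts, lin_parts = [], []
        lap_dur = lap_len / speed
        laps = []
        t0 = 0.0
        for _ in range(n_laps):
            tt = np.arange(0.0, lap_dur, 1 / fs)
            t_parts.append(t0 + tt)
            lin_parts.append(speed * tt)
            laps.append((t0, t0 + lap_dur))
            t0 += lap_dur + 5.0
        t = np.concatenate(t_parts)
        lin = np.concatenate(lin_parts)
        pos = PositionSeries(
            t=t, x=lin, y=np.zeros_like(t),
            traj_id=np.array(["left_out"] * len(t), dtype=object),
            lin_pos=lin, speed=np.full(len(t), speed),
        )
        return pos, IntervalSet(laps)

    def test_uniform_rate_gives_flat_curve(self, rng):
        pos, laps = self.make_position()
        # homogeneous 5 Hz unit across all laps
        spikes = np.sort(
            np.concatenate([rng.uniform(s, e, rng.poisson(5 * (e - s)))
                            for s, e in laps])
        )

        class U:
            unit_id = "u"
            spike_times = spikes

        curve = linearized_rate_curve(U(), pos, laps, "left_out")
        v = curve.rates[curve.valid]
        assert np.nanmean(v) == pytest.approx(5.0, rel=0.2)
        assert np.nanstd(v) < 1.5  # flat within sampling error

    def test_field_center_recovered(self, small_session):
        session, gt = small_session
        row = gt.units[(gt.units.region == "CA1")
                       & (gt.units.field_center.between(30, 170))].iloc[0]
        unit = session.unit(row.unit_id)
        traj = f"{row.pref_side}_out"
        laps = traj_lap_intervals(session, traj)
        curve = linearized_rate_curve(unit, session.position, laps, traj)
        peak_x = curve.bin_centers[np.nanargmax(curve.rates)]
        assert abs(peak_x - row.field_center) <= 4.0  # within 2 bins

    def test_no_spikes_gives_zero_curve(self):
        pos, laps = self.make_position(n_laps=3)

        class U:
            unit_id = "u"
            spike_times = np.empty(0)

        curve = linearized_rate_curve(U(), pos, laps, "left_out")
        assert np.all(curve.rates[curve.valid] == 0)


class TestTemplate:
    def make_curve(self, rates, uid="u", traj="left_out"):
        n = len(rates)
        return RateCurve(uid, traj, (np.arange(n) + 0.5) * 2.0,
                         np.asarray(rates, float))

    def test_constant_curve_excluded(self):
        tpl = build_template([self.make_curve(np.full(50, 4.0))])
        assert len(tpl) == 0

    def test_zero_curve_excluded(self):
        tpl = build_template([self.make_curve(np.zeros(50))])
        assert len(tpl) == 0

    def test_sharp_field_included(self):
        x = np.arange(50) * 2.0
        rates = 0.1 + 10 * np.exp(-((x - 50) ** 2) / (2 * 16.0))
        c = self.make_curve(rates)
        assert c.peak >= c.mean + 3 * c.sd  # direct computation
        assert len(build_template([c])) == 1

    def test_ensemble_union(self):
        def tpl(traj, ids):
            return Template(traj, ids, {})

        templates = {
            "left_out": tpl("left_out", ["b", "c"]),
            "left_in": tpl("left_in", ["a", "b"]),
            "right_out": tpl("right_out", ["d"]),
            "right_in": tpl("right_in", ["a"]),
        }
        left, right = build_ensembles(templates)
        assert left.unit_ids == ["a", "b", "c"]
        assert right.unit_ids == ["a", "d"]  # unit on both sides appears twice


class TestCandidates:
    def test_min_active_threshold(self):
        tpl = gaussian_template(6)
        ev = PbeEvent(0.0, 0.2, 0.1, 0.8)
        spk3 = {uid: np.array([0.05]) if i < 3 else np.empty(0)
                for i, uid in enumerate(tpl.unit_ids)}
        spk4 = {uid: np.array([0.05]) if i < 4 else np.empty(0)
                for i, uid in enumerate(tpl.unit_ids)}
        assert find_candidates([ev], tpl, spk3) == []
        assert find_candidates([ev], tpl, spk4) == [ev]


class TestDecode:
    def test_posteriors_sum_to_one(self, rng):
        tpl = gaussian_template()
        spikes = {uid: np.sort(rng.uniform(0, 0.2, rng.poisson(3)))
                  for uid in tpl.unit_ids}
        ev = PbeEvent(0.0, 0.2, 0.1, 0.9)
        dec = decode_event(ev, tpl, spikes)
        act = dec.active_windows
        sums = np.nansum(dec.posterior[:, act], axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_constant_rate_single_unit_gives_uniform_posterior(self):
        c = RateCurve("u", "left_out", (np.arange(40) + 0.5) * 2.0,
                      np.full(40, 4.0))
        tpl = Template("left_out", ["u"], {"u": c})
        dec = decode_event(PbeEvent(0, 0.1, 0.05, 1.0), tpl,
                           {"u": np.array([0.03, 0.05])})
        act = dec.active_windows
        post = dec.posterior[:, act]
        np.testing.assert_allclose(post, 1.0 / 40, atol=1e-12)

    def test_near_delta_field_forces_argmax(self):
        x = (np.arange(50) + 0.5) * 2.0
        rates = 0.01 + 50.0 * (np.abs(x - 61.0) < 1.0)
        c = RateCurve("u", "left_out", x, rates)
        tpl = Template("left_out", ["u"], {"u": c})
        dec = decode_event(PbeEvent(0, 0.1, 0.05, 1.0), tpl,
                           {"u": np.array([0.015])})
        decoded = dec.decoded_pos[dec.active_windows]
        assert np.all(decoded == 61.0)

    def test_log_domain_equals_direct_product(self, rng):
        # small random instances against a direct (linear-domain) oracle
        for _ in range(25):
            tpl = gaussian_template(n_units=5, n_bins=20)
            spikes = {uid: np.sort(rng.uniform(0, 0.1, rng.poisson(2)))
                      for uid in tpl.unit_ids}
            ev = PbeEvent(0.0, 0.1, 0.05, 0.9)
            dec = decode_event(ev, tpl, spikes)
            f = np.stack([np.maximum(tpl.curves[u].rates, 0.01)
                          for u in tpl.unit_ids])
            for w, (ws, act) in enumerate(
                zip(dec.window_starts, dec.active_windows)
            ):
                if not act:
                    continue
                tau = min(0.02, ev.end - ws)
                n = dec.counts[:, w]
                like = np.prod(
                    (tau * f) ** n[:, None] * np.exp(-tau * f), axis=0
                )
                direct = like / like.sum()
                np.testing.assert_allclose(dec.posterior[:, w], direct,
                                           atol=1e-9)

    def test_noiseless_forward_replay_is_monotone(self, rng):
        tpl = gaussian_template()
        spikes = sequence_spikes(tpl)
        dec = decode_event(PbeEvent(0.0, 0.2, 0.1, 1.0), tpl, spikes)
        decoded = dec.decoded_pos[dec.active_windows]
        assert np.all(np.diff(decoded) >= 0)
        dec = replay_significance(dec, 1000, rng)
        assert dec.r > 0.99
        assert dec.p < 0.05
        assert dec.is_replay
        assert dec.direction == "forward"

    def test_noiseless_replay_with_disjoint_windows_has_unit_r(self, rng):
        # one spike per window, near-delta fields equally spaced -> the
        # decoded positions are exactly linear in the window index
        m = 8
        x = (np.arange(50) + 0.5) * 2.0
        ids, curves = [], {}
        for k in range(m):
            c = 10.0 * k + 5.0  # an exact bin centre
            uid = f"u{k}"
            ids.append(uid)
            curves[uid] = RateCurve(
                uid, "left_out", x, 0.01 + 50.0 * (np.abs(x - c) < 1.0)
            )
        tpl = Template("left_out", ids, curves)
        spikes = {uid: np.array([0.01 + 0.02 * k])
                  for k, uid in enumerate(ids)}
        dec = decode_event(PbeEvent(0.0, 0.02 * m, 0.01, 1.0), tpl, spikes,
                           tau=0.02, step=0.02)
        dec = replay_significance(dec, 1000, rng)
        assert dec.r == pytest.approx(1.0, abs=1e-9)
        assert dec.p < 0.05


class TestSignificance:
    def make_decoded(self, positions):
        pos = np.asarray(positions, float)
        n = len(pos)
        return type(
            "D", (), {
                "decoded_pos": pos,
                "active_windows": np.isfinite(pos),
                "flag": "", "r": np.nan, "p": np.nan,
                "is_replay": False, "direction": "",
            },
        )()

    def test_shuffle_p_matches_exact_enumeration(self, rng):
        pos = np.array([10.0, 30.0, 20.0, 50.0, 40.0])
        idx = np.arange(5.0)
        r_obs = np.corrcoef(idx, pos)[0, 1]
        exact = np.mean([
            abs(np.corrcoef(np.array(p), pos)[0, 1]) >= abs(r_obs) - 1e-12
            for p in itertools.permutations(idx)
        ])
        dec = self.make_decoded(pos)
        dec = replay_significance(dec, 4000, rng)
        # (1+hits)/(n+1) estimator vs the exact permutation fraction
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(dec.p - exact) < 4 * se + 1e-3

    def test_reverse_mirror_has_same_p(self):
        pos = np.array([5.0, 12.0, 28.0, 33.0, 47.0, 60.0])
        d_f = replay_significance(self.make_decoded(pos), 500,
                                  np.random.default_rng(9))
        d_r = replay_significance(self.make_decoded(pos[::-1].copy()), 500,
                                  np.random.default_rng(9))
        assert d_f.direction == "forward"
        assert d_r.direction == "reverse"
        assert d_f.p == pytest.approx(d_r.p)
        assert d_f.r == pytest.approx(-d_r.r)

    def test_p_never_zero_and_insufficient_windows_flagged(self, rng):
        pos = np.arange(12.0) * 10
        dec = replay_significance(self.make_decoded(pos), 1000, rng)
        assert 0 < dec.p <= 1
        short = replay_significance(self.make_decoded([1.0, 2.0, 3.0]), 100, rng)
        assert "insufficient_windows" in short.flag
        assert not short.is_replay
        const = replay_significance(self.make_decoded([5.0] * 6), 100, rng)
        assert "constant_positions" in const.flag


class TestShuffleCalibration:
    def test_disjoint_windows_give_nominal_false_replay_rate(self, rng):
        """With non-overlapping decode windows the decoded positions of
        structureless events are exchangeable, so the time-bin permutation
        test fires at its nominal rate. (Overlapping windows share spikes
        and are anti-conservative; see the methods note.)"""
        from scipy import stats
        tpl = gaussian_template(n_units=10)
        n_events, hits = 400, 0
        for _ in range(n_events):
            spikes = {uid: np.sort(rng.uniform(0, 0.16, rng.poisson(0.16 * 25)))
                      for uid in tpl.unit_ids}
            dec = decode_event(PbeEvent(0.0, 0.16, 0.08, 1.0), tpl, spikes,
                               tau=0.02, step=0.02)
            dec = replay_significance(dec, 500, rng)
            hits += dec.is_replay
        lo, hi = stats.binom.interval(0.999, n_events, 0.05)
        assert lo <= hits <= hi


class TestReplayCounts:
    def test_counting_by_water_interval(self):
        trials = [
            TrialRecord(i, "left", True, t_ob_poke=100.0 * i,
                        water_interval=(100.0 * i, 100.0 * i + 10))
            for i in range(8)
        ]

        def ev(traj, t, sig=True):
            return type("E", (), {"traj_id": traj, "peak_time": t,
                                  "is_replay": sig})()

        events = [ev("left_in", 705.0), ev("left_in", 706.0),
                  ev("right_out", 101.0), ev("left_out", 205.0, sig=False)]
        counts = replay_counts_per_trial(trials, events)
        assert counts.loc[7, "left_in"] == 2
        assert counts.loc[1, "right_out"] == 1
        assert counts.loc[2, "left_out"] == 0
        assert counts.to_numpy().sum() == 3


class TestEndToEndRecovery:
    def test_embedded_replays_decoded_with_correct_direction(self, small_session):
        from oswm import swr
        session, gt = small_session
        trace = swr.smooth_standardize(swr.bin_mua(session.ca1_units))
        pbes = swr.detect_pbes(trace)
        templates = build_all_templates(session)
        spikes = {u.unit_id: u.spike_times for u in session.units}
        rng = np.random.default_rng(0)
        hits = total = 0
        for _, ev in gt.replays.iterrows():
            tpl = templates[ev["traj"]]
            if len(tpl) < 4:
                continue
            overlapping = [p for p in pbes
                           if p.start < ev["end"] and p.end > ev["start"]]
            if not overlapping:
                continue
            total += 1
            dec = decode_event(overlapping[0], tpl, spikes)
            dec = replay_significance(dec, 500, rng)
            if dec.is_replay and dec.direction == ev["direction"]:
                hits += 1
        assert total >= 5
        assert hits / total >= 0.8
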