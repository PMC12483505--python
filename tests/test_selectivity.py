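"""Selectivity/difference indices, t-test classification, permutation nulls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oswm.intervals import IntervalSet
from oswm.selectivity import (
    CellRates,
    classify_selectivity,
    correct_error_analysis,
    difference_index,
    lap_rate,
    same_side_fraction,
    selectivity_index,
    shuffle_selectivity_null,
)

rates_st = st.floats(0.0, 100.0, allow_nan=False)


class TestIndices:
    @pytest.mark.parametrize("l,r,si", [(2, 2, 0.0), (0, 3, 1.0), (3, 1, -0.5)])
    def test_si_values(self, l, r, si):
        assert selectivity_index(l, r) == pytest.approx(si)

    @pytest.mark.parametrize("c,e,di", [(4, 4, 0.0), (4, 0, 1.0), (1, 3, -0.5)])
    def test_di_values(self, c, e, di):
        assert difference_index(c, e) == pytest.approx(di)

    def test_zero_zero_is_nan(self):
        assert np.isnan(selectivity_index(0.0, 0.0))
        assert np.isnan(difference_index(0.0, 0.0))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(rates_st, rates_st, st.floats(1e-3, 1e3))
    def test_antisymmetry_scale_invariance_bounds(self, a, b, c):
        if a + b == 0:
            return
        si = selectivity_index(a, b)
        assert -1.0 <= si <= 1.0
        assert selectivity_index(b, a) == pytest.approx(-si, abs=1e-12)
        if (c * a + c * b) > 0:
            assert selectivity_index(c * a, c * b) == pytest.approx(si, abs=1e-9)
        assert difference_index(a, b) == pytest.approx(
            -difference_index(b, a), abs=1e-12
        )


class TestLapRate:
    def test_basic_rate(self):
        laps = IntervalSet([(0.0, 5.0)])
        spikes = np.linspace(0.1, 4.9, 10)
        assert lap_rate(spikes, laps) == pytest.approx(2.0)

    def test_spikes_inside_stops_do_not_count(self):
        laps = IntervalSet([(0.0, 10.0)])
        stops = IntervalSet([(0.0, 10.0)])
        with pytest.raises(ValueError):
            lap_rate([1.0, 2.0], laps, stops)

    def test_interval_subtraction_case(self):
        # two 10 s laps; a stop covers 5 s of lap 1; 30 spikes outside stops
        laps = IntervalSet([(0.0, 10.0), (20.0, 30.0)])
        stops = IntervalSet([(0.0, 5.0)])
        spikes = np.concatenate([
            np.linspace(5.01, 9.99, 15), np.linspace(20.01, 29.99, 15)
        ])
        assert lap_rate(spikes, laps, stops) == pytest.approx(30 / 15)
        # oracle: brute-force membership count over remaining time
        run = laps.subtract(stops)
        assert run.count(spikes) / run.total_duration() == pytest.approx(2.0)


class TestClassify:
    def test_identical_rates_nonselective(self):
        res = classify_selectivity([5.0] * 10, [5.0] * 10)
        assert res.label == "nonselective"
        assert res.si == 0.0

    def test_strong_difference_recovered_and_matches_formula(self, rng):
        lr = rng.normal(1, 0.1, 20)
        rr = rng.normal(5, 0.1, 20)
        res = classify_selectivity(lr, rr)
        assert res.label == "right"
        assert res.p_value < 1e-10
        # independent equal-variance t-test computed from the textbook formula
        n = 20
        sp2 = (lr.var(ddof=1) * (n - 1) + rr.var(ddof=1) * (n - 1)) / (2 * n - 2)
        t = (rr.mean() - lr.mean()) / np.sqrt(sp2 * (2 / n))
        p = 2 * stats.t.sf(abs(t), 2 * n - 2)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_insufficient_trials_flagged(self):
        res = classify_selectivity([1.0], [2.0, 3.0])
        assert res.label == "nonselective"
        assert res.flag == "insufficient_data"

    def test_type_one_error_near_alpha(self, rng):
        hits = 0
        n_cells = 1000
        for _ in range(n_cells):
            a = rng.normal(3, 1, 15)
            b = rng.normal(3, 1, 15)
            if classify_selectivity(a, b).selective:
                hits += 1
        lo, hi = stats.binom.interval(0.999, n_cells, 0.05)
        assert lo <= hits <= hi


class TestSameSide:
    def make(self, uid, context, si, label, p=0.01):
        from oswm.selectivity import SelectivityResult
        return SelectivityResult(uid, context, np.ones(5), np.ones(5),
                                 1.0, 1.0, si, p, label)

    def test_all_same_labels(self):
        maze = [self.make(f"u{i}", "maze", 0.2 + 0.1 * i, "right")
                for i in range(5)]
        box = [self.make(f"u{i}", "box", 0.1 + 0.1 * i, "right")
               for i in range(5)]
        out = same_side_fraction(maze, box)
        assert out["frac_same"] == 1.0
        assert out["frac_opposite"] == 0.0
        assert out["si_r"] == pytest.approx(1.0)  # SIs perfectly aligned

    def test_nonselective_box_gives_zero_fractions(self):
        maze = [self.make(f"u{i}", "maze", 0.5, "right") for i in range(4)]
        box = [self.make(f"u{i}", "box", 0.0, "nonselective", p=0.9)
               for i in range(4)]
        out = same_side_fraction(maze, box)
        assert out["frac_same"] == 0.0
        assert out["frac_opposite"] == 0.0


def _null_cells(rng, n_cells=12, n_trials=30):
    cells = []
    sides = np.array(["left", "right"] * (n_trials // 2), dtype=object)
    for i in range(n_cells):
        cells.append(
            CellRates(
                f"u{i}", rng.poisson(6, n_trials).astype(float), sides,
                np.ones(n_trials, bool), maze_label="left" if i % 2 else "right",
            )
        )
    return cells


class TestShuffleNull:
    def test_null_p_and_z_are_sane(self, rng):
        null = shuffle_selectivity_null(_null_cells(rng), 200, rng)
        assert 0 < null.p <= 1
        assert len(null.null) == 200
        # no planted effect: observed inside the central null region
        assert abs(null.z) < 4 if np.isfinite(null.z) else True

    def test_planted_effect_gives_extreme_z(self, rng):
        cells = []
        sides = np.array(["left", "right"] * 15, dtype=object)
        for i in range(10):
            base = np.where(sides == "right", 12.0, 2.0)
            r = rng.poisson(base).astype(float)
            cells.append(CellRates(f"u{i}", r, sides, np.ones(30, bool),
                                   maze_label="right"))
        null = shuffle_selectivity_null(cells, 200, rng)
        assert null.observed == 1.0
        assert null.z > 3
        assert null.p < 1e-3

    def test_observed_fraction_matches_direct_recount(self, rng):
        cells = _null_cells(rng)
        null = shuffle_selectivity_null(cells, 50, rng)
        hits = 0
        for c in cells:
            res = classify_selectivity(c.rates[c.sides == "left"],
                                       c.rates[c.sides == "right"])
            if res.selective and res.label == c.maze_label:
                hits += 1
        assert null.observed == pytest.approx(hits / len(cells))


class TestErrorAnalysis:
    def make_cell(self, rng, uid, pref, attenuation, n_corr=15, n_err=4,
                  base=10.0):
        sides = np.array([pref] * (n_corr + n_err) + ["left" if pref == "right"
                         else "right"] * 5, dtype=object)
        correct = np.array([True] * n_corr + [False] * n_err + [True] * 5)
        lam = np.where(correct & (sides == pref), base,
                       np.where(sides == pref, base * attenuation, 3.0))
        return CellRates(uid, rng.poisson(lam * 2).astype(float) / 2, sides,
                         correct, maze_label=pref, pref_side=pref)

    def test_single_cell_di_value(self):
        cell = CellRates(
            "u0",
            np.array([2.0, 2.0, 2.0, 2.0, 1.0, 1.0, 1.0]),
            np.array(["left"] * 7, dtype=object),
            np.array([True] * 4 + [False] * 3),
            maze_label="left", pref_side="left",
        )
        out = correct_error_analysis([cell], min_errors=3)
        assert len(out.results) == 1
        assert out.results[0].di == pytest.approx(1 / 3)

    def test_attenuation_recovered(self, rng):
        cells = [self.make_cell(rng, f"u{i}", "left" if i % 2 else "right", 0.5)
                 for i in range(12)]
        out = correct_error_analysis(cells, min_errors=3, rng=rng)
        assert out.mean_di > 0.1
        assert out.p < 0.05

    def test_too_few_errors_excluded(self, rng):
        cells = [self.make_cell(rng, "u0", "left", 0.5, n_err=2)]
        out = correct_error_analysis(cells, min_errors=3, rng=rng)
        assert out.results == []
        assert out.excluded and out.excluded[0][0] == "u0"
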