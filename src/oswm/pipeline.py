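"""End-to-end orchestration of the session analysis.

``run_analysis`` executes behaviour -> selectivity -> burst detection ->
replay decoding -> coupling on a session bundle and writes every result
table, a structured log, and the resolved configuration. Runs are fully
deterministic given the config seed.

``run_synthetic_validation`` generates null and effect sessions from the
synthetic generator and checks that each stage recovers (or correctly fails
to find) the planted structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, coupling, replay, selectivity, swr
from .data_model import TRAJECTORIES, SessionData
from .intervals import IntervalSet
from .io import FLOAT_FMT, load_session
from .synth import SynthParams, generate_session

__all__ = ["PipelineConfig", "run_analysis", "run_synthetic_validation"]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters, at the defaults of the underlying analyses."""

    # behaviour
    delay_duration: float = 2.0
    stop_v_thresh: float = 5.0     # cm/s
    stop_min_dur: float = 3.0      # s
    poke_bin: float = 0.25
    # selectivity
    alpha: float = 0.05
    n_shuffles: int = 1000
    min_error_trials: int = 3
    box_correct_only: bool = True
    equal_var_ttest: bool = True
    # burst detection
    mua_bin: float = 0.010
    mua_sigma_bins: float = 2.0
    pbe_peak_thr: float = 0.35
    pbe_edge_thr: float = 0.15
    pbe_merge_gap: float = 0.030
    # templates / decoding
    spatial_bin: float = 2.0
    curve_smooth_sigma: float = 2.0
    track_length: float = 200.0
    template_n_sd: float = 3.0
    rate_band_lo: float = 0.4
    rate_band_hi: float = 10.0
    min_active_cells: int = 4
    decode_tau: float = 0.020
    decode_step: float = 0.010
    replay_alpha: float = 0.05
    replay_shuffle_mode: str = "two_sided"
    # coupling
    coupling_bin: float = 0.200
    max_lag_bins: int = 5
    xcorr_mode: str = "per_trial"
    # misc
    seed: int = 0

    def validate(self) -> None:
        pos = [
            "delay_duration", "stop_v_thresh", "stop_min_dur", "poke_bin",
            "mua_bin", "mua_sigma_bins", "spatial_bin", "curve_smooth_sigma",
            "track_length", "decode_tau", "decode_step", "coupling_bin",
        ]
        for name in pos:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("alpha", "replay_alpha", "pbe_peak_thr", "pbe_edge_thr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def _sel_table(results) -> pd.DataFrame:
    rows = [
        dict(
            unit_id=r.unit_id, context=r.context, n_left=len(r.fr_left),
            n_right=len(r.fr_right), mean_left=r.mean_left,
            mean_right=r.mean_right, si=r.si, p_value=r.p_value,
            label=r.label, flag=r.flag,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["unit_id", "context", "n_left", "n_right", "mean_left",
                 "mean_right", "si", "p_value", "label", "flag"],
    )


def run_analysis(config: PipelineConfig, session, out_dir=None):
    """Run all stages on a session (a SessionData or a bundle path).

    Returns a dict of result tables; when ``out_dir`` is given, also writes
    them as CSV together with the resolved config and a structured log.
    """
    config.validate()
    if not isinstance(session, SessionData):
        session = load_session(session)
    rng = np.random.default_rng(config.seed)
    log: list = []
    results: dict = {}

    def note(stage, **kw):
        log.append({"stage": stage, **kw})

    # ---- behaviour ----------------------------------------------------
    stops = behavior.stop_mask(session.position, config.stop_v_thresh,
                               config.stop_min_dur)
    frac_correct = behavior.maze_performance(session.trials)
    results["behavior"] = pd.DataFrame(
        [
            dict(
                n_trials=len(session.trials),
                n_correct=sum(t.correct for t in session.trials),
                frac_correct=frac_correct,
                n_stop_intervals=len(stops),
            )
        ]
    )
    note("behavior", n_trials=len(session.trials), frac_correct=frac_correct)

    # ---- selectivity --------------------------------------------------
    maze_res, box_res, cell_rates = [], [], []
    for unit in session.acc_units:
        lr, rr = selectivity.maze_trial_rates(session, unit, stops)
        maze_res.append(
            selectivity.classify_selectivity(
                lr, rr, config.alpha, unit.unit_id, "maze",
                config.equal_var_ttest,
            )
        )
        cr = selectivity.delay_trial_rates(session, unit, config.delay_duration)
        keep = cr.correct if config.box_correct_only else np.ones(
            len(cr.rates), bool
        )
        box_res.append(
            selectivity.classify_selectivity(
                cr.rates[keep & (cr.sides == "left")],
                cr.rates[keep & (cr.sides == "right")],
                config.alpha, unit.unit_id, "box", config.equal_var_ttest,
            )
        )
        cell_rates.append(cr)
    results["selectivity_maze"] = _sel_table(maze_res)
    results["selectivity_box"] = _sel_table(box_res)
    n_sel = sum(r.selective for r in maze_res)
    note("selectivity", n_acc=len(maze_res), n_maze_selective=n_sel)

    sel_cells = []
    for res, cr in zip(maze_res, cell_rates):
        if res.selective:
            cr.maze_label = res.label
            cr.pref_side = res.label
            sel_cells.append(cr)
    if sel_cells:
        ss = selectivity.same_side_fraction(maze_res, box_res)
        null = selectivity.shuffle_selectivity_null(
            sel_cells, config.n_shuffles, rng, "same", config.alpha,
            config.box_correct_only,
        )
        results["same_side"] = pd.DataFrame(
            [dict(**ss, null_mean=float(np.mean(null.null)),
                  null_sd=float(np.std(null.null)), z=null.z, p=null.p)]
        )
        results["nulls"] = pd.DataFrame(
            {"shuffle": np.arange(len(null.null)), "frac_same": null.null}
        )
        err = selectivity.correct_error_analysis(
            sel_cells, config.min_error_trials, "preferred", config.alpha,
            config.n_shuffles, rng,
        )
        results["di_error"] = pd.DataFrame(
            [vars(r) for r in err.results],
            columns=["unit_id", "mean_correct", "mean_error", "di",
                     "n_error", "p_value"],
        )
        results["di_summary"] = pd.DataFrame(
            [
                dict(
                    n_cells=len(err.results), mean_di=err.mean_di, t=err.t,
                    p=err.p, frac_sig_positive=err.frac_sig_positive,
                    null_z=err.null.z if err.null else float("nan"),
                    null_p=err.null.p if err.null else float("nan"),
                )
            ]
        )
        note("error_analysis", n_cells=len(err.results),
             n_excluded=len(err.excluded),
             excluded=[list(e) for e in err.excluded])
    else:
        for key, cols in (
            ("same_side", None), ("nulls", ["shuffle", "frac_same"]),
            ("di_error", ["unit_id", "mean_correct", "mean_error", "di",
                          "n_error", "p_value"]),
            ("di_summary", None),
        ):
            results[key] = pd.DataFrame(columns=cols or [])
        note("selectivity", skip="no maze-selective ACC cells")

    # ---- burst detection ----------------------------------------------
    ca1 = session.ca1_units
    if ca1:
        trace = swr.smooth_standardize(
            swr.bin_mua(ca1, config.mua_bin), config.mua_sigma_bins
        )
        pbes = swr.detect_pbes(trace, config.pbe_peak_thr,
                               config.pbe_edge_thr, config.pbe_merge_gap)
        water = IntervalSet.from_unsorted(
            [t.water_interval for t in session.trials
             if t.water_interval is not None]
        )
        in_water = set(
            id(ev) for ev in swr.restrict_events(pbes, water)
        )
        results["pbes"] = pd.DataFrame(
            [
                dict(event_id=i, start=ev.start, end=ev.end,
                     peak_time=ev.peak_time, peak_value=ev.peak_value,
                     in_water_period=int(id(ev) in in_water))
                for i, ev in enumerate(pbes)
            ],
            columns=["event_id", "start", "end", "peak_time", "peak_value",
                     "in_water_period"],
        )
        note("swr", n_pbes=len(pbes),
             n_in_water=int(results["pbes"]["in_water_period"].sum()
                            if len(pbes) else 0))
    else:
        pbes = []
        results["pbes"] = pd.DataFrame(
            columns=["event_id", "start", "end", "peak_time", "peak_value",
                     "in_water_period"]
        )
        note("swr", skip="no CA1 units")

    # ---- replay decoding ----------------------------------------------
    decoded_all = []
    if ca1 and pbes:
        templates = replay.build_all_templates(
            session, config.spatial_bin, config.curve_smooth_sigma,
            config.track_length, config.template_n_sd,
            (config.rate_band_lo, config.rate_band_hi),
        )
        left_ens, right_ens = replay.build_ensembles(templates)
        spikes_by_unit = {u.unit_id: u.spike_times for u in session.units}
        water = IntervalSet.from_unsorted(
            [t.water_interval for t in session.trials
             if t.water_interval is not None]
        )
        pbes_water = swr.restrict_events(pbes, water)
        pbe_index = {id(ev): i for i, ev in enumerate(pbes)}
        for traj in TRAJECTORIES:
            tpl = templates[traj]
            if len(tpl) == 0:
                note("replay", template=traj, skip="empty template")
                continue
            cands = replay.find_candidates(
                pbes_water, tpl, spikes_by_unit, config.min_active_cells
            )
            for ev in cands:
                dec = replay.decode_event(
                    ev, tpl, spikes_by_unit, pbe_index[id(ev)],
                    config.decode_tau, config.decode_step,
                )
                dec = replay.replay_significance(
                    dec, config.n_shuffles, rng, config.replay_alpha,
                    config.replay_shuffle_mode,
                )
                decoded_all.append(dec)
            note("replay", template=traj, n_members=len(tpl),
                 n_candidates=len(cands))
        results["decoded_events"] = pd.DataFrame(
            [
                dict(pbe_id=d.pbe_id, template=d.traj_id,
                     n_windows=int(np.sum(d.active_windows)), r=d.r, p=d.p,
                     is_replay=int(d.is_replay), direction=d.direction,
                     flag=d.flag)
                for d in decoded_all
            ],
            columns=["pbe_id", "template", "n_windows", "r", "p",
                     "is_replay", "direction", "flag"],
        )
        counts = replay.replay_counts_per_trial(session.trials, decoded_all)
        results["replay_counts"] = counts.reset_index()
        # ---- coupling --------------------------------------------------
        cdf, pop = coupling.coupling_battery(
            session, maze_res, (left_ens, right_ens), pbes_water, counts,
            config.delay_duration, config.coupling_bin, config.max_lag_bins,
            config.xcorr_mode,
        )
        results["coupling"] = cdf
        results["population_tests"] = pop
        note("coupling", n_rows=len(cdf))
    else:
        results["decoded_events"] = pd.DataFrame(
            columns=["pbe_id", "template", "n_windows", "r", "p",
                     "is_replay", "direction", "flag"]
        )
        results["replay_counts"] = pd.DataFrame(
            columns=["trial_id", *TRAJECTORIES]
        )
        results["coupling"] = pd.DataFrame(
            columns=["acc_unit_id", "relation", "analysis", "r", "n"]
        )
        results["population_tests"] = pd.DataFrame(
            columns=["analysis", "comparison", "mean", "sem", "t", "p",
                     "sidedness", "n"]
        )
        note("replay", skip="no CA1 units or no bursts")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            _write(df, out / f"{name}.csv")
        with open(out / "config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        with open(out / "log.json", "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=1, sort_keys=True)
    results["log"] = log
    return results


# ----------------------------------------------------------------------
# synthetic validation harness
# ----------------------------------------------------------------------


def run_synthetic_validation(config: PipelineConfig = None, seed: int = 0,
                             out_path=None) -> dict:
    """Recovery report over a null and an effect synthetic condition.

    The null condition plants no side selectivity, no replay bias, and no
    trial-wise coupling; the effect condition uses the generator defaults.
    The report states, per condition, what each stage found and whether it
    lies in the expected band.
    """
    if config is None:
        config = PipelineConfig(seed=seed)
    grid = {
        "null": SynthParams(
            seed=seed, acc_selectivity_ratio=1.0, replay_bias=0.5,
            coupling_strength=0.0, acc_error_attenuation=1.0,
        ),
        "effect": SynthParams(seed=seed + 1),
    }
    report = {"seed": seed, "conditions": {}}
    for name, params in grid.items():
        session, gt = generate_session(params)
        res = run_analysis(config.replace(seed=seed), session)
        maze = res["selectivity_maze"]
        frac_sel = float((maze["label"] != "nonselective").mean()) if len(maze) else float("nan")
        # replay recall: every embedded burst overlapping a detected burst
        pbes = res["pbes"]
        recall = float("nan")
        if len(gt.replays):
            hits = 0
            for _, ev in gt.replays.iterrows():
                m = (pbes["start"] < ev["end"]) & (pbes["end"] > ev["start"])
                hits += bool(m.any())
            recall = hits / len(gt.replays)
        dec = res["decoded_events"]
        frac_replay = float(dec["is_replay"].mean()) if len(dec) else float("nan")
        pop = res["population_tests"]
        cond = {
            "params": params.to_dict(),
            "frac_acc_selective": frac_sel,
            "pbe_recall_vs_truth": recall,
            "frac_candidates_significant": frac_replay,
            "n_pbes": int(len(pbes)),
        }
        row = pop[(pop.analysis == "water_swr_trial_corr")
                  & (pop.comparison == "same_vs_opposite_paired")]
        if len(row):
            cond["coupling_same_minus_opposite"] = float(row["mean"].iloc[0])
            cond["coupling_paired_p"] = float(row["p"].iloc[0])
        if name == "null":
            cond["pass_selectivity_null"] = bool(frac_sel <= 0.25)
        else:
            cond["pass_selectivity_power"] = bool(frac_sel >= 0.9)
            cond["pass_pbe_recall"] = bool(recall >= 0.9)
        report["conditions"][name] = cond
    if out_path is not None:
        with open(out_path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report
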