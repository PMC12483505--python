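"""Read/write the plain-text session bundle.

A bundle is a directory of UTF-8 CSV tables plus a small YAML manifest:

- ``manifest.yaml`` — condition, table filenames, free-form metadata
- ``units.csv``     — unit_id, region (keeps silent units)
- ``spikes.csv``    — unit_id, region, t
- ``position.csv``  — t, x, y, traj_id, lin_pos, speed
- ``trials.csv``    — one row per trial (scalars only)
- ``intervals.csv`` — trial_id, kind, start, end (per-trial maze laps)

Output is byte-stable for a fixed session: fixed column order and a fixed
``%.9g`` float format, so identical sessions produce identical bytes.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    TRAJECTORIES,
    PositionSeries,
    SessionData,
    SpikeTrain,
    TrialRecord,
    validate_session,
)
from .intervals import IntervalSet

FLOAT_FMT = "%.9g"

_FILES = {
    "units": "units.csv",
    "spikes": "spikes.csv",
    "position": "position.csv",
    "trials": "trials.csv",
    "intervals": "intervals.csv",
}


class SessionValidationError(ValueError):
    """Raised when a loaded session violates a data-model invariant."""

    def __init__(self, violations):
        self.violations = violations
        super().__init__(
            "session failed validation:\n" + "\n".join(str(v) for v in violations)
        )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def write_session(session: SessionData, out_dir) -> Path:
    """Write ``session`` as a plain-text bundle under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.access(out, os.W_OK):
        raise IOError(f"directory not writable: {out}")

    _write_csv(
        pd.DataFrame(
            {
                "unit_id": [u.unit_id for u in session.units],
                "region": [u.region for u in session.units],
            }
        ),
        out / _FILES["units"],
    )

    sp_frames = [
        pd.DataFrame(
            {"unit_id": u.unit_id, "region": u.region, "t": u.spike_times}
        )
        for u in session.units
        if u.n_spikes
    ]
    spikes = (
        pd.concat(sp_frames, ignore_index=True)
        if sp_frames
        else pd.DataFrame(columns=["unit_id", "region", "t"])
    )
    _write_csv(spikes, out / _FILES["spikes"])

    pos = session.position
    _write_csv(
        pd.DataFrame(
            {
                "t": pos.t,
                "x": pos.x,
                "y": pos.y,
                "traj_id": pos.traj_id,
                "lin_pos": pos.lin_pos,
                "speed": pos.speed,
            }
        ),
        out / _FILES["position"],
    )

    rows = []
    for tr in session.trials:
        ws, we = tr.water_interval if tr.water_interval is not None else (None, None)
        rows.append(
            {
                "trial_id": tr.trial_id,
                "side": tr.side,
                "correct": int(tr.correct),
                "t_demo_cp": tr.t_demo_cp,
                "t_ob_poke": tr.t_ob_poke,
                "demo_poke_time": tr.demo_poke_time,
                "water_start": ws,
                "water_end": we,
            }
        )
    cols = [
        "trial_id",
        "side",
        "correct",
        "t_demo_cp",
        "t_ob_poke",
        "demo_poke_time",
        "water_start",
        "water_end",
    ]
    _write_csv(pd.DataFrame(rows, columns=cols), out / _FILES["trials"])

    irows = []
    for tr in session.trials:
        for traj in TRAJECTORIES:
            laps = tr.maze_laps.get(traj)
            if laps is None:
                continue
            for s, e in laps:
                irows.append(
                    {"trial_id": tr.trial_id, "kind": traj, "start": s, "end": e}
                )
    _write_csv(
        pd.DataFrame(irows, columns=["trial_id", "kind", "start", "end"]),
        out / _FILES["intervals"],
    )

    manifest = {
        "condition": session.condition,
        "files": dict(_FILES),
        "meta": {k: session.meta[k] for k in sorted(session.meta)},
    }
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def load_session(manifest_path, validate: bool = True) -> SessionData:
    """Load a session bundle from a manifest file (or its directory).

    Raises ``FileNotFoundError`` naming any missing table and
    :class:`SessionValidationError` if a data-model invariant fails.
    """
    p = Path(manifest_path)
    if p.is_dir():
        p = p / "manifest.yaml"
    if not p.exists():
        raise FileNotFoundError(f"manifest not found: {p}")
    with open(p, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    base = p.parent
    files = manifest.get("files", _FILES)
    tables = {}
    for key in _FILES:
        fpath = base / files.get(key, _FILES[key])
        if not fpath.exists():
            raise FileNotFoundError(f"bundle table missing: {fpath}")
        tables[key] = pd.read_csv(fpath)

    units = []
    sp = tables["spikes"]
    grouped = {uid: g["t"].to_numpy() for uid, g in sp.groupby("unit_id", sort=False)}
    for _, row in tables["units"].iterrows():
        uid = str(row["unit_id"])
        units.append(
            SpikeTrain(uid, str(row["region"]), grouped.get(uid, np.empty(0)))
        )

    posdf = tables["position"]
    position = PositionSeries(
        t=posdf["t"].to_numpy(),
        x=posdf["x"].to_numpy(),
        y=posdf["y"].to_numpy(),
        traj_id=posdf["traj_id"].astype(str).to_numpy(dtype=object),
        lin_pos=posdf["lin_pos"].to_numpy(),
        speed=posdf["speed"].to_numpy() if "speed" in posdf else None,
    )

    laps_by_trial: dict = {}
    for _, row in tables["intervals"].iterrows():
        kind = str(row["kind"])
        if kind not in TRAJECTORIES:
            continue
        laps_by_trial.setdefault(int(row["trial_id"]), {}).setdefault(
            kind, []
        ).append((float(row["start"]), float(row["end"])))

    trials = []
    for _, row in tables["trials"].iterrows():
        tid = int(row["trial_id"])

        def _opt(name):
            v = row[name]
            return None if pd.isna(v) else float(v)

        ws, we = _opt("water_start"), _opt("water_end")
        laps = {
            traj: IntervalSet.from_unsorted(ivs)
            for traj, ivs in laps_by_trial.get(tid, {}).items()
        }
        trials.append(
            TrialRecord(
                trial_id=tid,
                side=str(row["side"]),
                correct=bool(int(row["correct"])),
                t_demo_cp=_opt("t_demo_cp"),
                t_ob_poke=_opt("t_ob_poke"),
                demo_poke_time=_opt("demo_poke_time"),
                water_interval=(ws, we) if ws is not None else None,
                maze_laps=laps,
            )
        )

    session = SessionData(
        condition=manifest["condition"],
        units=units,
        position=position,
        trials=trials,
        meta=manifest.get("meta", {}) or {},
    )
    if validate:
        violations = validate_session(session)
        if violations:
            raise SessionValidationError(violations)
    return session
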