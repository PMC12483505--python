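"""Session data model for observational spatial working-memory recordings.

A session couples sorted spike trains from anterior cingulate cortex (ACC)
and hippocampal CA1 with tracked positions and a per-trial behavioural event
table. Times are session-relative seconds; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .intervals import IntervalSet

REGIONS = ("ACC", "CA1")
TRAJECTORIES = ("left_out", "left_in", "right_out", "right_in")
SIDES = ("left", "right")
CONDITIONS = ("Demo", "Object", "Empty")


def side_of(traj_id: str) -> str:
    """Maze side ('left'/'right') of a trajectory id."""
    return traj_id.split("_")[0]


def other_side(side: str) -> str:
    return "right" if side == "left" else "left"


@dataclass(frozen=True)
class SpikeTrain:
    """One sorted unit: region label plus strictly ascending spike times (s)."""

    unit_id: str
    region: str
    spike_times: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "spike_times", np.asarray(self.spike_times, dtype=float)
        )

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass
class PositionSeries:
    """Tracked head position at ~30 Hz.

    ``lin_pos`` is the linearised coordinate (cm) along the trajectory named
    by ``traj_id`` and is NaN whenever ``traj_id == 'none'`` (animal off the
    maze). ``speed`` (cm/s) is derived from x, y if not supplied.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    traj_id: np.ndarray  # str array, values in TRAJECTORIES or 'none'
    lin_pos: np.ndarray  # cm, NaN outside the maze
    speed: Optional[np.ndarray] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.traj_id = np.asarray(self.traj_id, dtype=object)
        self.lin_pos = np.asarray(self.lin_pos, dtype=float)
        if self.speed is None and len(self.t) > 1:
            dt = np.gradient(self.t)
            self.speed = np.hypot(np.gradient(self.x), np.gradient(self.y)) / dt
        elif self.speed is None:
            self.speed = np.zeros_like(self.t)
        else:
            self.speed = np.asarray(self.speed, dtype=float)

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class TrialRecord:
    """One trial's side, outcome, and event times.

    ``side`` is the demonstrator's choice. ``t_demo_cp`` is the demonstrator's
    choice-point crossing, ``t_ob_poke`` the observer's first rewarded poke in
    the box; the delay period is anchored to the latter. ``maze_laps`` maps a
    trajectory id to the IntervalSet of the observer's self-running laps.
    """

    trial_id: int
    side: str
    correct: bool
    t_demo_cp: Optional[float] = None
    t_ob_poke: Optional[float] = None
    demo_poke_time: Optional[float] = None
    water_interval: Optional[tuple] = None  # (start, end)
    maze_laps: dict = field(default_factory=dict)  # traj_id -> IntervalSet

    @property
    def run_side(self) -> str:
        """Side the observer actually ran (opposite of ``side`` on errors)."""
        return self.side if self.correct else other_side(self.side)


@dataclass
class SessionData:
    """A full recording session: units, position, trials, metadata."""

    condition: str
    units: list  # of SpikeTrain
    position: PositionSeries
    trials: list  # of TrialRecord
    meta: dict = field(default_factory=dict)

    def units_in(self, region: str) -> list:
        return [u for u in self.units if u.region == region]

    @property
    def ca1_units(self) -> list:
        return self.units_in("CA1")

    @property
    def acc_units(self) -> list:
        return self.units_in("ACC")

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_session`."""

    record_id: str
    rule: str
    detail: str = ""

    def __str__(self):
        msg = f"{self.record_id}: {self.rule}"
        return f"{msg} ({self.detail})" if self.detail else msg


def validate_session(session: SessionData) -> list:
    """Check every data-model invariant; return a list of violations.

    Always returns (never raises); an empty list means the session is valid.
    """
    out = []
    if session.condition not in CONDITIONS:
        out.append(Violation("session", "unknown_condition", session.condition))

    for u in session.units:
        if u.region not in REGIONS:
            out.append(Violation(u.unit_id, "unknown_region", u.region))
        st = u.spike_times
        if len(st) and not np.all(np.isfinite(st)):
            out.append(Violation(u.unit_id, "nonfinite_spike_times"))
        elif len(st) > 1 and np.any(np.diff(st) <= 0):
            out.append(Violation(u.unit_id, "spike_times_not_strictly_ascending"))

    pos = session.position
    if len(pos) > 1 and np.any(np.diff(pos.t) <= 0):
        out.append(Violation("position", "time_not_strictly_ascending"))
    if len(pos) and np.any(pos.speed < 0):
        out.append(Violation("position", "negative_speed"))
    on_maze = pos.traj_id != "none"
    if np.any(~np.isfinite(pos.lin_pos[on_maze])):
        out.append(Violation("position", "lin_pos_missing_on_maze"))
    if np.any(np.isfinite(pos.lin_pos[~on_maze])):
        out.append(Violation("position", "lin_pos_defined_off_maze"))

    for tr in session.trials:
        rid = f"trial_{tr.trial_id}"
        if tr.side not in SIDES:
            out.append(Violation(rid, "unknown_side", tr.side))
        if (
            tr.t_demo_cp is not None
            and tr.t_ob_poke is not None
            and tr.t_demo_cp > tr.t_ob_poke
        ):
            out.append(Violation(rid, "demo_cp_after_ob_poke"))
        if tr.water_interval is not None:
            ws, we = tr.water_interval
            if ws >= we:
                out.append(Violation(rid, "empty_water_interval"))
            if tr.t_ob_poke is not None and ws < tr.t_ob_poke:
                out.append(Violation(rid, "water_before_ob_poke"))
        for traj, laps in tr.maze_laps.items():
            if traj not in TRAJECTORIES:
                out.append(Violation(rid, "unknown_trajectory", traj))
            if not isinstance(laps, IntervalSet):
                # raw (n, 2) arrays: check ordering/disjointness by brute force
                arr = np.asarray(laps, dtype=float).reshape(-1, 2)
                for i in range(len(arr)):
                    if arr[i, 0] >= arr[i, 1]:
                        out.append(Violation(rid, "empty_lap_interval", traj))
                    for j in range(i + 1, len(arr)):
                        if arr[i, 1] > arr[j, 0] and arr[j, 1] > arr[i, 0]:
                            out.append(
                                Violation(rid, "overlapping_lap_intervals", traj)
                            )

    pokes = [tr.t_ob_poke for tr in session.trials if tr.t_ob_poke is not None]
    if any(b < a for a, b in zip(pokes, pokes[1:])):
        out.append(Violation("trials", "not_ordered_by_t_ob_poke"))
    return out
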