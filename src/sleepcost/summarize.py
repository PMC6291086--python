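"""Trajectory statistics: sleep episodes, daily hours, utility range.

An episode is a maximal run of consecutive asleep periods. Episodes are
attributed to the day containing their first period; on a converged
stylized day the series is treated as cyclic, so a run spanning the
midnight boundary of the cycle counts once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Trajectory

__all__ = [
    "SleepEpisode",
    "DailySummary",
    "episodes",
    "daily_summary",
    "daily_hours",
    "episodes_per_day",
    "utility_range",
    "make_fixture",
]


@dataclass(frozen=True)
class SleepEpisode:
    start: int
    length: int
    duration_hours: float
    day: int


@dataclass(frozen=True)
class DailySummary:
    """Across-day sleep statistics; SD uses the population formula."""

    n_days: int
    mean_hours: float
    sd_hours: float
    mean_episodes_per_day: float
    per_day: pd.DataFrame


def _action_series(traj) -> tuple[np.ndarray, int, bool]:
    if isinstance(traj, Trajectory):
        return np.asarray(traj.A, dtype=np.int8), traj.params.q, traj.stylized
    raise TypeError("expected a Trajectory; use make_fixture to wrap raw series")


def _runs(A: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal run of ones."""
    if A.size == 0:
        return []
    padded = np.concatenate(([0], A, [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def episodes(traj: Trajectory) -> list[SleepEpisode]:
    """Maximal-run decomposition of the asleep indicator.

    Stylized (limit-cycle) trajectories wrap around the day boundary: a
    sleep run covering both the last and first periods of the cycle is one
    episode starting at its pre-midnight start.
    """
    A, q, cyclic = _action_series(traj)
    runs = _runs(A)
    if cyclic and len(runs) >= 2 and A[0] == 1 and A[-1] == 1:
        first, last = runs[0], runs[-1]
        runs = runs[1:-1] + [(last[0], last[1] + first[1])]
    elif cyclic and len(runs) == 1 and A.all():
        pass  # asleep the whole cycle: a single 24 h episode
    hours_per_period = 24.0 / q
    return [
        SleepEpisode(
            start=int(s),
            length=int(n),
            duration_hours=n * hours_per_period,
            day=int(s // q),
        )
        for s, n in runs
    ]


def daily_summary(traj: Trajectory) -> DailySummary:
    """Mean and population SD of hours slept per day, plus episode counts.

    The trajectory must cover a whole number of days (day boundaries every
    q periods from its start); callers trim partial trailing days.
    """
    A, q, _ = _action_series(traj)
    if A.size == 0 or A.size % q:
        raise ValueError(f"trajectory length {A.size} is not a whole number of days")
    n_days = A.size // q
    hours = A.reshape(n_days, q).sum(axis=1) * (24.0 / q)
    eps_by_day = np.zeros(n_days, dtype=int)
    for ep in episodes(traj):
        eps_by_day[ep.day] += 1
    per_day = pd.DataFrame(
        {"day": np.arange(n_days), "hours": hours, "episodes": eps_by_day}
    )
    return DailySummary(
        n_days=n_days,
        mean_hours=float(hours.mean()),
        sd_hours=float(hours.std(ddof=0)),
        mean_episodes_per_day=float(eps_by_day.mean()),
        per_day=per_day,
    )


def daily_hours(traj: Trajectory) -> np.ndarray:
    """Hours asleep per day (fast path; no episode bookkeeping)."""
    A, q, _ = _action_series(traj)
    if A.size == 0 or A.size % q:
        raise ValueError(f"trajectory length {A.size} is not a whole number of days")
    return A.reshape(-1, q).sum(axis=1) * (24.0 / q)


def episodes_per_day(traj: Trajectory) -> float:
    """Episode count divided by the day span (cyclic for stylized cycles)."""
    A, q, _ = _action_series(traj)
    return len(episodes(traj)) / (A.size / q)


def utility_range(day: Trajectory) -> float:
    """Max minus min of realized per-period utility over a stylized cycle.

    For a one-day limit cycle this is the paper-style daily utility range;
    multi-day cycles use the whole cycle.
    """
    if not day.stylized:
        raise ValueError("utility_range expects a converged stylized cycle")
    if len(day) != day.params.q * day.cycle_days:
        raise ValueError("expected a whole limit cycle of periods")
    return float(np.max(day.U) - np.min(day.U))


def make_fixture(
    pattern: list[list[tuple[int, int]]], q: int, params=None
) -> Trajectory:
    """Build a deterministic action series with a requested run structure.

    ``pattern`` lists, per day, the episodes as (start-within-day, length)
    pairs; episodes must fit in their day without overlapping, so
    episodes() round-trips the spec exactly. Used to test the summary
    stage independently of the simulator.
    """
    from .params import preset

    if params is None:
        params = preset("elephant_wild").replace(q=q)
    if params.q != q:
        raise ValueError("params.q must match q")
    n_days = max(len(pattern), 1)
    A = np.zeros(n_days * q, dtype=np.int8)
    prev_end = -1  # exclusive end of the last placed episode, global index
    for day, eps in enumerate(pattern):
        for start, length in sorted(eps):
            if length < 1 or start < 0 or start + length > q:
                raise ValueError(f"episode ({start}, {length}) does not fit in a day")
            g = day * q + start
            if g <= prev_end:
                raise ValueError("episodes overlap or touch; separate by >= 1 period")
            A[g : g + length] = 1
            prev_end = g + length
    n = n_days * q
    t = np.arange(n)
    zeros = np.zeros(n)
    return Trajectory(
        t=t, A=A[:n], H=zeros, z=zeros, U=zeros, y=zeros, params=params
    )
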