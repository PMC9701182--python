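"""Shared builders and fixtures for the test suite.

All fixture data is generated programmatically; the synthetic_data module
is itself under test, so low-level helpers here build activities directly
from first principles (constant-speed samples on exact dates).
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from marathonlab.core_data import (
    IntervalSeries,
    RawActivity,
    RunnerHistory,
    normalize_to_intervals,
)

RACE_DAY = dt.date(2023, 10, 1)


def constant_activity(
    distance_m: float,
    pace_min_per_km: float,
    date: dt.date = RACE_DAY - dt.timedelta(days=10),
    runner_id: str = "r1",
    activity_id: str = "a1",
) -> IntervalSeries:
    """A constant-speed activity on the 100 m grid."""
    total_s = (distance_m / 1000.0) * pace_min_per_km * 60.0
    raw = RawActivity(
        runner_id, activity_id, date, np.array([[0.0, 0.0], [distance_m, total_s]])
    )
    return normalize_to_intervals(raw)


def series_from_paces(paces_min_per_km, **kwargs) -> IntervalSeries:
    """An activity whose per-100 m paces are exactly the given values."""
    times = np.asarray(paces_min_per_km, dtype=float) * 60.0 * 0.1
    defaults = dict(
        runner_id="r1",
        activity_id="a1",
        date=RACE_DAY - dt.timedelta(days=10),
    )
    defaults.update(kwargs)
    return IntervalSeries(interval_times=times, **defaults)


def history_of(
    sessions: list[tuple[int, float, float]],
    runner_id: str = "r1",
    sex: str = "M",
    marathon_time: float | None = 240.0,
    race_date: dt.date = RACE_DAY,
) -> RunnerHistory:
    """History from (days_before_race, distance_m, pace) session tuples."""
    acts = [
        constant_activity(
            d_m,
            pace,
            date=race_date - dt.timedelta(days=days),
            runner_id=runner_id,
            activity_id=f"{runner_id}-a{i}",
        )
        for i, (days, d_m, pace) in enumerate(sessions)
    ]
    return RunnerHistory(
        runner_id=runner_id,
        sex=sex,
        race_date=race_date,
        activities=acts,
        age=40.0,
        marathon_time=marathon_time,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-runner simulated dataset reused by read-only tests."""
    from marathonlab.synthetic_data import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(n_runners=30, seed=42))
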