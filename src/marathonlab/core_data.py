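"""Core domain types and I/O for marathon training analytics.

The atom of every fitness computation is an activity normalised onto a
100 m grid: raw trackers sample cumulative distance/time at device-dependent
rates, so each activity is resampled to the time taken for each successive
100 m interval.  Race records are represented by nine per-kilometre segment
paces (every 5 km plus the final 2.195 km of the 42.195 km distance).

Unit conventions (fixed package-wide):

* distances — metres for grids/samples, kilometres for session summaries;
* times — seconds internally;
* paces — minutes per kilometre at every public surface.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MARATHON_KM = 42.195
INTERVAL_M = 100.0
#: per-km lengths of the nine race segments: eight 5 km segments + 2.195 km
SEGMENT_LENGTHS_KM = np.array([5.0] * 8 + [2.195])
SEGMENT_LABELS = ("5k", "10k", "15k", "20k", "25k", "30k", "35k", "40k", "42.2k")
#: cumulative-split column names used in races.csv
SPLIT_COLUMNS = tuple(f"split_{lab}_s" for lab in SEGMENT_LABELS[:-1]) + ("finish_s",)

ACTIVITY_COLUMNS = (
    "runner_id", "activity_id", "date", "sample_index", "cum_distance_m", "cum_time_s",
)
RUNNER_COLUMNS = ("runner_id", "sex", "age", "race_date", "marathon_time_min")
RACE_COLUMNS = ("runner_id", "marathon_id", "year", "sex", "age_group") + SPLIT_COLUMNS

VALID_SEX = ("M", "F")


class MalformedActivityError(ValueError):
    """Raw samples violate monotonicity or interval times are degenerate."""


class ValidationError(ValueError):
    """An input file row violates the interchange schema."""


@dataclass(frozen=True)
class RawActivity:
    """One tracked activity as raw cumulative (distance m, time s) samples."""

    runner_id: str
    activity_id: str
    date: dt.date
    samples: np.ndarray  # shape (n, 2): cumulative metres, cumulative seconds

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2 or samples.shape[1] != 2 or samples.shape[0] < 2:
            raise MalformedActivityError(
                f"activity {self.activity_id}: need >= 2 (distance, time) samples"
            )
        if samples[0, 0] != 0.0 or samples[0, 1] != 0.0:
            raise MalformedActivityError(
                f"activity {self.activity_id}: first sample must be (0, 0)"
            )
        if np.any(np.diff(samples[:, 0]) <= 0) or np.any(np.diff(samples[:, 1]) <= 0):
            raise MalformedActivityError(
                f"activity {self.activity_id}: samples must strictly increase"
            )


@dataclass
class IntervalSeries:
    """An activity resampled to per-100 m interval times (seconds)."""

    runner_id: str
    activity_id: str
    date: dt.date
    interval_times: np.ndarray  # seconds, one entry per 100 m

    def __post_init__(self) -> None:
        self.interval_times = np.asarray(self.interval_times, dtype=float)
        if self.interval_times.ndim != 1 or self.interval_times.size == 0:
            raise MalformedActivityError(
                f"activity {self.activity_id}: empty interval series"
            )
        if np.any(self.interval_times <= 0):
            raise MalformedActivityError(
                f"activity {self.activity_id}: non-positive interval time"
            )

    @property
    def n_intervals(self) -> int:
        return int(self.interval_times.size)

    @property
    def total_distance_m(self) -> float:
        return self.n_intervals * INTERVAL_M

    @property
    def total_distance_km(self) -> float:
        return self.total_distance_m / 1000.0

    @property
    def duration_s(self) -> float:
        return float(self.interval_times.sum())

    @property
    def mean_pace(self) -> float:
        """Whole-activity mean pace in min/km."""
        return (self.duration_s / 60.0) / self.total_distance_km


@dataclass
class PaceSeries:
    """Per-100 m paces in min/km for one activity."""

    paces: np.ndarray

    def __post_init__(self) -> None:
        self.paces = np.asarray(self.paces, dtype=float)
        if np.any(self.paces <= 0):
            raise MalformedActivityError("non-positive pace")


def normalize_to_intervals(raw: RawActivity) -> IntervalSeries:
    """Resample a raw activity onto the 100 m grid.

    Cumulative time is linearly interpolated at every 100 m grid point and
    differenced; a trailing partial interval (< 100 m) is discarded.
    """
    dist = raw.samples[:, 0]
    time = raw.samples[:, 1]
    n_full = int(dist[-1] // INTERVAL_M)
    if n_full == 0:
        raise MalformedActivityError(
            f"activity {raw.activity_id}: shorter than one 100 m interval"
        )
    grid = INTERVAL_M * np.arange(1, n_full + 1)
    grid_times = np.interp(grid, dist, time)
    interval_times = np.diff(grid_times, prepend=0.0)
    return IntervalSeries(raw.runner_id, raw.activity_id, raw.date, interval_times)


def paces_of(series: IntervalSeries) -> PaceSeries:
    """Per-interval paces: pace_j = t_j(min) / 0.1 km."""
    return PaceSeries((series.interval_times / 60.0) / (INTERVAL_M / 1000.0))


def interval_times_of(paces: PaceSeries) -> np.ndarray:
    """Invert :func:`paces_of`, returning interval times in seconds."""
    return paces.paces * 60.0 * (INTERVAL_M / 1000.0)


@dataclass
class RunnerHistory:
    """A runner's time-ordered training activities ahead of one marathon."""

    runner_id: str
    sex: str
    race_date: dt.date
    activities: list[IntervalSeries] = field(default_factory=list)
    age: float | None = None
    marathon_time: float | None = None  # minutes

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEX:
            raise ValidationError(f"runner {self.runner_id}: unknown sex {self.sex!r}")
        self.activities = sorted(self.activities, key=lambda a: (a.date, a.activity_id))
        for act in self.activities:
            if act.date > self.race_date:
                raise ValidationError(
                    f"runner {self.runner_id}: activity {act.activity_id} after race-day"
                )


@dataclass
class RaceRecord:
    """One runner's result in one marathon: nine segment paces + finish time."""

    runner_id: str
    marathon_id: str
    year: int
    sex: str
    age_group: str
    segment_paces: np.ndarray  # min/km, one per segment
    finish_time: float  # minutes

    def __post_init__(self) -> None:
        self.segment_paces = np.asarray(self.segment_paces, dtype=float)
        if self.segment_paces.shape != (9,):
            raise ValidationError(
                f"race {self.runner_id}/{self.marathon_id}: need exactly 9 segment paces"
            )
        if np.any(self.segment_paces <= 0) or self.finish_time <= 0:
            raise ValidationError(
                f"race {self.runner_id}/{self.marathon_id}: non-positive pace or finish"
            )
        implied = float(self.segment_paces @ SEGMENT_LENGTHS_KM)
        if abs(implied - self.finish_time) > 0.005 * self.finish_time:
            raise ValidationError(
                f"race {self.runner_id}/{self.marathon_id}: segment paces imply "
                f"{implied:.2f} min but finish_time is {self.finish_time:.2f} min"
            )

    @property
    def mean_pace(self) -> float:
        return self.finish_time / MARATHON_KM


def week_index(race_date: dt.date, date: dt.date) -> int:
    """Index of the rolling 7-day training week containing ``date``.

    Week 0 is race week; weeks count backwards from race-day, so an activity
    d days before the race lands in week ceil(d/7) - 1 (race-day itself is
    week 0).
    """
    days_before = (race_date - date).days
    if days_before < 0:
        raise ValueError("date after race_date")
    return (max(days_before, 1) - 1) // 7


def weekly_partition(history: RunnerHistory) -> dict[int, list[IntervalSeries]]:
    """Partition a history's activities into rolling race-anchored weeks."""
    out: dict[int, list[IntervalSeries]] = {}
    for act in history.activities:
        out.setdefault(week_index(history.race_date, act.date), []).append(act)
    return out


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: tuple[str, ...], path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _parse_sex(value: str, context: str) -> str:
    if value not in VALID_SEX:
        raise ValidationError(f"{context}: unknown sex code {value!r}")
    return value


def read_activities(activities_path, runners_path) -> list[RunnerHistory]:
    """Read activity samples + runner metadata CSVs into runner histories.

    ``activities.csv`` is long form (one row per raw sample); raw samples are
    normalised onto the 100 m grid on read.
    """
    acts = pd.read_csv(activities_path, dtype={"runner_id": str, "activity_id": str})
    runners = pd.read_csv(runners_path, dtype={"runner_id": str})
    _require_columns(acts, ACTIVITY_COLUMNS, str(activities_path))
    _require_columns(runners, RUNNER_COLUMNS, str(runners_path))

    if len(acts) and acts.duplicated(["runner_id", "activity_id", "sample_index"]).any():
        row = acts[acts.duplicated(["runner_id", "activity_id", "sample_index"])].index[0]
        raise ValidationError(f"{activities_path}: duplicate sample at row {row}")

    by_activity: dict[str, list[IntervalSeries]] = {}
    if len(acts):
        acts = acts.sort_values(["runner_id", "activity_id", "sample_index"])
        for (runner_id, activity_id), grp in acts.groupby(
            ["runner_id", "activity_id"], sort=True
        ):
            date = dt.date.fromisoformat(str(grp["date"].iloc[0]))
            samples = grp[["cum_distance_m", "cum_time_s"]].to_numpy(dtype=float)
            try:
                raw = RawActivity(runner_id, activity_id, date, samples)
            except MalformedActivityError as exc:
                raise ValidationError(f"{activities_path}: {exc}") from exc
            by_activity.setdefault(runner_id, []).append(normalize_to_intervals(raw))

    histories = []
    for row in runners.itertuples(index=False):
        mt = getattr(row, "marathon_time_min")
        age = getattr(row, "age")
        histories.append(
            RunnerHistory(
                runner_id=str(row.runner_id),
                sex=_parse_sex(str(row.sex), f"runner {row.runner_id}"),
                race_date=dt.date.fromisoformat(str(row.race_date)),
                activities=by_activity.get(str(row.runner_id), []),
                age=None if pd.isna(age) else float(age),
                marathon_time=None if pd.isna(mt) else float(mt),
            )
        )
    return histories


def write_activities(histories: list[RunnerHistory], activities_path, runners_path) -> None:
    """Write runner histories back to the two-file CSV interchange format.

    Activities are emitted as cumulative samples on the 100 m grid (plus the
    origin), so ``read_activities`` round-trips exactly.
    """
    act_rows = []
    run_rows = []
    for h in sorted(histories, key=lambda h: h.runner_id):
        run_rows.append(
            {
                "runner_id": h.runner_id,
                "sex": h.sex,
                "age": h.age,
                "race_date": h.race_date.isoformat(),
                "marathon_time_min": h.marathon_time,
            }
        )
        for act in h.activities:
            cum_t = np.concatenate([[0.0], np.cumsum(act.interval_times)])
            cum_d = INTERVAL_M * np.arange(act.n_intervals + 1)
            for i, (d, t) in enumerate(zip(cum_d, cum_t)):
                act_rows.append(
                    {
                        "runner_id": h.runner_id,
                        "activity_id": act.activity_id,
                        "date": act.date.isoformat(),
                        "sample_index": i,
                        "cum_distance_m": d,
                        "cum_time_s": t,
                    }
                )
    pd.DataFrame(act_rows, columns=list(ACTIVITY_COLUMNS)).to_csv(
        activities_path, index=False
    )
    pd.DataFrame(run_rows, columns=list(RUNNER_COLUMNS)).to_csv(
        runners_path, index=False
    )


def read_races(path) -> list[RaceRecord]:
    """Read race records (cumulative 5 km split times) into segment paces."""
    df = pd.read_csv(path, dtype={"runner_id": str, "marathon_id": str, "age_group": str})
    _require_columns(df, RACE_COLUMNS, str(path))
    records = []
    for idx, row in df.iterrows():
        splits = row[list(SPLIT_COLUMNS)].to_numpy(dtype=float)
        if np.any(pd.isna(splits)):
            raise ValidationError(f"{path}: row {idx}: missing split")
        seg_times = np.diff(splits, prepend=0.0)
        paces = (seg_times / 60.0) / SEGMENT_LENGTHS_KM
        records.append(
            RaceRecord(
                runner_id=str(row["runner_id"]),
                marathon_id=str(row["marathon_id"]),
                year=int(row["year"]),
                sex=_parse_sex(str(row["sex"]), f"{path}: row {idx}"),
                age_group=str(row["age_group"]),
                segment_paces=paces,
                finish_time=float(splits[-1]) / 60.0,
            )
        )
    return records


def write_races(records: list[RaceRecord], path) -> None:
    rows = []
    for r in sorted(records, key=lambda r: (r.runner_id, r.year, r.marathon_id)):
        splits = np.cumsum(r.segment_paces * SEGMENT_LENGTHS_KM * 60.0)
        row = {
            "runner_id": r.runner_id,
            "marathon_id": r.marathon_id,
            "year": r.year,
            "sex": r.sex,
            "age_group": r.age_group,
        }
        row.update(dict(zip(SPLIT_COLUMNS, splits)))
        rows.append(row)
    pd.DataFrame(rows, columns=list(RACE_COLUMNS)).to_csv(path, index=False)
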