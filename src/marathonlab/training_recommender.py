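"""Case-based recommendation of next-week training plans.

A *training case* describes one runner-week with 18 summary features
(volume, session counts, within-week and to-date fastest/slowest paces over
1/5/10 km windows), the runner's eventual marathon time, and a pointer to
the week of training that runner actually did next.  To recommend training
for an adjusted goal time, the current week is used as a query into a
case base of same-sex, same-week cases whose marathon times fall within a
narrow window of the goal; the single nearest neighbour's next week of
training is returned verbatim, with provenance.

A 4-week ensemble variant queries the four most recent weeks (optionally
rank-aligned by long-run distance, since training blocks ramp up and down)
and recommends from the globally most similar retrieved case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core_data import INTERVAL_M, IntervalSeries, RunnerHistory, weekly_partition
from .fitness_models import runner_folds

FEATURE_NAMES = (
    "sex",
    "num_sessions",
    "total_distance",
    "mean_pace",
    "longest_run",
    "fastest_1k",
    "fastest_5k",
    "fastest_10k",
    "slowest_1k",
    "slowest_5k",
    "slowest_10k",
    "longest_run_to_date",
    "fastest_1k_to_date",
    "fastest_5k_to_date",
    "fastest_10k_to_date",
    "slowest_1k_to_date",
    "slowest_5k_to_date",
    "slowest_10k_to_date",
)
WINDOW_DISTANCES_M = (1000, 5000, 10000)
#: successive half-widths (minutes) of the goal-time candidate window
WIDENING_MINUTES = (1.0, 2.0, 4.0, 8.0)


class NoRecommendationError(LookupError):
    """No candidate case exists even after bounded window widening."""


@dataclass
class Session:
    distance_km: float
    pace_min_per_km: float


@dataclass
class TrainingCase:
    """One runner-week feature vector with its actual next week of training."""

    case_id: str
    runner_id: str
    sex: str
    week: int
    features: np.ndarray  # aligned to FEATURE_NAMES
    marathon_time: float
    next_week: list[Session] = field(default_factory=list)

    def feature(self, name: str) -> float:
        return float(self.features[FEATURE_NAMES.index(name)])


@dataclass
class Recommendation:
    plan: list[Session]
    provenance: str  # case_id of the reused case
    distance: float  # feature-space distance of the winning case
    window: float  # goal-time half-width that produced candidates

    @property
    def total_distance(self) -> float:
        return sum(s.distance_km for s in self.plan)

    @property
    def mean_pace(self) -> float:
        dist = self.total_distance
        if dist == 0:
            return math.nan
        return sum(s.distance_km * s.pace_min_per_km for s in self.plan) / dist


class NormalizedVector(np.ndarray):
    """Marker type: a feature vector already z-scored against a case base."""


def window_extremes(series: IntervalSeries, distance_m: int) -> tuple[float, float]:
    """(fastest, slowest) contiguous-window mean pace at a given distance."""
    w = int(distance_m // INTERVAL_M)
    t = series.interval_times
    if t.size < w:
        return math.nan, math.nan
    csum = np.concatenate([[0.0], np.cumsum(t)])
    sums = csum[w:] - csum[:-w]
    dist_km = distance_m / 1000.0
    return float(sums.min() / 60.0 / dist_km), float(sums.max() / 60.0 / dist_km)


def _week_sessions(acts: list[IntervalSeries]) -> list[Session]:
    return [Session(a.total_distance_km, a.mean_pace) for a in acts]


def build_training_case(history: RunnerHistory, week: int) -> TrainingCase | None:
    """Build the Table-style case for one runner-week.

    Returns None when the week holds no activities (no case).  ``week`` must
    be >= 1 so that a next week of training exists to recommend.
    """
    if week < 1:
        raise ValueError("recommendable cases need week >= 1")
    if history.marathon_time is None:
        raise ValueError("history needs a marathon_time")
    by_week = weekly_partition(history)
    acts = by_week.get(week, [])
    if not acts:
        return None
    to_date = [a for w, group in by_week.items() if w >= week for a in group]

    def extremes(group: list[IntervalSeries]) -> dict[str, float]:
        out = {}
        for d in WINDOW_DISTANCES_M:
            fastest, slowest = math.nan, math.nan
            for a in group:
                f, s = window_extremes(a, d)
                if not math.isnan(f):
                    fastest = f if math.isnan(fastest) else min(fastest, f)
                    slowest = s if math.isnan(slowest) else max(slowest, s)
            label = f"{d // 1000}k"
            out[f"fastest_{label}"] = fastest
            out[f"slowest_{label}"] = slowest
        return out

    total_km = sum(a.total_distance_km for a in acts)
    total_min = sum(a.duration_s for a in acts) / 60.0
    week_ext = extremes(acts)
    td_ext = extremes(to_date)
    values = {
        "sex": 1.0 if history.sex == "M" else 0.0,
        "num_sessions": float(len(acts)),
        "total_distance": total_km,
        "mean_pace": total_min / total_km,
        "longest_run": max(a.total_distance_km for a in acts),
        "longest_run_to_date": max(a.total_distance_km for a in to_date),
        **week_ext,
        **{f"{k}_to_date": v for k, v in td_ext.items()},
    }
    features = np.array([values[name] for name in FEATURE_NAMES], dtype=float)
    return TrainingCase(
        case_id=f"{history.runner_id}:w{week}",
        runner_id=history.runner_id,
        sex=history.sex,
        week=week,
        features=features,
        marathon_time=float(history.marathon_time),
        next_week=_week_sessions(by_week.get(week - 1, [])),
    )


class CaseBase:
    """Cases keyed by (week, sex) with per-base normalisation statistics."""

    def __init__(self) -> None:
        self._cases: dict[tuple[int, str], list[TrainingCase]] = {}
        self._stats: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}

    @classmethod
    def build(cls, histories: list[RunnerHistory], weeks: range | None = None) -> "CaseBase":
        base = cls()
        weeks = weeks if weeks is not None else range(1, 12)
        for h in histories:
            for w in weeks:
                case = build_training_case(h, w)
                if case is not None and case.next_week:
                    base.add(case)
        base.fit_stats()
        return base

    def add(self, case: TrainingCase) -> None:
        self._cases.setdefault((case.week, case.sex), []).append(case)

    def fit_stats(self) -> None:
        import warnings

        for key, cases in self._cases.items():
            x = np.vstack([c.features for c in cases])
            with warnings.catch_warnings():
                # all-NaN feature columns (e.g. no 10 km window run) are fine
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(x, axis=0)
                std = np.nanstd(x, axis=0)
            self._stats[key] = (np.nan_to_num(mean), np.nan_to_num(std))

    def cases(self, week: int, sex: str) -> list[TrainingCase]:
        return self._cases.get((week, sex), [])

    def runner_block(self, runner_id: str, sex: str, weeks: list[int]) -> list[TrainingCase] | None:
        """The runner's cases at the given weeks, or None if incomplete."""
        block = []
        for w in weeks:
            found = [c for c in self.cases(w, sex) if c.runner_id == runner_id]
            if not found:
                return None
            block.append(found[0])
        return block

    def normalize(self, vector: np.ndarray, week: int, sex: str) -> NormalizedVector:
        """z-score a raw feature vector against the (week, sex) base stats.

        Missing features map to the base mean (z = 0).  Re-normalising an
        already-normalised vector is rejected.
        """
        if isinstance(vector, NormalizedVector):
            raise TypeError("vector is already normalised against a case base")
        mean, std = self._stats.get((week, sex), (None, None))
        if mean is None:
            raise NoRecommendationError(f"empty case base for week {week}, sex {sex}")
        safe_std = np.where(std > 0, std, 1.0)
        z = (np.asarray(vector, dtype=float) - mean) / safe_std
        z = np.where(np.isnan(z) | (std == 0), 0.0, z)
        return z.view(NormalizedVector)


def _nearest(
    query_z: np.ndarray,
    candidates: list[TrainingCase],
    cand_z: np.ndarray,
    target_time: float,
) -> tuple[TrainingCase, float]:
    dists = np.sqrt(((cand_z - query_z) ** 2).sum(axis=1))
    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            dists[i],
            abs(candidates[i].marathon_time - target_time),
            candidates[i].case_id,
        ),
    )
    best = order[0]
    return candidates[best], float(dists[best])


def recommend_next_week(
    query: TrainingCase,
    base: CaseBase,
    target_time: float,
    exclude_runner: str | None = None,
) -> Recommendation:
    """1-NN retrieval of a next-week plan for an adjusted goal time.

    Candidates are same-sex week-w cases with marathon times within 1 minute
    of the goal (widened to 2/4/8 minutes if empty); the Euclidean nearest
    neighbour on z-scored features wins and its stored next week is returned
    unmodified.
    """
    pool = [
        c
        for c in base.cases(query.week, query.sex)
        if c.case_id != query.case_id and c.runner_id != (exclude_runner or query.runner_id)
    ]
    if not pool:
        raise NoRecommendationError(
            f"no cases for week {query.week}, sex {query.sex}"
        )
    query_z = base.normalize(query.features, query.week, query.sex)
    for width in WIDENING_MINUTES:
        candidates = [c for c in pool if abs(c.marathon_time - target_time) <= width]
        if not candidates:
            continue
        cand_z = np.vstack(
            [base.normalize(c.features, query.week, query.sex) for c in candidates]
        )
        case, dist = _nearest(query_z, candidates, cand_z, target_time)
        return Recommendation(case.next_week, case.case_id, dist, width)
    raise NoRecommendationError(
        f"no cases within ±{WIDENING_MINUTES[-1]} min of {target_time:.1f} min"
    )


def recommend_ensemble(
    queries: dict[int, TrainingCase],
    base: CaseBase,
    target_time: float,
    ordered: bool = False,
    exclude_runner: str | None = None,
) -> Recommendation:
    """Recommendation from the 4 most recent training weeks.

    Unordered mode retrieves week-by-week (query week w+i vs case base
    w+i); ordered mode first rank-aligns both the query weeks and each
    candidate runner's 4-week block in ascending order of long-run distance,
    then matches rank-for-rank.  The next week of the globally most similar
    retrieved case is recommended.
    """
    weeks = sorted(queries)
    if len(weeks) != 4 or weeks != list(range(weeks[0], weeks[0] + 4)):
        raise ValueError("queries must cover 4 consecutive weeks")
    sex = queries[weeks[0]].sex
    results: list[tuple[TrainingCase, float]] = []

    if not ordered:
        for w in weeks:
            try:
                rec_pool = [
                    c
                    for c in base.cases(w, sex)
                    if c.runner_id != (exclude_runner or queries[w].runner_id)
                ]
                results.extend(
                    _retrieve_ranked(queries[w], rec_pool, base, w, sex, target_time)
                )
            except NoRecommendationError:
                continue
    else:
        q_sorted = sorted(queries.values(), key=lambda c: c.feature("longest_run"))
        runner_ids = {
            c.runner_id
            for w in weeks
            for c in base.cases(w, sex)
            if c.runner_id != (exclude_runner or q_sorted[0].runner_id)
        }
        blocks = []
        for rid in sorted(runner_ids):
            block = base.runner_block(rid, sex, weeks)
            if block is not None:
                blocks.append(sorted(block, key=lambda c: c.feature("longest_run")))
        for rank, (q, w) in enumerate(zip(q_sorted, weeks)):
            pool = [b[rank] for b in blocks]
            results.extend(_retrieve_ranked(q, pool, base, w, sex, target_time))

    if not results:
        raise NoRecommendationError("all ensemble retrievals were empty")
    case, dist = min(results, key=lambda r: (r[1], r[0].case_id))
    return Recommendation(case.next_week, case.case_id, dist, math.nan)


def _retrieve_ranked(
    query: TrainingCase,
    pool: list[TrainingCase],
    base: CaseBase,
    stats_week: int,
    sex: str,
    target_time: float,
) -> list[tuple[TrainingCase, float]]:
    if not pool:
        return []
    query_z = base.normalize(query.features, stats_week, sex)
    for width in WIDENING_MINUTES:
        candidates = [c for c in pool if abs(c.marathon_time - target_time) <= width]
        if not candidates:
            continue
        cand_z = np.vstack(
            [base.normalize(c.features, stats_week, sex) for c in candidates]
        )
        return [_nearest(query_z, candidates, cand_z, target_time)]
    return []


def evaluate_recommendations(
    histories: list[RunnerHistory],
    delta_grid: tuple[float, ...] = (-20, -10, -5, 0, 5, 10, 20),
    weeks: tuple[int, ...] = (4, 6, 8),
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Goal-adjustment sweep: how recommended plans respond to ±delta goals.

    Runner-grouped tenfold cross-validation; for each test runner, week and
    delta, a plan is recommended for goal time MT + delta and compared with
    the runner's actual executed next week (% difference of total distance
    and of mean pace).  With delta = 0 the runner's own cases are excluded,
    so the reference is the nearest neighbour, not the runner themselves.
    """
    folds = runner_folds([h.runner_id for h in histories], n_folds, seed)
    by_id = {h.runner_id: h for h in histories}
    rows = []
    for fold_idx, test_ids in enumerate(folds):
        train = [h for h in histories if h.runner_id not in set(test_ids)]
        base = CaseBase.build(train, weeks=range(1, 13))
        for rid in test_ids:
            h = by_id[rid]
            for w in weeks:
                query = build_training_case(h, w)
                if query is None or not query.next_week:
                    continue
                actual_dist = sum(s.distance_km for s in query.next_week)
                actual_pace = (
                    sum(s.distance_km * s.pace_min_per_km for s in query.next_week)
                    / actual_dist
                )
                for delta in delta_grid:
                    try:
                        rec = recommend_next_week(
                            query, base, query.marathon_time + delta
                        )
                    except NoRecommendationError:
                        continue
                    rows.append(
                        {
                            "fold": fold_idx,
                            "runner_id": rid,
                            "sex": h.sex,
                            "week": w,
                            "delta": delta,
                            "pct_dpace": 100.0 * (rec.mean_pace - actual_pace) / actual_pace,
                            "pct_ddistance": 100.0
                            * (rec.total_distance - actual_dist)
                            / actual_dist,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "fold", "runner_id", "sex", "week", "delta", "pct_dpace", "pct_ddistance",
        ],
    )


def delta_response(results: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlations of mean %Δpace and %Δdistance with delta."""
    means = results.groupby("delta")[["pct_dpace", "pct_ddistance"]].mean()
    r_pace = float(sstats.pearsonr(means.index, means["pct_dpace"])[0])
    r_dist = float(sstats.pearsonr(means.index, means["pct_ddistance"])[0])
    return r_pace, r_dist
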