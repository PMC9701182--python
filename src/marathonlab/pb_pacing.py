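"""Personal-best prediction and pacing-plan recommendation from race histories.

Each runner's fastest marathon is their personal best (PB); pairing every
other (non-PB) race with the PB yields cases that encode a concrete
progression: "a runner who ran *this* race went on to run *that* PB".  For
a target runner, their non-PB race — a nine-segment relative pacing profile
plus finish time — retrieves the k most similar cases by cosine similarity
(sex-stratified), and the retrieved PBs are combined into a finish-time
prediction and an absolute pacing plan by one of three strategies: *best*
(fastest retrieved PB), *mean* (similarity-weighted mean) or *even* (the
PB with the most even pacing profile).  A small in-race feedback rule
compares current to planned pace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import MARATHON_KM, SEGMENT_LENGTHS_KM, RaceRecord
from .fitness_models import runner_folds

STRATEGIES = ("best", "mean", "even")


@dataclass
class RelativeProfile:
    """Nine segment paces relative to the race's mean pace."""

    relative_paces: np.ndarray  # length 9, length-weighted mean exactly 1
    mean_race_pace: float  # min/km

    def __post_init__(self) -> None:
        self.relative_paces = np.asarray(self.relative_paces, dtype=float)
        if self.relative_paces.shape != (9,):
            raise ValueError("profile needs exactly 9 relative paces")


@dataclass
class PBCase:
    """One non-PB -> PB progression for a runner."""

    case_id: str
    runner_id: str
    sex: str
    npb_profile: RelativeProfile
    npb_finish: float  # minutes
    pb_profile: RelativeProfile
    pb_finish: float  # minutes

    def __post_init__(self) -> None:
        if self.pb_finish > self.npb_finish:
            raise ValueError("PB must not be slower than the non-PB race")


@dataclass
class PacingPlan:
    """Absolute per-segment target paces realising a predicted finish."""

    paces: np.ndarray  # min/km, length 9
    predicted_finish: float  # minutes

    def __post_init__(self) -> None:
        self.paces = np.asarray(self.paces, dtype=float)
        implied = float(self.paces @ SEGMENT_LENGTHS_KM)
        if abs(implied - self.predicted_finish) > 0.005 * self.predicted_finish:
            raise ValueError("plan paces do not reproduce the predicted finish")

    @property
    def relative(self) -> np.ndarray:
        return self.paces / (self.predicted_finish / MARATHON_KM)


def relative_profile(record: RaceRecord) -> RelativeProfile:
    """Segment paces divided by the profile-implied mean race pace."""
    mean_pace = float(record.segment_paces @ SEGMENT_LENGTHS_KM) / MARATHON_KM
    if mean_pace <= 0:
        raise ValueError("zero finish time")
    return RelativeProfile(record.segment_paces / mean_pace, mean_pace)


def build_pb_cases(records: list[RaceRecord]) -> list[PBCase]:
    """Pair each runner's non-PB races with their single PB race.

    The PB is the fastest race (ties broken by earliest year); a runner with
    k >= 2 races yields k - 1 cases.
    """
    cases = []
    by_runner: dict[str, list[RaceRecord]] = {}
    for r in records:
        by_runner.setdefault(r.runner_id, []).append(r)
    for rid in sorted(by_runner):
        races = sorted(by_runner[rid], key=lambda r: (r.finish_time, r.year))
        if len(races) < 2:
            continue
        pb = races[0]
        for npb in sorted(races[1:], key=lambda r: r.year):
            cases.append(
                PBCase(
                    case_id=f"{rid}:{npb.marathon_id}->{pb.marathon_id}",
                    runner_id=rid,
                    sex=npb.sex,
                    npb_profile=relative_profile(npb),
                    npb_finish=npb.finish_time,
                    pb_profile=relative_profile(pb),
                    pb_finish=pb.finish_time,
                )
            )
    return cases


def _finish_scaler(cases: list[PBCase]) -> tuple[float, float]:
    finishes = [c.npb_finish for c in cases]
    lo, hi = min(finishes), max(finishes)
    return lo, (hi - lo) if hi > lo else 1.0


def _query_vector(profile: RelativeProfile, finish: float, lo: float, span: float) -> np.ndarray:
    return np.concatenate([profile.relative_paces, [(finish - lo) / span]])


def retrieve_similar(
    query_profile: RelativeProfile,
    query_finish: float,
    base: list[PBCase],
    k: int,
    sex: str,
    exclude_runner: str | None = None,
) -> list[tuple[PBCase, float]]:
    """Top-k cases by cosine similarity on [relative paces ‖ scaled finish].

    The non-PB finish time is min-max scaled over the sex stratum so it is
    commensurate with the nine relative pace coordinates; same-runner cases
    are excluded; ties break by case id.
    """
    stratum = [
        c for c in base if c.sex == sex and c.runner_id != exclude_runner
    ]
    if not stratum:
        raise LookupError(f"empty case base for sex {sex}")
    lo, span = _finish_scaler(stratum)
    q = _query_vector(query_profile, query_finish, lo, span)
    mat = np.vstack(
        [_query_vector(c.npb_profile, c.npb_finish, lo, span) for c in stratum]
    )
    sims = (mat @ q) / (np.linalg.norm(mat, axis=1) * np.linalg.norm(q))
    order = sorted(
        range(len(stratum)), key=lambda i: (-sims[i], stratum[i].case_id)
    )[: max(k, 0)]
    return [(stratum[i], float(sims[i])) for i in order]


def predict_pb(
    retrieved: list[tuple[PBCase, float]], strategy: str = "mean"
) -> PacingPlan:
    """Combine retrieved PBs into a finish prediction and pacing plan."""
    if not retrieved:
        raise ValueError("need at least one retrieved case")
    if strategy == "best":
        case = min(retrieved, key=lambda r: (r[0].pb_finish, r[0].case_id))[0]
        finish, rel = case.pb_finish, case.pb_profile.relative_paces
    elif strategy == "mean":
        weights = np.array([max(sim, 1e-12) for _, sim in retrieved])
        finishes = np.array([c.pb_finish for c, _ in retrieved])
        profiles = np.vstack([c.pb_profile.relative_paces for c, _ in retrieved])
        finish = float(weights @ finishes / weights.sum())
        rel = weights @ profiles / weights.sum()
    elif strategy == "even":
        def cv(case: PBCase) -> float:
            r = case.pb_profile.relative_paces
            return float(r.std(ddof=0) / r.mean())

        case = min(retrieved, key=lambda r: (cv(r[0]), r[0].case_id))[0]
        finish, rel = case.pb_finish, case.pb_profile.relative_paces
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return PacingPlan(rel * (finish / MARATHON_KM), finish)


def plan_similarity(plan: PacingPlan, actual: RelativeProfile) -> float:
    """Cosine similarity of recommended vs actual relative pacing profiles."""
    a, b = plan.relative, actual.relative_paces
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def finish_band(finish_min: float) -> str:
    """PB finish-time ability band (minutes -> label)."""
    if finish_min < 180:
        return "<3h"
    if finish_min < 210:
        return "3h-3h30"
    if finish_min < 240:
        return "3h30-4h"
    return ">=4h"


def evaluate_pb(
    cases: list[PBCase],
    strategies: tuple[str, ...] = STRATEGIES,
    k_grid: range = range(1, 21),
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentage PB prediction error and plan similarity, k-averaged.

    Runner-grouped folds keep every case of a test runner out of the
    training case base (splits are therefore only approximately 10/90).
    Errors are |predicted - actual PB| / actual PB x 100; results are
    averaged over k for each case and reported per strategy with the
    runner's sex and PB ability band.
    """
    folds = runner_folds([c.runner_id for c in cases], n_folds, seed)
    rows = []
    for fold_idx, test_runners in enumerate(folds):
        test_set = set(test_runners)
        train = [c for c in cases if c.runner_id not in test_set]
        test = [c for c in cases if c.runner_id in test_set]
        for case in test:
            try:
                ranked = retrieve_similar(
                    case.npb_profile,
                    case.npb_finish,
                    train,
                    max(k_grid),
                    case.sex,
                    exclude_runner=case.runner_id,
                )
            except LookupError:
                continue
            for strategy in strategies:
                errs, sims = [], []
                for k in k_grid:
                    plan = predict_pb(ranked[:k], strategy)
                    errs.append(
                        100.0 * abs(plan.predicted_finish - case.pb_finish) / case.pb_finish
                    )
                    sims.append(plan_similarity(plan, case.pb_profile))
                rows.append(
                    {
                        "fold": fold_idx,
                        "runner_id": case.runner_id,
                        "case_id": case.case_id,
                        "sex": case.sex,
                        "band": finish_band(case.pb_finish),
                        "strategy": strategy,
                        "error_pct": float(np.mean(errs)),
                        "plan_similarity": float(np.mean(sims)),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "fold", "runner_id", "case_id", "sex", "band", "strategy",
            "error_pct", "plan_similarity",
        ],
    )


def in_race_feedback(
    current_pace: float, planned_pace: float, tolerance_s_per_km: float = 3.0
) -> str:
    """Pace feedback: paces are min/km, so smaller means faster.

    Running faster than plan (current < planned - tol) earns "slow-down";
    slower than plan earns "speed-up"; otherwise "on-pace".
    """
    if current_pace <= 0 or planned_pace <= 0:
        raise ValueError("paces must be positive")
    tol = tolerance_s_per_km / 60.0
    if current_pace < planned_pace - tol:
        return "slow-down"
    if current_pace > planned_pace + tol:
        return "speed-up"
    return "on-pace"
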