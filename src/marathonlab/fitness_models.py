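"""Fitness representations mined from raw training streams.

Four fitness models are computed from the fastest paces a runner has
*happened* to run in training (no supervised time trials required):

* **FP** — cumulative fastest paces over benchmark distances (1500 m, 5 km,
  10 km);
* **FTP** — functional threshold pace: the fastest pace sustained over
  45/50/55/60-minute spans;
* **VO2** — mean and standard deviation of Daniels–Gilbert VO2max estimates
  over fastest paces for distances 1500 m–30 km;
* **CV** — critical speed CS and capacity D' from the linear distance vs
  time-to-exhaustion relationship D = D' + CS * T_lim.

A weekly feature matrix over the final 12 training weeks feeds a
runner-grouped cross-validated marathon-time prediction harness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import INTERVAL_M, IntervalSeries, RunnerHistory, weekly_partition

FP_DISTANCES_M = (1500, 5000, 10000)
FTP_MINUTES = (45, 50, 55, 60)
#: distance range (m) mined for the VO2max and critical-speed models
MINING_RANGE_M = (1500, 30000)

FP_FEATURES = ("fp_1500m", "fp_5k", "fp_10k")
FTP_FEATURES = ("ftp_45", "ftp_50", "ftp_55", "ftp_60")
VO2_FEATURES = ("vo2_mean", "vo2_std")
CV_FEATURES = ("cs", "dprime")
MODEL_FEATURES = {
    "FP": FP_FEATURES,
    "FTP": FTP_FEATURES,
    "VO2": VO2_FEATURES,
    "CV": CV_FEATURES,
    "CB": FP_FEATURES + FTP_FEATURES + VO2_FEATURES + CV_FEATURES,
}


class DegenerateFitError(ValueError):
    """Critical-speed regression attempted on a degenerate point set."""


@dataclass
class FastestPaceTable:
    """Mapping 100 m-multiple distance (m) -> fastest pace (min/km)."""

    paces: dict[int, float] = field(default_factory=dict)
    scope: str = "activity"  # "activity" or "cumulative"

    def get(self, distance_m: int) -> float:
        return self.paces.get(int(distance_m), math.nan)

    def in_range(self, lo_m: float, hi_m: float) -> tuple[np.ndarray, np.ndarray]:
        """Distances and paces with lo <= d <= hi, distance-sorted."""
        ds = np.array(sorted(d for d in self.paces if lo_m <= d <= hi_m), dtype=float)
        ps = np.array([self.paces[int(d)] for d in ds])
        return ds, ps

    def __len__(self) -> int:
        return len(self.paces)


def fastest_paces(
    series: IntervalSeries, max_distance_m: float | None = None
) -> FastestPaceTable:
    """Fastest mean pace over every contiguous within-activity window.

    For each window length of w intervals (w * 100 m up to the activity
    length, optionally capped), the table stores the minimum mean pace over
    all contiguous windows of that length.
    """
    t = series.interval_times
    m = t.size
    w_max = m if max_distance_m is None else min(m, int(max_distance_m // INTERVAL_M))
    csum = np.concatenate([[0.0], np.cumsum(t)])
    table: dict[int, float] = {}
    for w in range(1, w_max + 1):
        best_time = float(np.min(csum[w:] - csum[:-w]))
        dist_km = w * INTERVAL_M / 1000.0
        table[int(w * INTERVAL_M)] = (best_time / 60.0) / dist_km
    return FastestPaceTable(table, scope="activity")


def cumulative_fastest(tables: list[FastestPaceTable]) -> list[FastestPaceTable]:
    """Running elementwise minimum over date-ordered per-activity tables."""
    out: list[FastestPaceTable] = []
    running: dict[int, float] = {}
    for tab in tables:
        for d, p in tab.paces.items():
            if p < running.get(d, math.inf):
                running[d] = p
        out.append(FastestPaceTable(dict(running), scope="cumulative"))
    return out


def fp_features(cum: FastestPaceTable) -> dict[str, float]:
    """Fastest-pace model features (Fastest 1500 m / 5 km / 10 km so far)."""
    return {
        name: cum.get(dist) for name, dist in zip(FP_FEATURES, FP_DISTANCES_M)
    }


def best_span_pace(series: IntervalSeries, minutes: float) -> float:
    """Fastest mean pace over any contiguous span of duration >= ``minutes``.

    Returns NaN when the whole activity is shorter than the span.
    """
    t = series.interval_times
    target_s = minutes * 60.0
    if t.sum() < target_s:
        return math.nan
    csum = np.concatenate([[0.0], np.cumsum(t)])
    # span (i, j]: duration csum[j]-csum[i], distance (j-i)*100 m
    dur = csum[None, :] - csum[:, None]
    n = np.arange(csum.size)
    dist_km = (n[None, :] - n[:, None]) * INTERVAL_M / 1000.0
    mask = dur >= target_s
    with np.errstate(divide="ignore", invalid="ignore"):
        pace = np.where(mask, (dur / 60.0) / dist_km, np.inf)
    return float(pace.min())


def ftp_features(
    activities: list[IntervalSeries], durations: tuple[int, ...] = FTP_MINUTES
) -> dict[str, float]:
    """FTP model features: fastest pace sustained for each duration so far."""
    out = {f"ftp_{d}": math.nan for d in durations}
    for act in activities:
        for d in durations:
            pace = best_span_pace(act, d)
            key = f"ftp_{d}"
            if not math.isnan(pace) and not pace >= out[key]:  # NaN-safe min
                out[key] = pace
    return out


def vo2max_estimate(t_min: float, v_m_per_min: float) -> float:
    """Daniels–Gilbert VO2max estimate from a maximal effort.

    ``t_min`` is the effort duration in minutes and ``v_m_per_min`` its
    velocity in metres/minute.  The estimate is the ratio of the oxygen cost
    of running at v to the fraction of VO2max sustainable for t minutes.
    """
    if t_min <= 0 or v_m_per_min <= 0:
        raise ValueError("duration and velocity must be positive")
    frac = (
        0.8
        + 0.1894393 * math.exp(-0.012778 * t_min)
        + 0.2989558 * math.exp(-0.1932605 * t_min)
    )
    vo2 = -4.6 + 0.182258 * v_m_per_min + 0.000104 * v_m_per_min**2
    return vo2 / frac


def vo2_features(
    cum: FastestPaceTable, mining_range: tuple[float, float] = MINING_RANGE_M
) -> dict[str, float]:
    """Mean and population SD of VO2max estimates over mined distances."""
    ds, ps = cum.in_range(*mining_range)
    if ds.size < 2:
        return {"vo2_mean": math.nan, "vo2_std": math.nan}
    t_min = (ds / 1000.0) * ps  # duration of the fastest effort, minutes
    v = ds / t_min  # metres per minute
    est = np.array([vo2max_estimate(t, vel) for t, vel in zip(t_min, v)])
    return {"vo2_mean": float(est.mean()), "vo2_std": float(est.std(ddof=0))}


def tlim_estimate(distance_m: float, pace_min_per_km: float) -> float:
    """Estimated time-to-exhaustion (seconds) at the fastest observed pace."""
    if distance_m <= 0 or pace_min_per_km <= 0:
        raise ValueError("distance and pace must be positive")
    return (distance_m / 1000.0) * pace_min_per_km * 60.0


def cv_fit(
    cum: FastestPaceTable, mining_range: tuple[float, float] = MINING_RANGE_M
) -> tuple[float, float]:
    """Critical speed CS (m/s) and D' (m) from D = D' + CS * T_lim.

    Ordinary least squares of distance (m) on estimated time-to-exhaustion
    (s) over the mined distance range; the slope is CS, the intercept D'.
    """
    ds, ps = cum.in_range(*mining_range)
    if ds.size < 2:
        raise DegenerateFitError("need >= 2 distances for the critical-speed fit")
    tlim = np.array([tlim_estimate(d, p) for d, p in zip(ds, ps)])
    if np.ptp(tlim) == 0:
        raise DegenerateFitError("identical T_lim values")
    fit = stats.linregress(tlim, ds)
    return float(fit.slope), float(fit.intercept)


# ---------------------------------------------------------------------------
# Weekly feature matrix + prediction harness
# ---------------------------------------------------------------------------

def build_weekly_matrix(
    histories: list[RunnerHistory],
    model: str = "CB",
    weeks: tuple[int, int] = (11, 0),
) -> pd.DataFrame:
    """One row per runner x training week with that model's fitness features.

    Week w uses the cumulative fastest paces over all activities up to and
    including week w (weeks count down to race-day); inactive weeks carry the
    previous cumulative values forward.
    """
    if model not in MODEL_FEATURES:
        raise ValueError(f"unknown model {model!r}")
    feature_names = MODEL_FEATURES[model]
    first_week, last_week = weeks
    rows = []
    for h in histories:
        by_week = weekly_partition(h)
        start = max(list(by_week) + [first_week])
        cum: dict[int, float] = {}
        seen_activities: list[IntervalSeries] = []
        ftp_running = {f: math.nan for f in FTP_FEATURES}
        for w in range(start, last_week - 1, -1):
            for act in by_week.get(w, []):
                seen_activities.append(act)
                tab = fastest_paces(act, max_distance_m=MINING_RANGE_M[1])
                for d, p in tab.paces.items():
                    if p < cum.get(d, math.inf):
                        cum[d] = p
                if act.duration_s >= min(FTP_MINUTES) * 60.0:
                    for mins in FTP_MINUTES:
                        pace = best_span_pace(act, mins)
                        key = f"ftp_{mins}"
                        if not math.isnan(pace) and not pace >= ftp_running[key]:
                            ftp_running[key] = pace
            if w > first_week:
                continue
            table = FastestPaceTable(cum, scope="cumulative")
            feats: dict[str, float] = {}
            feats.update(fp_features(table))
            feats.update(ftp_running)
            feats.update(vo2_features(table))
            try:
                cs, dprime = cv_fit(table)
            except DegenerateFitError:
                cs, dprime = math.nan, math.nan
            feats.update({"cs": cs, "dprime": dprime})
            row = {
                "runner_id": h.runner_id,
                "week": w,
                "model": model,
                "sex": 1.0 if h.sex == "M" else 0.0,
                "age": math.nan if h.age is None else h.age,
                "marathon_time": math.nan if h.marathon_time is None else h.marathon_time,
            }
            row.update({f: feats[f] for f in feature_names})
            rows.append(row)
    columns = ["runner_id", "week", "model", "sex", "age", "marathon_time"] + list(
        feature_names
    )
    return pd.DataFrame(rows, columns=columns)


def default_regressor_factory(seed: int = 0):
    """Gradient boosting with 100 boosting stages and squared-error loss."""
    from sklearn.ensemble import GradientBoostingRegressor

    def factory():
        return GradientBoostingRegressor(
            loss="squared_error", learning_rate=0.1, n_estimators=100, random_state=seed
        )

    return factory


def runner_folds(runner_ids: list[str], n_folds: int, seed: int) -> list[list[str]]:
    """Deterministic runner-grouped fold assignment."""
    runners = sorted(set(runner_ids))
    if len(runners) < n_folds:
        raise ValueError(f"need >= {n_folds} runners, got {len(runners)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(runners))
    return [[runners[i] for i in order[f::n_folds]] for f in range(n_folds)]


def evaluate_prediction(
    matrix: pd.DataFrame,
    regressor_factory=None,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Runner-grouped cross-validated marathon-time prediction error.

    Folds are grouped by runner so a test runner never contributes training
    rows.  Missing features are imputed with the training-fold mean.  Returns
    a tidy frame with columns (week, fold, mae) in minutes.
    """
    if regressor_factory is None:
        regressor_factory = default_regressor_factory(seed)
    feature_cols = [
        c
        for c in matrix.columns
        if c not in ("runner_id", "week", "model", "marathon_time")
    ]
    folds = runner_folds(matrix["runner_id"].tolist(), n_folds, seed)
    records = []
    for fold_idx, test_runners in enumerate(folds):
        test_mask = matrix["runner_id"].isin(test_runners)
        for week, wk in matrix.groupby("week"):
            train = wk[~wk["runner_id"].isin(test_runners)]
            test = wk[wk["runner_id"].isin(test_runners)]
            if train.empty or test.empty:
                continue
            x_train = train[feature_cols].to_numpy(dtype=float)
            x_test = test[feature_cols].to_numpy(dtype=float)
            counts = np.sum(~np.isnan(x_train), axis=0)
            sums = np.nansum(x_train, axis=0)
            col_means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
            x_train = np.where(np.isnan(x_train), col_means, x_train)
            x_test = np.where(np.isnan(x_test), col_means, x_test)
            reg = regressor_factory()
            reg.fit(x_train, train["marathon_time"].to_numpy(dtype=float))
            pred = reg.predict(x_test)
            mae = float(
                np.abs(pred - test["marathon_time"].to_numpy(dtype=float)).mean()
            )
            records.append({"week": week, "fold": fold_idx, "mae": mae})
    return pd.DataFrame(records, columns=["week", "fold", "mae"])


def mae_by_week(result: pd.DataFrame) -> pd.Series:
    """Average fold MAE per training week."""
    return result.groupby("week")["mae"].mean()
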