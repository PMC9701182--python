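"""Training-disruption detection and injury-risk scoring.

Long gaps between logged activities are used as an injury proxy: an
activity *starts a break* when more than n days pass before the next
activity.  The prediction task is: given an activity, will some activity in
the next m days start a break of more than n days?  Instances carry four
feature groups — baseline (sex, age, days before race), ability (cumulative
fastest 1/5/10 km paces), disruption history (previous break, days since),
and training load (acute:chronic workload ratios over 4/6/8-week chronic
windows).  Because positives are rare the training folds are re-balanced by
random undersampling (never the test folds), and beyond the hard class
prediction the positive-class probability is exposed as a calibrated risk
score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core_data import INTERVAL_M, IntervalSeries, RunnerHistory
from .fitness_models import runner_folds

B_FEATURES = ("sex", "age", "days_before_race")
A_FEATURES = ("fastest_1k", "fastest_5k", "fastest_10k")
H_FEATURES = ("has_prev_break", "days_since_break")
T_FEATURES = ("acr_1w_4w", "acr_1w_6w", "acr_1w_8w")
ALL_FEATURES = B_FEATURES + A_FEATURES + H_FEATURES + T_FEATURES


@dataclass
class RiskReport:
    risk_score: float  # positive-class probability in [0, 1]
    cohort_incidence: float  # break incidence among similarly-scored runners
    relative_risk: float  # cohort incidence / overall incidence


def next_gaps(history: RunnerHistory) -> np.ndarray:
    """Days between each activity and the next (length n_activities - 1)."""
    ords = np.array([a.date.toordinal() for a in history.activities])
    if ords.size < 2:
        return np.array([], dtype=int)
    return np.diff(ords).astype(int)


def break_label(history: RunnerHistory, i: int, n: int, m: float) -> bool | None:
    """Does a break of more than n days begin within m days after activity i?

    True iff some later activity j > i dated within m days of activity i is
    followed by a gap strictly greater than n days.  m = inf means "up to
    race-day".  Returns None when the look-ahead window extends beyond
    race-day (the label is unobservable and the instance must be excluded).
    """
    acts = history.activities
    if not 0 <= i < len(acts):
        raise IndexError("activity index out of range")
    date_i = acts[i].date
    if math.isfinite(m) and (history.race_date - date_i).days < m:
        return None
    gaps = next_gaps(history)
    for j in range(i + 1, len(acts)):
        if (acts[j].date - date_i).days > m:
            break
        # gap after activity j (to activity j+1); undefined for the last one
        if j < gaps.size and gaps[j] > n:
            return True
    return False


def acr_from_arrays(
    ords: np.ndarray, kms: np.ndarray, at_ord: int, chronic_weeks: int
) -> float:
    """Acute:chronic ratio on raw (date ordinal, km) arrays.

    Acute load is the km total over the 7 days ending at ``at_ord``; chronic
    load is the mean of the preceding ``chronic_weeks`` rolling 7-day blocks.
    NaN when the history does not span the chronic window or chronic load is
    zero.
    """
    if ords.size == 0 or at_ord - int(ords[0]) < 7 * chronic_weeks:
        return float("nan")
    acute = float(kms[(ords > at_ord - 7) & (ords <= at_ord)].sum())
    blocks = [
        float(kms[(ords > at_ord - 7 * (b + 1)) & (ords <= at_ord - 7 * b)].sum())
        for b in range(1, chronic_weeks + 1)
    ]
    chronic = float(np.mean(blocks))
    if chronic == 0.0:
        return float("nan")
    return acute / chronic


def acr(history: RunnerHistory, date, chronic_weeks: int = 4) -> float:
    """Acute:chronic workload ratio anchored at ``date`` (rolling 7-day blocks)."""
    if chronic_weeks not in (4, 6, 8):
        raise ValueError("chronic_weeks must be one of 4, 6, 8")
    ords = np.array([a.date.toordinal() for a in history.activities])
    kms = np.array([a.total_distance_km for a in history.activities])
    return acr_from_arrays(ords, kms, date.toordinal(), chronic_weeks)


def _fastest_window_time(series: IntervalSeries, w: int) -> float:
    t = series.interval_times
    if t.size < w:
        return math.nan
    csum = np.concatenate([[0.0], np.cumsum(t)])
    return float(np.min(csum[w:] - csum[:-w]))


def build_instances(histories: list[RunnerHistory], n: int, m: float) -> pd.DataFrame:
    """One labelled instance per activity with an observable break label.

    History (H) features use the same break threshold n as the label; ability
    (A) features are cumulative fastest 1/5/10 km paces up to the activity.
    """
    rows = []
    window_lengths = {lab: int(d // INTERVAL_M) for lab, d in
                      zip(A_FEATURES, (1000, 5000, 10000))}
    for h in histories:
        acts = h.activities
        if len(acts) < 2:
            continue
        ords = np.array([a.date.toordinal() for a in acts])
        kms = np.array([a.total_distance_km for a in acts])
        gaps = np.diff(ords)
        race_ord = h.race_date.toordinal()
        cum_fast = {lab: math.nan for lab in A_FEATURES}
        last_break_idx = -1
        for i, act in enumerate(acts):
            for lab, w in window_lengths.items():
                t_best = _fastest_window_time(act, w)
                if not math.isnan(t_best):
                    pace = (t_best / 60.0) / (w * INTERVAL_M / 1000.0)
                    if not pace >= cum_fast[lab]:  # NaN-safe min
                        cum_fast[lab] = pace
            has_prev = last_break_idx >= 0
            days_since = (
                float(ords[i] - ords[last_break_idx]) if has_prev else math.nan
            )
            label: bool | None
            if math.isfinite(m) and race_ord - ords[i] < m:
                label = None
            else:
                horizon = ords[i] + m
                future = np.arange(i + 1, len(acts) - 1)
                label = bool(
                    np.any((ords[future] <= horizon) & (gaps[future] > n))
                ) if future.size else False
            if label is not None:
                row = {
                    "runner_id": h.runner_id,
                    "date": act.date,
                    "sex": 1.0 if h.sex == "M" else 0.0,
                    "age": math.nan if h.age is None else h.age,
                    "days_before_race": float(race_ord - ords[i]),
                    **cum_fast,
                    "has_prev_break": float(has_prev),
                    "days_since_break": days_since,
                    "label": bool(label),
                }
                for cw in (4, 6, 8):
                    row[f"acr_1w_{cw}w"] = acr_from_arrays(
                        ords[: i + 1], kms[: i + 1], int(ords[i]), cw
                    )
                rows.append(row)
            if i < gaps.size and gaps[i] > n:
                last_break_idx = i
    df = pd.DataFrame(
        rows, columns=["runner_id", "date"] + list(ALL_FEATURES) + ["label"]
    )
    df.attrs["n"] = n
    df.attrs["m"] = m
    return df


def undersample(instances: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Balance classes by deleting negatives at random (training data only)."""
    pos = instances[instances["label"]]
    neg = instances[~instances["label"]]
    if pos.empty:
        raise ValueError("no positive instances to balance against")
    if len(neg) <= len(pos):
        return instances
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(neg), size=len(pos), replace=False)
    out = pd.concat([pos, neg.iloc[np.sort(keep)]])
    return out.sort_index()


def default_classifier_factories(seed: int = 0) -> dict:
    """Logistic regression, random forest and Gaussian naive Bayes menus."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB

    return {
        # L2 penalty (sklearn default), stopping tolerance 1e-4, strength C=1
        "LR": lambda: LogisticRegression(tol=1e-4, C=1.0, max_iter=1000),
        "RF": lambda: RandomForestClassifier(n_estimators=100, random_state=seed),
        "NB": lambda: GaussianNB(),
    }


def _impute(x_train: np.ndarray, x_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    counts = np.sum(~np.isnan(x_train), axis=0)
    means = np.where(counts > 0, np.nansum(x_train, axis=0) / np.maximum(counts, 1), 0.0)
    return (
        np.where(np.isnan(x_train), means, x_train),
        np.where(np.isnan(x_test), means, x_test),
    )


def evaluate_classifiers(
    instances: pd.DataFrame,
    classifier_factories: dict | None = None,
    n_folds: int = 10,
    seed: int = 0,
    features: tuple[str, ...] = ALL_FEATURES,
) -> pd.DataFrame:
    """Runner-grouped cross-validated precision/recall/F1 per classifier.

    Undersampling is applied to the training split only, after the fold
    split, so test folds keep their natural class imbalance.
    """
    from sklearn.metrics import f1_score, precision_score, recall_score

    if classifier_factories is None:
        classifier_factories = default_classifier_factories(seed)
    folds = runner_folds(instances["runner_id"].tolist(), n_folds, seed)
    records = []
    for fold_idx, test_runners in enumerate(folds):
        test_mask = instances["runner_id"].isin(set(test_runners))
        train = undersample(instances[~test_mask], seed=seed + fold_idx)
        test = instances[test_mask]
        if train["label"].nunique() < 2 or test.empty:
            continue
        x_train, x_test = _impute(
            train[list(features)].to_numpy(dtype=float),
            test[list(features)].to_numpy(dtype=float),
        )
        y_train = train["label"].to_numpy(dtype=bool)
        y_test = test["label"].to_numpy(dtype=bool)
        for name, factory in classifier_factories.items():
            clf = factory()
            clf.fit(x_train, y_train)
            pred = clf.predict(x_test).astype(bool)
            records.append(
                {
                    "classifier": name,
                    "fold": fold_idx,
                    "precision": precision_score(y_test, pred, zero_division=0),
                    "recall": recall_score(y_test, pred, zero_division=0),
                    "f1": f1_score(y_test, pred, zero_division=0),
                }
            )
    return pd.DataFrame(
        records, columns=["classifier", "fold", "precision", "recall", "f1"]
    )


def score_instances(model, instances: pd.DataFrame,
                    features: tuple[str, ...] = ALL_FEATURES) -> np.ndarray:
    """Positive-class probabilities (the injury-risk score)."""
    if not hasattr(model, "predict_proba"):
        raise ValueError("model must expose class probabilities")
    if len(getattr(model, "classes_", [0, 1])) < 2:
        raise ValueError("single-class model cannot produce a risk score")
    x = instances[list(features)].to_numpy(dtype=float)
    x = np.where(np.isnan(x), 0.0, x)
    return model.predict_proba(x)[:, 1]


def risk_report(
    score: float, ref_scores: np.ndarray, ref_labels: np.ndarray, bins: int = 10
) -> RiskReport:
    """Contextualise one risk score against a scored reference cohort."""
    ref_scores = np.asarray(ref_scores, dtype=float)
    ref_labels = np.asarray(ref_labels, dtype=bool)
    edges = np.quantile(ref_scores, np.linspace(0, 1, bins + 1))
    idx = min(np.searchsorted(edges, score, side="right") - 1, bins - 1)
    idx = max(idx, 0)
    in_bin = (ref_scores >= edges[idx]) & (ref_scores <= edges[idx + 1])
    incidence = float(ref_labels[in_bin].mean()) if in_bin.any() else float("nan")
    overall = float(ref_labels.mean())
    rel = incidence / overall if overall > 0 else float("nan")
    return RiskReport(float(score), incidence, rel)


def calibration(
    scores: np.ndarray, labels: np.ndarray, bins: int = 10
) -> tuple[float, float]:
    """(Pearson, Spearman) correlation of decile mean score vs incidence.

    Scores are binned into deciles; each bin's mean score is correlated with
    its break incidence.  Constant scores make the correlation undefined and
    raise.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if np.ptp(scores) == 0:
        raise ValueError("constant risk scores: calibration undefined")
    edges = np.quantile(scores, np.linspace(0, 1, bins + 1))
    edges[0] -= 1e-12
    which = np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, bins - 1)
    mean_scores, incidences = [], []
    for b in range(bins):
        mask = which == b
        if mask.any():
            mean_scores.append(scores[mask].mean())
            incidences.append(labels[mask].mean())
    if len(set(mean_scores)) < 2:
        raise ValueError("fewer than two distinct score bins")
    pearson = float(sstats.pearsonr(mean_scores, incidences)[0])
    spearman = float(sstats.spearmanr(mean_scores, incidences)[0])
    return pearson, spearman


def format_alert(report: RiskReport, n: int, style: str = "incidence") -> str:
    """Render a risk report in one of the two user-facing alert templates."""
    score = f"{report.risk_score:.1f}"
    if style == "incidence":
        pct = int(math.floor(report.cohort_incidence * 100))
        return (
            f"Alert: your current injury risk score is {score}. "
            f"At least {pct}% of runners with a similar risk score go on to "
            f"experience a training disruption of >{n} days before race-day."
        )
    if style == "relative":
        times = int(math.floor(report.relative_risk))
        return (
            f"Alert: your current injury risk score is {score}. "
            f"This means you are >{times}-times more likely to suffer from a "
            f"training disruption of >{n} days than a typical runner."
        )
    raise ValueError(f"unknown alert style {style!r}")
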