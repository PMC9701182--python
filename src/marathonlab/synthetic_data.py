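"""Synthetic runner populations, training logs, disruptions and race histories.

The single latent fitness driver is the hyperbolic speed–duration
relationship v(T) = CS + D'/T (equivalently D = D' + CS * T): every session
and race pace derives from each runner's latent critical speed CS and
capacity D'.  Maximal efforts are paced on the runner's own curve — an
initial sprint followed by a steady critical-speed stretch — so that every
prefix distance of an all-out effort is covered in the minimum achievable
time.  This makes the latent parameters exactly recoverable from noiseless
logs by the critical-speed fit, which is the identifiability property all
downstream estimators are tested against.

Training follows a periodised programme (base / strength / speed / taper)
with a weekly long run, easy sessions, tempo work and occasional maximal
time trials at 1500 m, 5 km, 10 km and ~half-marathon distance.  Training
disruptions (breaks of 8–21 days, an injury proxy) occur after an activity
with a logistic hazard in the acute:chronic workload ratio; short
non-injury gaps (4–7 days) are injected independently so that the break
labeller has realistic negatives.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .core_data import (
    MARATHON_KM,
    SEGMENT_LENGTHS_KM,
    IntervalSeries,
    RaceRecord,
    RawActivity,
    RunnerHistory,
    normalize_to_intervals,
)
from .injury_risk import acr_from_arrays

#: weeks-before-race -> maximal-effort time-trial distance (m)
TIME_TRIAL_SCHEDULE = {14: 5000, 12: 10000, 10: 1500, 8: 5000, 6: 21100, 4: 10000, 2: 1500}
#: 9-segment race slowdown template; scaled by a runner's split bias
SPLIT_TEMPLATE = np.array([-1.0, -0.9, -0.7, -0.4, 0.0, 0.4, 0.8, 1.1, 1.5])
#: marathon speed as a fraction of critical speed (recreational runners)
MARATHON_CS_FRACTION = 0.90

EASY_CS_FRACTION = 0.70
LONG_CS_FRACTION = 0.72
TEMPO_CS_FRACTION = 0.85
SPRINT_CS_FACTOR = 1.9  # peak speed at the start of an all-out effort
MAX_LONG_RUN_KM = 21.0
#: critical speed ramps up during early training and plateaus at CS_true for
#: the final PLATEAU_WEEKS weeks; the plateau keeps every late maximal effort
#: on one hyperbola, so the final cumulative fastest table is exactly CS_true's.
#: The ramp size is drawn per runner (uncorrelated with CS_true), so early-week
#: paces genuinely under-identify race-day fitness.
FITNESS_RAMP_RANGE = (0.03, 0.20)
PLATEAU_WEEKS = 9


@dataclass(frozen=True)
class RunnerProfile:
    """Latent physiology and behaviour of one synthetic runner."""

    runner_id: str
    sex: str
    age: float
    CS_true: float  # critical speed, m/s
    Dprime_true: float  # capacity above CS, metres
    weekly_volume_base: float  # km
    split_bias: float  # positive => positive-split tendency
    noise_sd: float  # multiplicative pace noise, fraction
    fitness_ramp: float = 0.10  # fraction of CS_true gained during training

    def __post_init__(self) -> None:
        if self.CS_true <= 0 or self.Dprime_true < 0 or self.noise_sd < 0:
            raise ValueError("invalid profile")


@dataclass
class SimulationConfig:
    n_runners: int = 100
    n_weeks: int = 16
    seed: int = 0
    male_fraction: float = 0.74
    noise_sd: float = 0.02
    disruption_base_rate: float = 0.02  # per-activity break probability at ACR=1
    acr_hazard_coeff: float = 2.0  # log-odds increase per unit of (ACR - 1)
    short_gap_rate: float = 0.04  # per-activity probability of a 4-7 day gap
    n_races: int = 3
    race_date: dt.date = dt.date(2023, 10, 1)
    #: base / strength / speed / taper week counts
    programme: tuple[int, int, int, int] = (5, 4, 5, 2)

    def __post_init__(self) -> None:
        if self.n_weeks < 1 or self.n_runners < 0:
            raise ValueError("n_weeks >= 1 and n_runners >= 0 required")
        for p in (
            self.male_fraction,
            self.disruption_base_rate,
            self.short_gap_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class BreakEvent:
    """Ground-truth injected training break."""

    runner_id: str
    start_date: dt.date  # date of the activity the break follows
    length_days: int


@dataclass
class SimulatedDataset:
    profiles: list[RunnerProfile]
    histories: list[RunnerHistory]
    races: list[RaceRecord]
    breaks: list[BreakEvent] = field(default_factory=list)


def _rng(config_seed: int, stage: int, index: int = 0) -> np.random.Generator:
    """Deterministic per-stage / per-runner generator fan-out."""
    return np.random.default_rng([config_seed, stage, index])


def simulate_population(config: SimulationConfig) -> list[RunnerProfile]:
    """Draw a runner population; deterministic in ``config.seed``.

    The sex split is exact (round(male_fraction * n) males).  CS is a
    truncated normal around 3.3 m/s (females shifted 0.25 m/s slower), D'
    uniform on 120–260 m, and base weekly volume increases with CS so that
    faster runners also train longer.
    """
    if config.n_runners <= 0:
        raise ValueError("n_runners must be positive")
    rng = _rng(config.seed, 0)
    n_male = int(round(config.male_fraction * config.n_runners))
    profiles = []
    for i in range(config.n_runners):
        sex = "M" if i < n_male else "F"
        cs = float(np.clip(rng.normal(3.3, 0.4), 2.5, 4.6))
        if sex == "F":
            cs = float(np.clip(cs - 0.25, 2.3, 4.4))
        dprime = float(rng.uniform(120.0, 260.0))
        volume = float(np.clip(20.0 + 18.0 * (cs - 2.5) + rng.normal(0.0, 4.0), 15.0, 80.0))
        bias_mu, bias_sd = (0.06, 0.04) if sex == "M" else (0.03, 0.02)
        bias = float(max(rng.normal(bias_mu, bias_sd), -0.05))
        age = float(np.clip(rng.normal(41.0, 9.0), 18.0, 70.0))
        profiles.append(
            RunnerProfile(
                runner_id=f"R{i:05d}",
                sex=sex,
                age=round(age, 1),
                CS_true=cs,
                Dprime_true=dprime,
                weekly_volume_base=volume,
                split_bias=bias,
                noise_sd=config.noise_sd,
                fitness_ramp=float(rng.uniform(*FITNESS_RAMP_RANGE)),
            )
        )
    return profiles


def cs_at_week(profile: RunnerProfile, weeks_before_race: int, n_weeks: int) -> float:
    """Current critical speed: linear ramp, then a plateau at CS_true.

    Fitness improves from (1 - fitness_ramp) * CS_true at programme start to
    CS_true by PLATEAU_WEEKS before race-day, and holds there.
    """
    ramp_span = n_weeks - PLATEAU_WEEKS
    if ramp_span <= 0 or weeks_before_race < PLATEAU_WEEKS:
        return profile.CS_true
    behind = min((weeks_before_race - (PLATEAU_WEEKS - 1)) / ramp_span, 1.0)
    return profile.CS_true * (1.0 - profile.fitness_ramp * behind)


def allout_time(distance_m: float, cs: float, dprime: float) -> float:
    """Minimum time (s) to cover a distance: solves d = D' + CS * T."""
    if distance_m <= dprime:
        raise ValueError("distance within the sprint capacity D'")
    return (distance_m - dprime) / cs


def _allout_activity(
    cs: float,
    dp: float,
    runner_id: str,
    activity_id: str,
    date: dt.date,
    distance_m: float,
    time_factor: float,
) -> IntervalSeries:
    """Maximal effort paced on the speed–duration curve.

    The cumulative time profile is max(d / v_sprint, (d - D') / CS) scaled by
    ``time_factor``; the kink is included as an explicit sample so the 100 m
    grid interpolation is exact.
    """
    v_sprint = SPRINT_CS_FACTOR * cs
    d_kink = dp * v_sprint / (v_sprint - cs)
    samples = [(0.0, 0.0)]
    if d_kink < distance_m:
        samples.append((d_kink, time_factor * d_kink / v_sprint))
        samples.append((distance_m, time_factor * allout_time(distance_m, cs, dp)))
    else:
        samples.append((distance_m, time_factor * distance_m / v_sprint))
    raw = RawActivity(runner_id, activity_id, date, np.array(samples))
    return normalize_to_intervals(raw)


def _steady_activity(
    runner_id: str,
    activity_id: str,
    date: dt.date,
    distance_m: float,
    speed: float,
    time_factor: float,
) -> IntervalSeries:
    samples = np.array([[0.0, 0.0], [distance_m, time_factor * distance_m / speed]])
    raw = RawActivity(runner_id, activity_id, date, samples)
    return normalize_to_intervals(raw)


def _week_multipliers(config: SimulationConfig) -> np.ndarray:
    """Per-week volume multipliers, earliest week first."""
    base, strength, speed, taper = config.programme
    mult = []
    mult += list(np.linspace(0.70, 0.95, max(base, 1)))[:base]
    mult += [1.0] * strength
    mult += list(np.linspace(1.05, 1.15, max(speed, 1)))[:speed]
    mult += list(np.linspace(0.65, 0.40, max(taper, 1)))[:taper]
    mult = mult[: config.n_weeks]
    while len(mult) < config.n_weeks:
        mult.append(1.0)
    return np.array(mult)


def simulate_training_log(
    profile: RunnerProfile, config: SimulationConfig, rng: np.random.Generator | None = None
) -> RunnerHistory:
    """Generate one runner's periodised training history (no disruptions).

    Each week holds 3–6 sessions: a fixed-slot long run (so natural gaps never
    exceed 7 days), easy runs, a tempo run in the strength/speed periods, and
    scheduled maximal time trials.  All paces derive from the profile's
    speed–duration curve with multiplicative log-time noise.
    """
    if rng is None:
        rng = _rng(config.seed, 1, int(profile.runner_id.lstrip("R") or 0))
    mults = _week_multipliers(config)
    activities: list[IntervalSeries] = []
    counter = 0
    for w in range(config.n_weeks - 1, -1, -1):  # weeks before race, oldest first
        week_pos = config.n_weeks - 1 - w
        cs = cs_at_week(profile, w, config.n_weeks)
        weekly_km = profile.weekly_volume_base * mults[week_pos]
        n_sessions = int(rng.integers(3, 7))
        period = _period_of_week(week_pos, config.programme)
        tt_distance = TIME_TRIAL_SCHEDULE.get(w) if w < config.n_weeks else None

        # day slots: long run anchored at slot 3; others drawn from the rest
        other_slots = [0, 1, 2, 4, 5, 6]
        n_other = n_sessions - 1
        slots = sorted(rng.choice(other_slots, size=n_other, replace=False).tolist())

        sessions: list[tuple[int, str, float]] = [(3, "long", 0.0)]
        remaining = slots.copy()
        if tt_distance is not None and remaining:
            tt_slot = remaining.pop(int(rng.integers(0, len(remaining))))
            sessions.append((tt_slot, "tt", float(tt_distance)))
        if period in ("strength", "speed") and remaining:
            tempo_slot = remaining.pop(int(rng.integers(0, len(remaining))))
            sessions.append((tempo_slot, "tempo", 0.0))
        for s in remaining:
            sessions.append((s, "easy", 0.0))

        long_km = min(0.35 * weekly_km, MAX_LONG_RUN_KM)
        n_easy = sum(1 for _, kind, _ in sessions if kind == "easy")
        easy_km = float(np.clip((weekly_km - long_km) / max(n_easy, 1), 3.0, 15.0))
        tempo_km = float(np.clip(0.18 * weekly_km, 4.0, 10.0))

        for slot, kind, tt_d in sorted(sessions):
            days_before = 7 * w + 7 - slot
            date = config.race_date - dt.timedelta(days=days_before)
            counter += 1
            act_id = f"{profile.runner_id}-A{counter:04d}"
            noise = float(rng.normal(0.0, profile.noise_sd))
            factor = max(1.0 + noise, 0.8)
            if kind == "tt":
                act = _allout_activity(
                    cs, profile.Dprime_true, profile.runner_id, act_id, date,
                    tt_d, factor,
                )
            else:
                km = {"long": long_km, "easy": easy_km, "tempo": tempo_km}[kind]
                frac = {
                    "long": LONG_CS_FRACTION,
                    "easy": EASY_CS_FRACTION,
                    "tempo": TEMPO_CS_FRACTION,
                }[kind]
                jitter = float(rng.uniform(-1.0, 1.0))
                # steady runs stay within the longest maximal-effort distance
                dist_m = min(max(round((km + jitter) * 10) * 100, 3000), 21000)
                act = _steady_activity(
                    profile.runner_id, act_id, date, dist_m, frac * cs, factor
                )
            activities.append(act)

    mt_noise = float(rng.normal(0.0, 0.02))
    v_marathon = MARATHON_CS_FRACTION * profile.CS_true * (1.0 + mt_noise)
    marathon_time = (MARATHON_KM * 1000.0 / v_marathon) / 60.0
    return RunnerHistory(
        runner_id=profile.runner_id,
        sex=profile.sex,
        race_date=config.race_date,
        activities=activities,
        age=profile.age,
        marathon_time=marathon_time,
    )


def _period_of_week(week_pos: int, programme: tuple[int, int, int, int]) -> str:
    base, strength, speed, taper = programme
    if week_pos < base:
        return "base"
    if week_pos < base + strength:
        return "strength"
    if week_pos < base + strength + speed:
        return "speed"
    return "taper"


def inject_disruptions(
    history: RunnerHistory,
    profile: RunnerProfile,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[RunnerHistory, list[BreakEvent]]:
    """Inject training breaks with a logistic hazard in the ACR.

    After each activity a break of 8–21 days begins with probability
    expit(logit(base_rate) + coeff * (ACR - 1)); short 4–7 day non-injury
    gaps are injected independently.  Subsequent activities are shifted
    later, and any pushed onto or past race-day are dropped.  Ground-truth
    break events are returned alongside the disrupted history.
    """
    if rng is None:
        rng = _rng(config.seed, 2, int(profile.runner_id.lstrip("R") or 0))
    acts = history.activities
    if not acts:
        return history, []
    base = config.disruption_base_rate
    coeff = config.acr_hazard_coeff
    race_ord = history.race_date.toordinal()

    kept: list[IntervalSeries] = []
    kept_ords: list[int] = []
    kept_kms: list[float] = []
    breaks: list[BreakEvent] = []
    shift = 0
    for i, act in enumerate(acts):
        ord_i = act.date.toordinal() + shift
        if ord_i >= race_ord:
            continue
        date_i = dt.date.fromordinal(ord_i)
        kept.append(replace(act, date=date_i))
        kept_ords.append(ord_i)
        kept_kms.append(act.total_distance_km)
        if i + 1 >= len(acts):
            break
        gap = acts[i + 1].date.toordinal() + shift - ord_i
        acr = acr_from_arrays(np.array(kept_ords), np.array(kept_kms), ord_i, 4)
        if base <= 0.0:
            p_break = 0.0
        elif base >= 1.0:
            p_break = 1.0
        else:
            delta = 0.0 if np.isnan(acr) else coeff * (acr - 1.0)
            p_break = float(expit(logit(base) + delta))
        if rng.random() < p_break:
            length = int(rng.integers(8, 22))
            if length > gap:
                shift += length - gap
            breaks.append(BreakEvent(history.runner_id, date_i, max(length, gap)))
        elif rng.random() < config.short_gap_rate:
            length = int(rng.integers(4, 8))
            if length > gap:
                shift += length - gap

    out = RunnerHistory(
        runner_id=history.runner_id,
        sex=history.sex,
        race_date=history.race_date,
        activities=kept,
        age=history.age,
        marathon_time=history.marathon_time,
    )
    return out, breaks


def simulate_race_history(
    profile: RunnerProfile,
    n_races: int = 3,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> list[RaceRecord]:
    """Simulate a multi-marathon race history with a PB progression.

    Finish speed is the CS-derived sustainable marathon speed with
    race-to-race noise (larger for males); segment paces follow a slowdown
    template scaled by the runner's split bias, renormalised so the
    length-weighted mean relative pace is exactly 1.
    """
    if n_races < 1:
        raise ValueError("n_races >= 1 required")
    if rng is None:
        rng = _rng(seed, 3, int(profile.runner_id.lstrip("R") or 0))
    finish_sd, bias_sd, seg_sd = (
        (0.035, 0.030, 0.012) if profile.sex == "M" else (0.020, 0.015, 0.006)
    )
    records = []
    for k in range(n_races):
        year = 2015 + k
        v = MARATHON_CS_FRACTION * profile.CS_true * (1.0 + float(rng.normal(0, finish_sd)))
        finish_min = (MARATHON_KM * 1000.0 / v) / 60.0
        bias = profile.split_bias + float(rng.normal(0.0, bias_sd))
        rel = 1.0 + bias * SPLIT_TEMPLATE + rng.normal(0.0, seg_sd, size=9)
        rel = np.clip(rel, 0.5, 2.0)
        rel = rel * MARATHON_KM / float(rel @ SEGMENT_LENGTHS_KM)
        paces = rel * (finish_min / MARATHON_KM)
        records.append(
            RaceRecord(
                runner_id=profile.runner_id,
                marathon_id=f"M{year}",
                year=year,
                sex=profile.sex,
                age_group=_age_group(profile.age),
                segment_paces=paces,
                finish_time=finish_min,
            )
        )
    return records


def _age_group(age: float) -> str:
    if age < 40:
        return "18-39"
    lo = 40 + 5 * int((age - 40) // 5)
    return f"{lo}-{lo + 4}"


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full pipeline: population -> logs -> disruptions -> race histories."""
    profiles = simulate_population(config)
    histories = []
    breaks: list[BreakEvent] = []
    races: list[RaceRecord] = []
    for idx, prof in enumerate(profiles):
        log = simulate_training_log(prof, config, _rng(config.seed, 1, idx))
        log, ev = inject_disruptions(log, prof, config, _rng(config.seed, 2, idx))
        histories.append(log)
        breaks.extend(ev)
        races.extend(
            simulate_race_history(prof, config.n_races, _rng(config.seed, 3, idx))
        )
    return SimulatedDataset(profiles, histories, races, breaks)
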