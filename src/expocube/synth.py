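"""Synthetic outlet registries, GPS cohorts and outcomes for the framework.

The generator emulates the structure the framework assumes rather than any
particular city: food outlets clustered along two road corridors with
heterogeneous day-type schedules (24-h convenience stores, daytime fast
food, short-window lunch spots, early bakeries and overnight pizzerias,
with a configurable fraction keeping different weekend hours); multi-week
1-min GPS tracks following home → work → errand anchor routines with
bounded travel speed and small positional jitter; dropout gaps of all
three imputation classes (short stationary, sub-hour moving, over an
hour); and participant covariates drawn from the demographic mix of a
small adult cohort (predominantly female, mostly 18-30, just over half
college-educated).  Overweight status is drawn from a logistic model on
the z-scored *true* exposure, enabling parameter-recovery and
model-discrimination experiments.

Every generator is a pure function of (scenario, seed); each draws from a
named sub-stream of the scenario seed so adding a generator never
perturbs the others.
"""

from __future__ import annotations

import datetime as _dt
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MINUTES_PER_DAY, StudyConfig, day_type_of
from .io import OutletRegistry

#: Covariate mix of the emulated cohort (fractions).
COHORT_MIX = {
    "female": 0.6087,
    "age_31_65": 0.4130,
    "age_65plus": 0.0218,
    "college": 0.5652,
}


@dataclass
class GapModel:
    """Per-day GPS dropout injection rates and length ranges (minutes)."""

    enabled: bool = True
    p_short: float = 0.5    # stationary dropout, endpoints < 30 m apart
    p_medium: float = 0.4   # moving dropout < 1 h, endpoints >= 30 m apart
    p_long: float = 0.25    # dropout of an hour or longer (left missing)
    short_len: tuple[int, int] = (3, 10)
    medium_len: tuple[int, int] = (10, 45)
    long_len: tuple[int, int] = (75, 180)
    #: Probability a day is cut to a 5-h window (fails the 8-h validity rule).
    invalid_day_rate: float = 0.04

    def __post_init__(self) -> None:
        for p in (self.p_short, self.p_medium, self.p_long,
                  self.invalid_day_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("gap probabilities must lie in [0, 1]")


@dataclass
class OutcomeModel:
    """Logistic coefficients generating overweight from true exposure."""

    intercept: float = -0.2
    exposure: float = 1.5
    female: float = 0.5
    age_31_65: float = 0.3
    age_65plus: float = 0.5
    college: float = -0.5


@dataclass
class SynthScenario:
    n_outlets: int = 80
    n_participants: int = 46
    n_days: int = 14
    start_date: _dt.date = _dt.date(2009, 8, 3)  # a Monday
    schedule_mix: float = 0.4
    gap_model: GapModel = field(default_factory=GapModel)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    max_speed: float = 250.0  # m/min hard cap on generated movement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 7:
            raise ValueError("n_days must be >= 7 (weekday + weekend coverage)")
        if not 0.0 <= self.schedule_mix <= 1.0:
            raise ValueError("schedule_mix must lie in [0, 1]")
        if self.start_date.weekday() != 0:
            raise ValueError("start_date must be a Monday")


def _rng(scenario: SynthScenario, stream: str) -> np.random.Generator:
    """Named sub-stream of the scenario seed."""
    key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence(entropy=scenario.seed, spawn_key=(key,))
    )


# -- outlets ---------------------------------------------------------------

#: Base weekday schedules per category, minutes of day (close < open wraps
#: overnight).  Lunch spots get per-outlet 10-min offsets so fine temporal
#: resolution genuinely matters.
_CATEGORY_SCHEDULES = {
    "fast_food": (600, 1320),      # 10:00-22:00
    "convenience": (0, 1440),      # 24 h
    "pizzeria": (960, 120),        # 16:00-02:00 overnight
    "bakery": (390, 780),          # 06:30-13:00
    "lunch_spot": (660, 840),      # 11:00-14:00
}
_CATEGORY_P = {"fast_food": 0.3, "convenience": 0.15, "pizzeria": 0.15,
               "bakery": 0.15, "lunch_spot": 0.25}


def _corridors(config: StudyConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    x0, y0, x1, y1 = config.grid_extent
    w, h = x1 - x0, y1 - y0
    return [
        (np.array([x0 + 0.05 * w, y0 + 0.40 * h]),
         np.array([x0 + 0.95 * w, y0 + 0.45 * h])),
        (np.array([x0 + 0.60 * w, y0 + 0.05 * h]),
         np.array([x0 + 0.55 * w, y0 + 0.95 * h])),
    ]


def make_outlets(scenario: SynthScenario, config: StudyConfig) -> OutletRegistry:
    """Outlets clustered along corridors with heterogeneous schedules.

    At least ``ceil(schedule_mix * n_outlets)`` outlets have Saturday hours
    that differ from their weekday hours (and Sunday hours differing
    further); with ``schedule_mix == 0`` all three day-type schedules are
    identical per outlet.
    """
    rng = _rng(scenario, "outlets")
    n = scenario.n_outlets
    corridors = _corridors(config)
    cats = rng.choice(list(_CATEGORY_P), size=n, p=list(_CATEGORY_P.values()))
    xy = np.empty((n, 2))
    for k in range(n):
        a, b = corridors[int(rng.integers(len(corridors)))]
        f = rng.uniform()
        xy[k] = a + f * (b - a) + rng.normal(0, 60.0, size=2)

    weekday_hours = []
    for k in range(n):
        o, c = _CATEGORY_SCHEDULES[cats[k]]
        if cats[k] == "lunch_spot":
            # 10-min per-outlet offset of the lunch window
            off = int(rng.integers(-3, 4)) * 10
            o, c = o + off, c + off
        weekday_hours.append((o % MINUTES_PER_DAY,
                              c if c == MINUTES_PER_DAY else c % MINUTES_PER_DAY))

    n_mixed = math.ceil(scenario.schedule_mix * n)
    mixed = np.zeros(n, dtype=bool)
    if n_mixed:
        # prefer scheduled (non-24h) outlets: a later Saturday open is only
        # distinct if the weekday schedule has an open to shift
        eligible = [k for k in range(n) if weekday_hours[k] != (0, MINUTES_PER_DAY)]
        rest = [k for k in range(n) if k not in set(eligible)]
        order = list(rng.permutation(eligible)) + list(rng.permutation(rest))
        mixed[np.array(order[:n_mixed], dtype=int)] = True

    schedules = {dt: [] for dt in ("weekday", "saturday", "sunday")}
    for k in range(n):
        wd = weekday_hours[k]
        schedules["weekday"].append(wd)
        if not mixed[k]:
            schedules["saturday"].append(wd)
            schedules["sunday"].append(wd)
            continue
        if wd == (0, MINUTES_PER_DAY):
            # a 24-h outlet with weekend hours: opens 06:00 on Saturdays
            sat = (360, MINUTES_PER_DAY)
        else:
            # open an hour later Saturdays
            so = (wd[0] + 60) % MINUTES_PER_DAY
            sat = (so, wd[1])
            if sat == wd or so == wd[1]:
                sat = (wd[0], (wd[1] - 60) % MINUTES_PER_DAY or MINUTES_PER_DAY)
        schedules["saturday"].append(sat)
        # close 40-80 min earlier on Sundays; a few close all day
        shrink = int(rng.integers(4, 9)) * 10
        sc = (sat[1] - shrink) % MINUTES_PER_DAY
        sun = None if rng.uniform() < 0.2 else (sat[0], sc)
        if sun is not None and sun[0] == sun[1]:
            sun = None
        schedules["sunday"].append(sun)

    df = pd.DataFrame(
        {
            "id": [f"O{k:04d}" for k in range(n)],
            "x": np.round(xy[:, 0], 6),
            "y": np.round(xy[:, 1], 6),
            "category": cats,
        }
    )
    return OutletRegistry(df=df, schedules=schedules)


# -- trajectories ----------------------------------------------------------


@dataclass
class _Anchors:
    home: np.ndarray
    work: np.ndarray
    errand: np.ndarray


def _draw_anchors(rng: np.random.Generator, config: StudyConfig) -> _Anchors:
    x0, y0, x1, y1 = config.grid_extent
    m = 200.0
    corridors = _corridors(config)

    def near_corridor(spread: float) -> np.ndarray:
        a, b = corridors[int(rng.integers(len(corridors)))]
        p = a + rng.uniform() * (b - a) + rng.normal(0, spread, size=2)
        return np.clip(p, [x0 + m, y0 + m], [x1 - m, y1 - m])

    home = np.array([rng.uniform(x0 + m, x1 - m), rng.uniform(y0 + m, y1 - m)])
    work = near_corridor(150.0)
    while np.hypot(*(work - home)) < 300.0:
        work = near_corridor(150.0)
    errand = near_corridor(80.0)
    while np.hypot(*(errand - home)) < 200.0:
        errand = near_corridor(80.0)
    return _Anchors(home=home, work=work, errand=errand)


def _travel(path: np.ndarray, start: np.ndarray, end: np.ndarray,
            t0: int, speed: float) -> int:
    """Fill minutes t0.. with linear movement start→end; return arrival minute."""
    dist = float(np.hypot(*(end - start)))
    dur = max(1, math.ceil(dist / speed))
    for m in range(1, dur + 1):
        t = t0 + m
        if t >= MINUTES_PER_DAY:
            return MINUTES_PER_DAY - 1
        f = m / dur
        path[t] = start + f * (end - start)
    return min(t0 + dur, MINUTES_PER_DAY - 1)


def _day_path(rng: np.random.Generator, anchors: _Anchors, day_type: str,
              max_speed: float) -> np.ndarray:
    """(1440, 2) exact positions for one day before jitter and gap removal."""
    path = np.tile(anchors.home, (MINUTES_PER_DAY, 1)).astype(float)
    speed = rng.uniform(0.5, 0.9) * max_speed
    if day_type == "weekday":
        t_leave = int(rng.integers(430, 491))          # 07:10-08:10
        t = _travel(path, anchors.home, anchors.work, t_leave, speed)
        t_work_end = int(rng.integers(1000, 1061))     # 16:40-17:40
        path[t:t_work_end + 1] = anchors.work
        t = _travel(path, anchors.work, anchors.errand, t_work_end, speed)
        dwell = int(rng.integers(20, 41))
        path[t:t + dwell + 1] = anchors.errand
        t = _travel(path, anchors.errand, anchors.home, t + dwell, speed)
        path[t:] = anchors.home
    else:
        t_leave = int(rng.integers(570, 691))          # 09:30-11:30
        t = _travel(path, anchors.home, anchors.errand, t_leave, speed)
        dwell = int(rng.integers(45, 91))
        path[t:t + dwell + 1] = anchors.errand
        t = _travel(path, anchors.errand, anchors.home, t + dwell, speed)
        path[t:] = anchors.home
        if rng.uniform() < 0.5:                        # afternoon second trip
            t2 = int(rng.integers(840, 961))
            if t2 > t:
                t3 = _travel(path, anchors.home, anchors.work, t2, speed)
                dwell2 = int(rng.integers(30, 61))
                path[t3:t3 + dwell2 + 1] = anchors.work
                t4 = _travel(path, anchors.work, anchors.home, t3 + dwell2, speed)
                path[t4:] = anchors.home
    return path


def _inject_gaps(rng: np.random.Generator, keep: np.ndarray,
                 gm: GapModel, t_leave: int) -> None:
    """Mark minutes False per the three dropout classes (in place)."""
    if rng.uniform() < gm.p_short:
        ln = int(rng.integers(gm.short_len[0], gm.short_len[1] + 1))
        s = int(rng.integers(60, 300))                 # home, stationary
        keep[s + 1 : s + ln] = False
    if rng.uniform() < gm.p_medium:
        ln = int(rng.integers(gm.medium_len[0], gm.medium_len[1] + 1))
        s = t_leave + 1                                # spans the commute
        keep[s + 1 : s + ln] = False
    if rng.uniform() < gm.p_long:
        ln = int(rng.integers(gm.long_len[0], gm.long_len[1] + 1))
        s = int(rng.integers(1140, 1261))              # evening at home
        keep[s + 1 : min(s + ln, MINUTES_PER_DAY - 1)] = False


def make_trajectories(scenario: SynthScenario, config: StudyConfig
                      ) -> dict[str, pd.DataFrame]:
    """Raw per-participant GPS frames (participant_id keys).

    Without gaps each participant has exactly ``1440 * n_days`` records;
    with the gap model enabled, records are removed per the three dropout
    classes and the occasional short (invalid) day.  Movement speed never
    exceeds ``scenario.max_speed``.
    """
    out: dict[str, pd.DataFrame] = {}
    gm = scenario.gap_model
    for p in range(scenario.n_participants):
        pid = f"P{p:03d}"
        rng = _rng(scenario, f"trajectory:{pid}")
        anchors = _draw_anchors(rng, config)
        frames = []
        for d in range(scenario.n_days):
            date = scenario.start_date + _dt.timedelta(days=d)
            path = _day_path(rng, anchors, day_type_of(date), scenario.max_speed)
            # sub-cap jitter: stationary fixes wander ~1 m, moving ~2 m
            moving = np.zeros(MINUTES_PER_DAY, dtype=bool)
            moving[1:] = np.hypot(*(path[1:] - path[:-1]).T) > 0.5
            sigma = np.where(moving, 2.0, 1.0)[:, None]
            path = path + rng.normal(0, 1.0, size=path.shape) * sigma

            keep = np.ones(MINUTES_PER_DAY, dtype=bool)
            if gm.enabled:
                if rng.uniform() < gm.invalid_day_rate:
                    keep[:] = False
                    keep[540:840] = True               # 09:00-14:00 only
                else:
                    t_leave = int(np.flatnonzero(moving)[0]) - 1 if moving.any() else 480
                    _inject_gaps(rng, keep, gm, t_leave)
            minutes = np.flatnonzero(keep)
            ts = pd.Timestamp(date) + pd.to_timedelta(minutes, unit="min")
            frames.append(
                pd.DataFrame(
                    {"timestamp": ts, "x": path[minutes, 0], "y": path[minutes, 1]}
                )
            )
        df = pd.concat(frames, ignore_index=True)
        df["day_type"] = [day_type_of(t.date()) for t in df["timestamp"]]
        out[pid] = df
    return out


# -- covariates and outcomes ----------------------------------------------


def make_covariates(scenario: SynthScenario) -> pd.DataFrame:
    """Participant covariates drawn from the emulated cohort mix."""
    rng = _rng(scenario, "covariates")
    n = scenario.n_participants
    gender = np.where(rng.uniform(size=n) < COHORT_MIX["female"],
                      "female", "male")
    u = rng.uniform(size=n)
    age = np.where(
        u < COHORT_MIX["age_65plus"], "65+",
        np.where(u < COHORT_MIX["age_65plus"] + COHORT_MIX["age_31_65"],
                 "31-65", "18-30"),
    )
    edu = np.where(rng.uniform(size=n) < COHORT_MIX["college"],
                   "college", "lt_college")
    return pd.DataFrame(
        {
            "participant_id": [f"P{p:03d}" for p in range(n)],
            "gender": gender,
            "age_group": age,
            "education": edu,
        }
    )


def make_outcomes(scenario: SynthScenario, true_exposure: pd.Series,
                  covariates: pd.DataFrame | None = None,
                  outcome_seed: int | None = None) -> pd.DataFrame:
    """Covariate table with an overweight flag drawn from true exposure.

    ``true_exposure`` is indexed by participant_id; it is z-scored
    internally before entering the linear predictor.  ``outcome_seed``
    varies the Bernoulli draw (and only it) across replicates of the same
    scenario.
    """
    if covariates is None:
        covariates = make_covariates(scenario)
    cov = covariates.set_index("participant_id")
    exp_z = (true_exposure - true_exposure.mean())
    sd = true_exposure.std(ddof=1)
    exp_z = exp_z / sd if sd > 0 else exp_z * 0.0
    exp_z = exp_z.loc[cov.index]

    om = scenario.outcome_model
    eta = (
        om.intercept
        + om.exposure * exp_z.to_numpy()
        + om.female * (cov["gender"] == "female").to_numpy()
        + om.age_31_65 * (cov["age_group"] == "31-65").to_numpy()
        + om.age_65plus * (cov["age_group"] == "65+").to_numpy()
        + om.college * (cov["education"] == "college").to_numpy()
    )
    prob = 1.0 / (1.0 + np.exp(-eta))
    stream = "outcomes" if outcome_seed is None else f"outcomes:{outcome_seed}"
    rng = _rng(scenario, stream)
    overweight = (rng.uniform(size=len(prob)) < prob).astype(int)
    out = cov.reset_index()
    out["overweight"] = overweight
    return out
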