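"""GPS trajectory cleaning: gap imputation, valid-day and participant screening.

The cleaning rules follow the standard minute-epoch GPS protocol for
free-living tracking studies:

* a dropout whose bounding fixes are **< 30 m** apart is filled at the
  earlier fix's location (the subject is taken to be stationary);
* a dropout of **< 1 h** with endpoints 30 m or more apart is filled by
  linear interpolation at 1-min steps between the bounding fixes;
* a dropout of **an hour or longer** is left missing.

A survey day is *valid* when it carries at least eight hours (480 min) of
recorded-or-imputed minutes, and a participant is retained when they have
at least five valid weekdays and two valid weekend days.

Boundary conventions are strict: exactly 30 m falls into the interpolation
branch, exactly 60 min into the not-imputed branch.  The one-hour cap is
global — a dropout of an hour or longer stays missing even when its
endpoints are nearly coincident — so overnight device-off periods at home
are never back-filled.  Imputed minutes count toward the 8-h validity rule
(they are valid records by construction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import day_type_of

STATIONARY_FILL_MAX_M = 30.0
INTERPOLATE_MAX_MIN = 60.0
VALID_DAY_MIN_MINUTES = 480
MIN_VALID_WEEKDAYS = 5
MIN_VALID_WEEKEND_DAYS = 2


@dataclass
class Trajectory:
    """A cleaned per-participant sequence of timestamped positions.

    ``records`` columns: timestamp (datetime64, strictly increasing), x, y
    (meters), imputed (bool), velocity (m/min; planar distance to the
    previous record over elapsed minutes, 0 for the first record).
    ``missing_intervals`` lists (start, end) timestamp pairs of unimputed
    gaps (> 1 h); ``day_summaries`` (after :func:`flag_valid_days`) has one
    row per local date: date, day_type, valid_minutes, is_valid_day.
    """

    participant_id: str
    records: pd.DataFrame
    missing_intervals: list = field(default_factory=list)
    day_summaries: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ts = self.records["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("trajectory timestamps must be sorted")

    @classmethod
    def from_raw(cls, participant_id: str, raw: pd.DataFrame) -> "Trajectory":
        rec = raw[["timestamp", "x", "y"]].copy().reset_index(drop=True)
        rec["imputed"] = False
        traj = cls(participant_id=participant_id, records=rec)
        traj._recompute_velocity()
        return traj

    def _recompute_velocity(self) -> None:
        r = self.records
        dx = r["x"].diff().to_numpy()
        dy = r["y"].diff().to_numpy()
        dt_min = r["timestamp"].diff().dt.total_seconds().to_numpy() / 60.0
        v = np.hypot(dx, dy) / dt_min
        v[0] = 0.0
        self.records["velocity"] = v

    def valid_dates(self, day_type: str | None = None) -> list:
        """Local dates flagged valid, optionally restricted to a day type."""
        if self.day_summaries is None:
            raise ValueError("flag_valid_days has not been run")
        ds = self.day_summaries
        mask = ds["is_valid_day"]
        if day_type is not None:
            mask = mask & (ds["day_type"] == day_type)
        return list(ds.loc[mask, "date"])


def impute_gaps(traj: Trajectory) -> Trajectory:
    """Fill GPS dropouts per the 30 m / 1 h rules; flag all fills as imputed.

    Original records are never altered, only 1-min interim records inserted.
    Idempotent: re-running on a filled trajectory changes nothing (filled
    gaps have no remaining > 1-min steps except unimputed > 1 h holes,
    which stay excluded by the duration rule).
    """
    r = traj.records.reset_index(drop=True)
    ts = r["timestamp"].to_numpy()
    xs = r["x"].to_numpy(dtype=float)
    ys = r["y"].to_numpy(dtype=float)

    pieces = [r]
    missing: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    one_min = pd.Timedelta(minutes=1)
    gap_minutes = (ts[1:] - ts[:-1]) / np.timedelta64(60, "s")
    for k in np.flatnonzero(gap_minutes > 1.0):
        gap_min = gap_minutes[k]
        if gap_min >= INTERPOLATE_MAX_MIN:
            # an hour or longer: considered missing, never imputed
            missing.append((pd.Timestamp(ts[k]), pd.Timestamp(ts[k + 1])))
            continue
        dist = math.hypot(xs[k + 1] - xs[k], ys[k + 1] - ys[k])
        fill_times = pd.date_range(
            pd.Timestamp(ts[k]) + one_min, pd.Timestamp(ts[k + 1]) - one_min,
            freq="min",
        )
        # drop any fill landing exactly on the later fix (non-integer gaps)
        fill_times = fill_times[fill_times < pd.Timestamp(ts[k + 1])]
        if dist < STATIONARY_FILL_MAX_M:
            fx = np.full(len(fill_times), xs[k])
            fy = np.full(len(fill_times), ys[k])
        else:
            f = (
                (fill_times - pd.Timestamp(ts[k])).total_seconds().to_numpy()
                / ((ts[k + 1] - ts[k]) / np.timedelta64(1, "s"))
            )
            fx = xs[k] + f * (xs[k + 1] - xs[k])
            fy = ys[k] + f * (ys[k + 1] - ys[k])
        if len(fill_times):
            pieces.append(
                pd.DataFrame(
                    {"timestamp": fill_times, "x": fx, "y": fy, "imputed": True}
                )
            )
    out = pd.concat(pieces, ignore_index=True).sort_values("timestamp")
    out = out.reset_index(drop=True)
    new = Trajectory(
        participant_id=traj.participant_id,
        records=out,
        missing_intervals=missing,
    )
    new._recompute_velocity()
    return new


def flag_valid_days(traj: Trajectory) -> Trajectory:
    """Mark each local date valid iff it has >= 480 recorded-or-imputed minutes."""
    r = traj.records
    dates = r["timestamp"].dt.date
    counts = r.groupby(dates, sort=True).size()
    summaries = pd.DataFrame(
        {
            "date": counts.index,
            "day_type": [day_type_of(d) for d in counts.index],
            "valid_minutes": counts.to_numpy(),
        }
    ).reset_index(drop=True)
    summaries["is_valid_day"] = summaries["valid_minutes"] >= VALID_DAY_MIN_MINUTES
    traj.day_summaries = summaries
    return traj


def select_participants(trajs: dict[str, Trajectory]) -> dict[str, Trajectory]:
    """Keep participants with >= 5 valid weekdays and >= 2 valid weekend days."""
    kept: dict[str, Trajectory] = {}
    dropped: list[str] = []
    for pid, traj in trajs.items():
        if traj.day_summaries is None:
            raise ValueError(f"participant {pid}: flag_valid_days not run")
        ds = traj.day_summaries
        valid = ds[ds["is_valid_day"]]
        n_weekday = int((valid["day_type"] == "weekday").sum())
        n_weekend = int(valid["day_type"].isin(["saturday", "sunday"]).sum())
        if n_weekday >= MIN_VALID_WEEKDAYS and n_weekend >= MIN_VALID_WEEKEND_DAYS:
            kept[pid] = traj
        else:
            dropped.append(pid)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} participant(s) failing the "
            f"{MIN_VALID_WEEKDAYS}-weekday/{MIN_VALID_WEEKEND_DAYS}-weekend-day "
            f"rule; kept {len(kept)}"
        )
    if not kept:
        raise RuntimeError(
            "no participant passes the valid-day filters; collect more days "
            "or relax the synthetic scenario"
        )
    return kept


def preprocess_all(raw: dict[str, pd.DataFrame]) -> dict[str, Trajectory]:
    """Raw per-participant frames → imputed, day-flagged, filtered trajectories."""
    trajs = {
        pid: flag_valid_days(impute_gaps(Trajectory.from_raw(pid, df)))
        for pid, df in raw.items()
    }
    return select_participants(trajs)


def minute_positions(traj: Trajectory, date) -> np.ndarray:
    """(1440, 3) array of [x, y, velocity] per minute of one local date.

    NaN rows mark minutes without a recorded or imputed position (unimputed
    gaps, and time before the first / after the last fix of the date).
    """
    r = traj.records
    mask = r["timestamp"].dt.date == date
    out = np.full((1440, 3), np.nan)
    sub = r[mask]
    minutes = (
        sub["timestamp"].dt.hour * 60 + sub["timestamp"].dt.minute
    ).to_numpy()
    out[minutes, 0] = sub["x"].to_numpy()
    out[minutes, 1] = sub["y"].to_numpy()
    out[minutes, 2] = sub["velocity"].to_numpy()
    return out
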