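"""Individual space-time tunnels, 3-D intersection and the exposure index.

The tunnel (ISTT) is the region swept through the space-time cube by a
horizontal disc of radius ``br`` (meters) that follows the participant's
trajectory: at every instant with a recorded or imputed position the
tunnel covers the disc centred on the (time-interpolated) position;
instants inside unimputed > 1 h gaps are not covered.  There is no
buffering along the time axis — a metric ball mixing meters and minutes
would be dimensionally undefined.

Exposure is the environmental context exposure index (ECEI): cube
point-cloud points falling inside the tunnel contribute their voxel value
times a weight, and the weighted sum is divided by observation time, so
the index is an exposure rate per observed hour,

    ECEI = sum_i EC_i * W_i / T.

Weights are 1 everywhere in ``constant`` mode; in ``velocity`` mode a
point passed at velocity v (m/min) weighs (1/2)^v — contextual influence
halves for every additional meter-per-minute of speed, and a stationary
subject (v = 0) carries full weight 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DAY_TYPES
from .cube import ContextCube, CubePointCloud
from .preprocess import Trajectory, minute_positions


@dataclass
class SpaceTimeTunnel:
    """Buffered trajectory restricted to valid days of one day type.

    ``day_positions`` maps each valid local date to a (1440, 3) array of
    [x, y, velocity] per minute (NaN where no position exists).
    """

    participant_id: str
    day_type: str
    br: float
    day_positions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.br <= 0:
            raise ValueError("br must be positive")

    @property
    def n_days(self) -> int:
        return len(self.day_positions)

    def observed_minutes(self) -> int:
        """Total minutes with a position across the tunnel's days."""
        return int(
            sum(np.isfinite(pos[:, 0]).sum() for pos in self.day_positions.values())
        )

    def position_at(self, date, t: float) -> np.ndarray | None:
        """[x, y, velocity] at minute-of-day t on one date, or None.

        Positions between the 1-min fixes are linearly interpolated; the
        velocity is that of the trajectory segment containing t.  Both
        bracketing fixes must exist (a missing flank means the instant
        falls in an uncovered hole).
        """
        pos = self.day_positions[date]
        lo = int(np.floor(t))
        if lo < 0 or lo > 1439:
            return None
        if t == lo or lo == 1439:
            p = pos[lo]
            return None if not np.isfinite(p[0]) else p
        p0, p1 = pos[lo], pos[lo + 1]
        if not (np.isfinite(p0[0]) and np.isfinite(p1[0])):
            return None
        f = t - lo
        return np.array(
            [p0[0] + f * (p1[0] - p0[0]), p0[1] + f * (p1[1] - p0[1]), p1[2]]
        )


def build_tunnel(traj: Trajectory, day_type: str, br: float) -> SpaceTimeTunnel:
    """Tunnel over all valid days of ``day_type`` in a cleaned trajectory."""
    dates = traj.valid_dates(day_type)
    if not dates:
        warnings.warn(
            f"participant {traj.participant_id}: no valid {day_type} days; "
            "empty tunnel"
        )
    return SpaceTimeTunnel(
        participant_id=traj.participant_id,
        day_type=day_type,
        br=br,
        day_positions={d: minute_positions(traj, d) for d in dates},
    )


def point_weight(velocity, mode: str = "constant"):
    """Eq.-style point weight: 1 in constant mode; (1/2)^v in velocity mode."""
    v = np.asarray(velocity, dtype=float)
    if np.any(v < 0):
        raise ValueError("velocity must be non-negative")
    if mode == "constant":
        w = np.ones_like(v)
    elif mode == "velocity":
        w = np.where(v == 0, 1.0, 0.5**v)
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    return w if w.shape else float(w)


def intersect(tunnel: SpaceTimeTunnel, cloud: CubePointCloud,
              weight_mode: str = "constant") -> pd.DataFrame:
    """All cloud points inside the tunnel, one row per (point, day) hit.

    A cloud point (x, y, t) is intersected on a given valid day iff the
    participant has a position at minute t that day and its planar distance
    to (x, y) is at most br.  A voxel revisited on several days of the
    same day type is counted once per day (repeated exposure accumulates).
    Columns: x, y, t, value, velocity, weight, date.
    """
    pts = cloud.points
    hits = []
    br2 = tunnel.br**2
    for date in tunnel.day_positions:
        for t, grp in pts.groupby("t", sort=True):
            p = tunnel.position_at(date, float(t))
            if p is None:
                continue
            d2 = (grp["x"].to_numpy() - p[0]) ** 2 + (grp["y"].to_numpy() - p[1]) ** 2
            sel = grp[d2 <= br2]
            if len(sel):
                sub = sel[["x", "y", "t", "value"]].copy()
                sub["velocity"] = p[2]
                sub["date"] = date
                hits.append(sub)
    if not hits:
        return pd.DataFrame(
            columns=["x", "y", "t", "value", "velocity", "weight", "date"]
        )
    out = pd.concat(hits, ignore_index=True)
    out["weight"] = point_weight(out["velocity"].to_numpy(), weight_mode)
    return out[["x", "y", "t", "value", "velocity", "weight", "date"]]


def ecei(points: pd.DataFrame, T: float) -> float:
    """Exposure index: weighted sum of intersected values per hour observed."""
    if T <= 0:
        raise ValueError("T must be positive")
    if len(points) == 0:
        return 0.0
    return float((points["value"] * points["weight"]).sum() / T)


def _slot_positions(pos: np.ndarray, t_mid: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated [x, y, velocity] at each slot midpoint of one day.

    ``pos`` is the (1440, 3) per-minute array; returns (P, valid) with P of
    shape (n_slots, 3).  Midpoints on a fix use that fix; midpoints between
    fixes require both flanking fixes (else the instant is uncovered) and
    carry the velocity of the segment containing them.
    """
    lo = np.floor(t_mid).astype(int)
    lo = np.clip(lo, 0, 1439)
    f = t_mid - lo
    on_fix = (f == 0) | (lo >= 1439)
    hi = np.minimum(lo + 1, 1439)
    p0, p1 = pos[lo], pos[hi]
    both = np.isfinite(p0[:, 0]) & np.isfinite(p1[:, 0])
    valid = np.where(on_fix, np.isfinite(p0[:, 0]), both)
    fcol = f[:, None]
    interp = np.empty_like(p0)
    interp[:, :2] = p0[:, :2] + fcol * (p1[:, :2] - p0[:, :2])
    interp[:, 2] = p1[:, 2]
    P = np.where(on_fix[:, None], p0, interp)
    return P, valid


def _ecei_for_cube(tunnel: SpaceTimeTunnel, cube: ContextCube,
                   weight_mode: str, t_mode: str) -> tuple[float, int, float]:
    """Vectorized ECEI of one tunnel against one cube.

    Equivalent to ``ecei(intersect(tunnel, to_point_cloud(cube)), T)`` but
    sums over cube layers without materialising the cloud.  Returns
    (ecei_raw, n_points, T_hours).
    """
    cx, cy = cube.grid_spec.centroids()
    vals = cube.values()
    slot = cube.slot_minutes
    t_mid = cube.t_axis + slot / 2
    br2 = tunnel.br**2

    total = 0.0
    n_points = 0
    span_minutes = 0.0
    for pos in tunnel.day_positions.values():
        P, valid = _slot_positions(pos, t_mid)
        if not valid.any():
            continue
        d2 = (cx[None] - P[:, 0][:, None, None]) ** 2 \
            + (cy[None] - P[:, 1][:, None, None]) ** 2
        mask = (d2 <= br2) & valid[:, None, None]
        hits_per_slot = mask.sum(axis=(1, 2))
        w = point_weight(np.where(valid, P[:, 2], 0.0), weight_mode)
        total += float((w * (vals * mask).sum(axis=(1, 2))).sum())
        n_points += int(hits_per_slot.sum())
        hit = hits_per_slot > 0
        if hit.any():
            span_minutes += float(t_mid[hit].max() - t_mid[hit].min() + slot)
    if t_mode == "observed":
        T_hours = tunnel.observed_minutes() / 60.0
    elif t_mode == "span":
        T_hours = span_minutes / 60.0
    else:
        raise ValueError(f"unknown t_mode {t_mode!r}")
    if T_hours <= 0:
        return 0.0, 0, 0.0
    return total / T_hours, n_points, T_hours


def participant_ecei(traj: Trajectory, cubes_by_day_type: dict[str, ContextCube],
                     br: float, weight_mode: str = "constant",
                     t_mode: str = "observed",
                     _tunnels: dict[str, SpaceTimeTunnel] | None = None) -> dict:
    """One participant's ECEI for one method key, aggregated across day types.

    Each day type's cube is intersected with the tunnel over that day
    type's valid days; the per-day-type indices are combined as a
    valid-day-weighted mean, yielding one exposure per participant per
    method.  ``t_mode`` selects the observation-time denominator:
    ``observed`` (total valid observation hours, the default) or ``span``
    (temporal span of the intersected points per day).
    """
    per_dt: dict[str, tuple[float, int, float]] = {}
    day_counts: dict[str, int] = {}
    for day_type in DAY_TYPES:
        if day_type not in cubes_by_day_type:
            continue
        dates = traj.valid_dates(day_type)
        day_counts[day_type] = len(dates)
        if not dates:
            per_dt[day_type] = (0.0, 0, 0.0)
            continue
        if _tunnels is not None and day_type in _tunnels:
            tunnel = _tunnels[day_type]
        else:
            tunnel = build_tunnel(traj, day_type, br)
        per_dt[day_type] = _ecei_for_cube(
            tunnel, cubes_by_day_type[day_type], weight_mode, t_mode
        )
    n_total = sum(day_counts.values())
    raw = (
        sum(day_counts[dt] * per_dt[dt][0] for dt in per_dt) / n_total
        if n_total else 0.0
    )
    return {
        "participant_id": traj.participant_id,
        "ecei_raw": raw,
        "n_points": int(sum(per_dt[dt][1] for dt in per_dt)),
        "T_hours": float(sum(per_dt[dt][2] for dt in per_dt)),
    }


def standardize(records: pd.DataFrame, value_col: str = "ecei_raw",
                z_col: str = "ecei_z", by: str | None = "method_key"
                ) -> pd.DataFrame:
    """z-score a column across participants (sample sd, n-1), per method key.

    A zero-variance (or singleton) group gets z = 0 with a warning.
    """
    out = records.copy()

    def _z(x: pd.Series) -> pd.Series:
        if len(x) < 2 or x.std(ddof=1) == 0:
            warnings.warn("degenerate exposure distribution; z set to 0")
            return pd.Series(np.zeros(len(x)), index=x.index)
        return (x - x.mean()) / x.std(ddof=1)

    if by is None:
        out[z_col] = _z(out[value_col])
    else:
        out[z_col] = out.groupby(by, group_keys=False)[value_col].apply(_z)
    return out


def compute_exposures(trajs: dict[str, Trajectory],
                      cubes: dict[tuple, ContextCube],
                      br: float, weight_mode: str = "constant",
                      t_mode: str = "observed") -> pd.DataFrame:
    """ECEI table for every participant x (method, cell_size, slot) key.

    ``cubes`` is the :func:`expocube.cube.enumerate_cubes` mapping.  The
    result is tidy: participant_id, method_key, ecei_raw, ecei_z, n_points,
    T_hours.
    """
    method_keys: dict[str, dict[str, ContextCube]] = {}
    for (method, cell_size, slot, day_type), cube in cubes.items():
        key = cube.key
        method_keys.setdefault(key, {})[day_type] = cube

    # tunnels depend only on (participant, day type): build once, reuse
    tunnels: dict[str, dict[str, SpaceTimeTunnel]] = {}
    for pid, traj in trajs.items():
        tunnels[pid] = {
            dt: build_tunnel(traj, dt, br)
            for dt in DAY_TYPES if traj.valid_dates(dt)
        }

    rows = []
    for key, by_dt in sorted(method_keys.items()):
        for pid, traj in trajs.items():
            rec = participant_ecei(traj, by_dt, br, weight_mode, t_mode,
                                   _tunnels=tunnels[pid])
            rec["method_key"] = key
            rows.append(rec)
    table = pd.DataFrame(rows)[
        ["participant_id", "method_key", "ecei_raw", "n_points", "T_hours"]
    ]
    return standardize(table)
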