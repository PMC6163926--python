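"""Static activity-space exposure measures: trajectory buffer, hull, ellipses.

These are the four conventional 2-D delineations the dynamic framework is
contrasted against: a 100-m buffer along the GPS polyline (GTB), the
minimum convex polygon of all GPS points (MCP) and the 1- and
2-standard-deviation deviational ellipses (SDE1, SDE2).  Exposure is the
density of *all* registered outlets inside the polygon — business hours
are deliberately ignored, which is exactly the temporal blindness of
static activity-space measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .io import OutletRegistry
from .preprocess import Trajectory

KINDS = ("GTB", "MCP", "SDE1", "SDE2")

#: Vertices used to polygonise an ellipse or point buffer.
ELLIPSE_VERTICES = 256

#: Quadrant segments for shapely buffers: 64 segments per full circle keeps
#: the polygonization area error below 0.2%.
_BUFFER_QUAD_SEGS = 16


@dataclass
class ExposureSpace:
    participant_id: str
    kind: str
    polygon: Polygon
    area: float  # m^2

    def __post_init__(self) -> None:
        if self.polygon.is_empty or self.area <= 0:
            raise ValueError(f"{self.kind}: empty or zero-area exposure space")


def _valid_points(traj: Trajectory) -> np.ndarray:
    """GPS fixes (recorded + imputed) on valid days, as an (n, 2) array."""
    dates = set(traj.valid_dates())
    r = traj.records
    mask = r["timestamp"].dt.date.map(lambda d: d in dates)
    return r.loc[mask, ["x", "y"]].to_numpy(dtype=float)


def _polyline_runs(traj: Trajectory) -> list[np.ndarray]:
    """Valid-day point runs, split wherever an unimputed > 1 h gap occurs."""
    dates = set(traj.valid_dates())
    r = traj.records
    mask = r["timestamp"].dt.date.map(lambda d: d in dates).to_numpy()
    ts = r["timestamp"].to_numpy()
    gap_breaks = np.zeros(len(r), dtype=bool)
    gap_breaks[1:] = (ts[1:] - ts[:-1]) / np.timedelta64(60, "s") > 1.0
    runs: list[np.ndarray] = []
    current: list[int] = []
    for k in range(len(r)):
        if not mask[k] or (gap_breaks[k] and current):
            if len(current) >= 1:
                runs.append(r.iloc[current][["x", "y"]].to_numpy(dtype=float))
            current = [k] if mask[k] else []
        else:
            current.append(k)
    if current:
        runs.append(r.iloc[current][["x", "y"]].to_numpy(dtype=float))
    return runs


def gtb(traj: Trajectory, radius: float = 100.0) -> ExposureSpace:
    """GPS trajectory buffer: the polyline buffered by ``radius`` meters.

    Unimputed > 1 h gaps break the polyline; each run is buffered
    separately and the union taken, so the buffer never bridges an
    uncovered hole.
    """
    runs = _polyline_runs(traj)
    n_pts = sum(len(run) for run in runs)
    if n_pts < 2:
        raise ValueError("GTB requires at least two GPS points")
    geoms = []
    for run in runs:
        if len(run) == 1:
            geoms.append(Point(run[0]).buffer(radius, quad_segs=_BUFFER_QUAD_SEGS))
        else:
            # Douglas-Peucker at radius/20 bounds the polyline deviation to
            # 5% of the buffer radius; it collapses stationary GPS jitter
            # clouds while leaving exact geometric fixtures untouched
            line = LineString(run).simplify(radius / 20.0, preserve_topology=False)
            geoms.append(line.buffer(radius, quad_segs=_BUFFER_QUAD_SEGS))
    poly = unary_union(geoms)
    return ExposureSpace(traj.participant_id, "GTB", poly, poly.area)


def mcp(traj: Trajectory) -> ExposureSpace:
    """Minimum convex polygon: the convex hull of all valid-day GPS points."""
    pts = _valid_points(traj)
    if len(pts) < 3:
        raise ValueError("MCP requires at least three GPS points")
    hull = MultiPoint([tuple(p) for p in np.unique(pts, axis=0)]).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("MCP is degenerate: GPS points are collinear")
    return ExposureSpace(traj.participant_id, "MCP", hull, hull.area)


def sde_parameters(points: np.ndarray) -> tuple[float, float, float, float, float]:
    """Standard deviational ellipse parameters (Yuill convention).

    Returns (cx, cy, theta, sigma_major, sigma_minor).  ``theta`` is the
    rotation of the major axis measured counterclockwise from east (the
    +x axis), in radians, modulo pi.  With centred deviations x', y':

        tan(2*theta) = 2*Sxy / (Sxx - Syy)

    resolved to the orientation maximising the projected variance, and the
    axis standard deviations are the sample (n-1) standard deviations of
    the coordinates projected on the rotated axes.
    """
    n = len(points)
    cx, cy = points.mean(axis=0)
    xd = points[:, 0] - cx
    yd = points[:, 1] - cy
    sxx = float((xd * xd).sum())
    syy = float((yd * yd).sum())
    sxy = float((xd * yd).sum())
    if sxx == 0 and syy == 0:
        raise ValueError("SDE is degenerate: zero scatter")
    # principal-axis solution of tan(2*theta) = 2*Sxy / (Sxx - Syy); atan2
    # resolves the +-pi/2 ambiguity toward the variance-maximising axis
    theta = 0.5 * math.atan2(2 * sxy, sxx - syy)
    ct, st = math.cos(theta), math.sin(theta)
    proj_major = xd * ct + yd * st
    proj_minor = -xd * st + yd * ct
    s_major = float(np.sqrt((proj_major**2).sum() / (n - 1)))
    s_minor = float(np.sqrt((proj_minor**2).sum() / (n - 1)))
    if s_major < s_minor:  # ensure the major axis carries the larger spread
        theta = (theta + math.pi / 2) % math.pi
        s_major, s_minor = s_minor, s_major
    if s_minor == 0:
        raise ValueError("SDE is degenerate: zero variance along an axis")
    return float(cx), float(cy), theta % math.pi, s_major, s_minor


def sde(traj: Trajectory, k_sd: int = 1) -> ExposureSpace:
    """Standard deviational ellipse of valid-day GPS points (1 or 2 sigma)."""
    if k_sd not in (1, 2):
        raise ValueError("k_sd must be 1 or 2")
    pts = _valid_points(traj)
    if len(pts) < 3:
        raise ValueError("SDE requires at least three GPS points")
    cx, cy, theta, s_major, s_minor = sde_parameters(pts)
    a, b = k_sd * s_major, k_sd * s_minor
    phi = np.linspace(0, 2 * math.pi, ELLIPSE_VERTICES, endpoint=False)
    ex = cx + a * np.cos(phi) * math.cos(theta) - b * np.sin(phi) * math.sin(theta)
    ey = cy + a * np.cos(phi) * math.sin(theta) + b * np.sin(phi) * math.cos(theta)
    poly = Polygon(np.column_stack([ex, ey]))
    return ExposureSpace(traj.participant_id, f"SDE{k_sd}", poly, poly.area)


def outlet_density(space: ExposureSpace, registry: OutletRegistry) -> float:
    """Outlets inside-or-on the polygon per km^2, ignoring business hours."""
    if space.area <= 0:
        raise ValueError("exposure space has zero area")
    pts = registry.coords()
    count = sum(
        1 for p in pts if space.polygon.covers(Point(p[0], p[1]))
    )
    return count / (space.area / 1e6)


def compute_activity_space_exposures(trajs: dict[str, Trajectory],
                                     registry: OutletRegistry,
                                     gtb_radius: float = 100.0) -> pd.DataFrame:
    """Outlet-density exposure per participant for all four static measures.

    Tidy output mirroring the ECEI table: participant_id, method_key
    (M-GTB, M-MCP, M-SDE1, M-SDE2), ecei_raw (the density), ecei_z.
    """
    from .tunnel import standardize

    rows = []
    for pid, traj in trajs.items():
        spaces = {
            "M-GTB": gtb(traj, gtb_radius),
            "M-MCP": mcp(traj),
            "M-SDE1": sde(traj, 1),
            "M-SDE2": sde(traj, 2),
        }
        for key, space in spaces.items():
            rows.append(
                {
                    "participant_id": pid,
                    "method_key": key,
                    "ecei_raw": outlet_density(space, registry),
                    "n_points": np.nan,
                    "T_hours": np.nan,
                }
            )
    return standardize(pd.DataFrame(rows))
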