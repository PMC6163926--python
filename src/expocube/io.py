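"""Readers and writers for outlet registries, GPS tracks, raster layers and results.

Formats are deliberately plain text: outlets as CSV or GeoJSON, GPS as CSV
or GPX, raster layers as ESRI ASCII grid (.asc) with a JSON sidecar, point
clouds and result tables as CSV.  Parsing is locale-independent (decimal
points, timezone-naive local timestamps).
"""

from __future__ import annotations

import datetime as _dt
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    DAY_TYPES,
    DAY_TYPE_SUCCESSORS,
    MINUTES_PER_DAY,
    GridSpec,
    StudyConfig,
    day_type_of,
)

SCHEDULE_COLUMNS = [
    f"{dt}_{side}" for dt in DAY_TYPES for side in ("open", "close")
]

#: Schedule sentinels: open around the clock / closed all day.
OPEN_24H = "24h"
CLOSED = "closed"

_HHMM = re.compile(r"^(\d{1,2}):(\d{2})$")


class SchemaError(ValueError):
    """A required column is missing or a row cannot be parsed."""


def parse_hhmm(text: str) -> int:
    """'HH:MM' → minute of day in [0, 1440]."""
    m = _HHMM.match(text.strip())
    if not m:
        raise ValueError(f"not an HH:MM time: {text!r}")
    hh, mm = int(m.group(1)), int(m.group(2))
    if hh > 24 or mm > 59 or (hh == 24 and mm != 0):
        raise ValueError(f"time out of range: {text!r}")
    return hh * 60 + mm


def format_hhmm(minute: int) -> str:
    return f"{minute // 60:02d}:{minute % 60:02d}"


@dataclass
class OutletRegistry:
    """Point environmental features with day-type-specific operating hours.

    ``df`` holds one row per outlet (id, x, y in meters, category).
    ``schedules[day_type]`` holds, per outlet, either ``None`` (closed all
    day) or a raw ``(open, close)`` minute pair; ``close < open`` denotes an
    overnight interval that wraps past midnight.
    """

    df: pd.DataFrame
    schedules: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def intervals(self, day_type: str) -> list[list[tuple[int, int]]]:
        """Half-open minute-of-day intervals per outlet for one day type.

        Overnight hours wrap: an interval (open, close) with close < open on
        day type D contributes [open, 1440) to D and [0, close) to every day
        type that can immediately follow a calendar day of type D.
        """
        out = [[] for _ in range(len(self.df))]
        for dt in DAY_TYPES:
            for k, raw in enumerate(self.schedules[dt]):
                if raw is None:
                    continue
                o, c = raw
                if o < c:
                    if dt == day_type:
                        out[k].append((o, c))
                else:  # overnight wrap
                    if dt == day_type:
                        out[k].append((o, MINUTES_PER_DAY))
                    if day_type in DAY_TYPE_SUCCESSORS[dt] and c > 0:
                        out[k].append((0, c))
        return [sorted(iv) for iv in out]

    def open_mask(self, day_type: str, minute: int) -> np.ndarray:
        """Boolean array: outlet open at ``minute`` of a ``day_type`` day."""
        ivs = self.intervals(day_type)
        return np.array(
            [any(o <= minute < c for o, c in iv) for iv in ivs], dtype=bool
        )

    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)


def _parse_schedule_cell(text, row_no: int, col: str):
    """One schedule cell → minute of day, OPEN_24H or CLOSED."""
    t = str(text).strip().lower()
    if t in ("24h", "24 h", "24hr", "always", "open24"):
        return OPEN_24H
    if t in ("closed", "none", "-", ""):
        return CLOSED
    try:
        return parse_hhmm(t)
    except ValueError as exc:
        raise SchemaError(f"row {row_no}: column {col}: {exc}") from exc


def _schedules_from_frame(df: pd.DataFrame) -> dict:
    schedules = {dt: [] for dt in DAY_TYPES}
    bad_rows: list[str] = []
    for pos, (row_no, row) in enumerate(df.iterrows()):
        for dt in DAY_TYPES:
            try:
                o = _parse_schedule_cell(row[f"{dt}_open"], row_no, f"{dt}_open")
                c = _parse_schedule_cell(row[f"{dt}_close"], row_no, f"{dt}_close")
            except SchemaError as exc:
                bad_rows.append(str(exc))
                schedules[dt].append(None)
                continue
            if OPEN_24H in (o, c):
                schedules[dt].append((0, MINUTES_PER_DAY))
            elif CLOSED in (o, c):
                schedules[dt].append(None)
            elif o == c:
                warnings.warn(
                    f"row {row_no}: {dt} open equals close "
                    f"({format_hhmm(o)}); interpreted as closed that day type"
                )
                schedules[dt].append(None)
            else:
                # closing at 00:00 or 24:00 means end of day
                c = MINUTES_PER_DAY if c in (0, MINUTES_PER_DAY) else int(c)
                schedules[dt].append((int(o), c))
    if bad_rows:
        raise SchemaError("unparseable schedules:\n" + "\n".join(bad_rows))
    return schedules


def read_outlets(path, config: StudyConfig) -> OutletRegistry:
    """Read an outlet registry from CSV or GeoJSON.

    Required fields: id, x, y (or lon/lat with a ``local:`` CRS), category,
    and the six schedule columns weekday/saturday/sunday open/close in
    HH:MM with sentinels '24h' and 'closed'.  Coordinates outside
    ``config.grid_extent`` are retained with a warning — an outlet beyond
    the grid can still influence in-extent cells through distance decay.
    """
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        df = _outlets_frame_from_geojson(path)
    else:
        df = pd.read_csv(path)

    lonlat = {"lon", "lat"}.issubset(df.columns) and not {"x", "y"}.issubset(df.columns)
    required = ["id", "category"] + SCHEDULE_COLUMNS + (
        ["lon", "lat"] if lonlat else ["x", "y"]
    )
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"outlet file is missing required column {col!r}")

    if lonlat:
        crs = config.local_crs
        if crs is None:
            raise SchemaError(
                "outlet coordinates are lon/lat but config.crs is not 'local:...'"
            )
        df["x"], df["y"] = crs.forward(df["lon"], df["lat"])

    x0, y0, x1, y1 = config.grid_extent
    outside = (df["x"] < x0) | (df["x"] >= x1) | (df["y"] < y0) | (df["y"] >= y1)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} outlet(s) fall outside the grid extent; "
            "retained (they can still influence in-extent cells via decay)"
        )
    schedules = _schedules_from_frame(df)
    keep = df[["id", "x", "y", "category"]].reset_index(drop=True)
    return OutletRegistry(df=keep, schedules=schedules)


def _outlets_frame_from_geojson(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        gj = json.load(fh)
    rows = []
    for feat in gj.get("features", []):
        props = dict(feat.get("properties") or {})
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise SchemaError("GeoJSON outlet features must be Points")
        cx, cy = geom["coordinates"][:2]
        # GeoJSON coordinates are lon/lat by convention; expose them as such
        # unless the properties already carry projected x/y.
        if "x" not in props or "y" not in props:
            props["lon"], props["lat"] = cx, cy
        rows.append(props)
    return pd.DataFrame(rows)


def write_outlets_csv(registry: OutletRegistry, path) -> None:
    df = registry.df.copy()
    for dt in DAY_TYPES:
        opens, closes = [], []
        for raw in registry.schedules[dt]:
            if raw is None:
                opens.append("closed")
                closes.append("closed")
            elif raw == (0, MINUTES_PER_DAY):
                opens.append("24h")
                closes.append("24h")
            else:
                opens.append(format_hhmm(raw[0]))
                closes.append(format_hhmm(raw[1]))
        df[f"{dt}_open"] = opens
        df[f"{dt}_close"] = closes
    df.to_csv(path, index=False, float_format="%.6f")


# -- GPS ------------------------------------------------------------------


def read_gps(path, config: StudyConfig) -> dict[str, pd.DataFrame]:
    """Read raw GPS records from CSV or GPX into per-participant frames.

    Each frame has columns timestamp (datetime64, tz-naive local), x, y
    (meters) and day_type, sorted by time with duplicate timestamps
    collapsed to the first occurrence (with a warning).  Participants with
    no records are dropped with a warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".gpx":
        df = _gps_frame_from_gpx(path, config)
    else:
        df = pd.read_csv(path)
        for col in ("participant_id", "timestamp", "x", "y"):
            if col not in df.columns:
                raise SchemaError(f"GPS file is missing required column {col!r}")
        df["timestamp"] = pd.to_datetime(df["timestamp"])

    out: dict[str, pd.DataFrame] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        n_dup = int(grp["timestamp"].duplicated().sum())
        if n_dup:
            warnings.warn(
                f"participant {pid}: {n_dup} duplicate timestamp(s) collapsed "
                "to the first occurrence"
            )
            grp = grp[~grp["timestamp"].duplicated()]
        if grp.empty:
            warnings.warn(f"participant {pid}: no records, dropped")
            continue
        grp = grp.reset_index(drop=True)
        grp["day_type"] = [day_type_of(ts.date()) for ts in grp["timestamp"]]
        out[str(pid)] = grp[["timestamp", "x", "y", "day_type"]]
    return out


def _gps_frame_from_gpx(path: Path, config: StudyConfig) -> pd.DataFrame:
    from lxml import etree

    crs = config.local_crs
    if crs is None:
        raise SchemaError("GPX input (lon/lat) requires a 'local:...' config CRS")
    tree = etree.parse(str(path))
    ns = {"g": tree.getroot().nsmap.get(None, "http://www.topografix.com/GPX/1/1")}
    rows = []
    for trk in tree.findall(".//g:trk", ns):
        name_el = trk.find("g:name", ns)
        pid = name_el.text if name_el is not None else "track"
        for pt in trk.findall(".//g:trkpt", ns):
            t_el = pt.find("g:time", ns)
            if t_el is None:
                continue
            ts = pd.Timestamp(t_el.text).tz_localize(None)
            x, y = crs.forward(float(pt.get("lon")), float(pt.get("lat")))
            rows.append((pid, ts, float(x), float(y)))
    return pd.DataFrame(rows, columns=["participant_id", "timestamp", "x", "y"])


def write_gps_csv(frames: dict[str, pd.DataFrame], path) -> None:
    parts = []
    for pid, df in frames.items():
        out = df[["timestamp", "x", "y"]].copy()
        out.insert(0, "participant_id", pid)
        parts.append(out)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False,
                                               float_format="%.6f")


# -- Raster layers --------------------------------------------------------


def write_layer_asc(grid_values: np.ndarray, grid: GridSpec, path,
                    sidecar: dict | None = None) -> None:
    """Write one raster layer as ESRI ASCII grid plus a JSON sidecar.

    The .asc body lists rows north-to-south per the format; row 0 of
    ``grid_values`` is the southernmost row.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.nx}\n")
        fh.write(f"nrows {grid.ny}\n")
        fh.write(f"xllcorner {grid.x0:.6f}\n")
        fh.write(f"yllcorner {grid.y0:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write("NODATA_value -9999\n")
        for row in grid_values[::-1]:
            fh.write(" ".join(format(v, ".12g") for v in row) + "\n")
    if sidecar is not None:
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)


def read_layer_asc(path) -> tuple[np.ndarray, GridSpec, dict | None]:
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in ("ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array(rows[::-1], dtype=float)
    grid = GridSpec(
        x0=header["xllcorner"], y0=header["yllcorner"],
        cell_size=header["cellsize"],
        nx=int(header["ncols"]), ny=int(header["nrows"]),
    )
    sidecar = None
    sc_path = path.with_suffix(".json")
    if sc_path.exists():
        with open(sc_path) as fh:
            sidecar = json.load(fh)
    return values, grid, sidecar


def write_point_cloud_csv(points: pd.DataFrame, path) -> None:
    points.to_csv(path, index=False, float_format="%.9g")


def read_point_cloud_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
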