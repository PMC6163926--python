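"""Study configuration, grid geometry, day-type calendar rules and coordinate handling.

All geometry in this package lives in a single projected, planar coordinate
system with units of meters; every distance is Euclidean.  Time-of-day is an
integer minute in [0, 1440), timestamps are timezone-naive local civil time,
and calendar dates are stratified into three *day types* — ``weekday``,
``saturday`` and ``sunday`` — because environmental schedules (business
hours) differ between them.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import yaml

DAY_TYPES = ("weekday", "saturday", "sunday")

#: Day types that can immediately follow a calendar day of the keyed type.
#: Used to assign the post-midnight portion of overnight business hours.
DAY_TYPE_SUCCESSORS = {
    "weekday": ("weekday", "saturday"),
    "saturday": ("sunday",),
    "sunday": ("weekday",),
}

MINUTES_PER_DAY = 1440

#: Mean earth radius (m) for the local tangent-plane projection.
_EARTH_RADIUS_M = 6_371_008.8


def day_type_of(date: _dt.date) -> str:
    """Day type (weekday / saturday / sunday) of a local calendar date."""
    wd = date.weekday()
    if wd == 5:
        return "saturday"
    if wd == 6:
        return "sunday"
    return "weekday"


class LocalCRS:
    """Equirectangular tangent-plane projection about a reference lon/lat.

    A lightweight, invertible lon/lat ↔ meters mapping adequate at county
    scale (distortion is second order in the angular offset from the
    reference point).  Identified by the string ``"local:<lon0>,<lat0>"``;
    any other CRS string is treated as "coordinates are already projected
    meters" and is a pure passthrough.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._coslat = math.cos(math.radians(self.lat0))

    @classmethod
    def parse(cls, crs: str) -> "LocalCRS | None":
        if crs.startswith("local:"):
            lon0, lat0 = (float(v) for v in crs[len("local:"):].split(","))
            return cls(lon0, lat0)
        return None

    def forward(self, lon, lat):
        """lon/lat degrees → (x, y) meters."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = np.radians(lon - self.lon0) * self._coslat * _EARTH_RADIUS_M
        y = np.radians(lat - self.lat0) * _EARTH_RADIUS_M
        return x, y

    def inverse(self, x, y):
        """(x, y) meters → lon/lat degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = np.degrees(x / (_EARTH_RADIUS_M * self._coslat)) + self.lon0
        lat = np.degrees(y / _EARTH_RADIUS_M) + self.lat0
        return lon, lat


@dataclass(frozen=True)
class GridSpec:
    """Regular square-cell raster geometry.

    The origin is the lower-left (south-west) corner of the extent; cells
    are indexed row-major from the south-west, cell (i, j) covering the
    half-open square [x0 + j*s, x0 + (j+1)*s) x [y0 + i*s, y0 + (i+1)*s).
    """

    x0: float
    y0: float
    cell_size: float
    nx: int
    ny: int

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """(cx, cy) arrays of shape (ny, nx) with cell-centroid coordinates."""
        s = self.cell_size
        cx = self.x0 + (np.arange(self.nx) + 0.5) * s
        cy = self.y0 + (np.arange(self.ny) + 0.5) * s
        return np.meshgrid(cx, cy)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(i, j) index of the cell containing a point (half-open rule)."""
        j = int(math.floor((x - self.x0) / self.cell_size))
        i = int(math.floor((y - self.y0) / self.cell_size))
        return i, j


@dataclass
class StudyConfig:
    """Run configuration for one study.

    Parameters
    ----------
    crs:
        Coordinate system identifier.  ``"local:<lon0>,<lat0>"`` enables
        lon/lat input via :class:`LocalCRS`; any other value asserts that
        input coordinates are already projected meters.
    grid_extent:
        (x0, y0, x1, y1) in meters.  If a cell size does not divide the
        extent, the extent is padded east/north to the next multiple and
        the padding recorded in :attr:`padding_m`.
    spatial_resolutions:
        Raster cell sizes in meters.
    temporal_resolutions:
        Layer slot lengths in minutes; each must divide 1440.
    decay_methods:
        Subset of {"KD", "ISDD", "NEDD"}.
    decay_params:
        Per-method scale parameter in meters (KD bandwidth h; ISDD and
        NEDD half-distance / e-folding scale d0).
    br:
        Space-time tunnel buffer radius in meters.
    weight_mode:
        "constant" (every intersected point weighs 1) or "velocity"
        (weight halves per m/min of movement speed).
    """

    crs: str = "EPSG:32617"
    grid_extent: tuple[float, float, float, float] = (0.0, 0.0, 3000.0, 3000.0)
    spatial_resolutions: tuple[float, ...] = (100.0, 150.0, 200.0)
    temporal_resolutions: tuple[int, ...] = (30, 10)
    decay_methods: tuple[str, ...] = ("KD", "ISDD", "NEDD")
    decay_params: dict = field(
        default_factory=lambda: {"KD": 1000.0, "ISDD": 100.0, "NEDD": 500.0}
    )
    br: float = 100.0
    weight_mode: str = "constant"
    seed: int = 0
    #: Per-cell-size (east, north) padding applied to reach a whole cell count.
    padding_m: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.grid_extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError("grid_extent must have positive width and height")
        for t in self.temporal_resolutions:
            if MINUTES_PER_DAY % int(t) != 0:
                raise ValueError(f"temporal resolution {t} does not divide 1440")
        unknown = set(self.decay_methods) - {"KD", "ISDD", "NEDD"}
        if unknown:
            raise ValueError(f"unknown decay methods: {sorted(unknown)}")
        for m in self.decay_methods:
            if self.decay_params.get(m, 0) <= 0:
                raise ValueError(f"decay scale for {m} must be positive")
        if self.br <= 0:
            raise ValueError("br must be positive")
        if self.weight_mode not in ("constant", "velocity"):
            raise ValueError("weight_mode must be 'constant' or 'velocity'")
        for s in self.spatial_resolutions:
            self.grid(s)  # record padding up front

    def grid(self, cell_size: float) -> GridSpec:
        """Grid geometry for one cell size, padding the extent if needed."""
        x0, y0, x1, y1 = self.grid_extent
        nx = math.ceil(round((x1 - x0) / cell_size, 9))
        ny = math.ceil(round((y1 - y0) / cell_size, 9))
        pad_e = nx * cell_size - (x1 - x0)
        pad_n = ny * cell_size - (y1 - y0)
        if pad_e > 1e-9 or pad_n > 1e-9:
            self.padding_m[cell_size] = (pad_e, pad_n)
        return GridSpec(x0=x0, y0=y0, cell_size=cell_size, nx=nx, ny=ny)

    @property
    def local_crs(self) -> LocalCRS | None:
        return LocalCRS.parse(self.crs)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_extent"] = list(self.grid_extent)
        d["spatial_resolutions"] = list(self.spatial_resolutions)
        d["temporal_resolutions"] = list(self.temporal_resolutions)
        d["decay_methods"] = list(self.decay_methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        d.pop("padding_m", None)
        for key in ("grid_extent", "spatial_resolutions", "temporal_resolutions",
                    "decay_methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def method_key(method: str, cell_size: float, slot_minutes: int) -> str:
    """Canonical exposure-model key, e.g. ``ISDD100T10``."""
    return f"{method}{int(round(cell_size))}T{int(slot_minutes)}"


def iter_cube_keys(config: StudyConfig) -> Iterator[tuple[str, float, int, str]]:
    """All (method, cell_size, slot_minutes, day_type) combinations."""
    for m in config.decay_methods:
        for s in config.spatial_resolutions:
            for t in config.temporal_resolutions:
                for dt in DAY_TYPES:
                    yield m, s, t, dt
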