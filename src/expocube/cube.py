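"""Environmental context cubes: stacked time-sliced rasters and point clouds.

A cube is a (time, y, x) voxel grid for one day type, decay method and
spatial/temporal resolution pair.  The native build has 48 half-hour
layers; a 10-min cube keeps those 48 and inserts 96 layers by per-pixel
linear interpolation between temporally adjacent originals, wrapping
23:30 → 00:00 to honour the daily periodicity of schedules.  For
intersection with space-time tunnels a cube is flattened to a point cloud
with one point per voxel at the voxel centroid (cell centroid in x/y, slot
midpoint in t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DAY_TYPES, MINUTES_PER_DAY, GridSpec, StudyConfig, method_key
from .decay import EnvLayer, build_layer, decay_matrix
from .io import OutletRegistry


@dataclass
class ContextCube:
    day_type: str
    method: str
    cell_size: float
    slot_minutes: int
    layers: list[EnvLayer]
    grid_spec: GridSpec

    def __post_init__(self) -> None:
        if len(self.layers) != MINUTES_PER_DAY // self.slot_minutes:
            raise ValueError(
                f"cube needs {MINUTES_PER_DAY // self.slot_minutes} layers, "
                f"got {len(self.layers)}"
            )
        starts = [l.slot_start for l in self.layers]
        if starts != sorted(set(starts)):
            raise ValueError("layer slot starts must be strictly increasing")

    @property
    def t_axis(self) -> np.ndarray:
        """Slot start times (minute of day)."""
        return np.array([l.slot_start for l in self.layers])

    @property
    def key(self) -> str:
        return method_key(self.method, self.cell_size, self.slot_minutes)

    def values(self) -> np.ndarray:
        """(n_layers, ny, nx) voxel values."""
        return np.stack([l.grid for l in self.layers])

    def lookup(self, x: float, y: float, t: float) -> float:
        """Value of the voxel containing planar point (x, y) at minute t."""
        i, j = self.grid_spec.cell_of(x, y)
        k = int(t // self.slot_minutes) % len(self.layers)
        return float(self.layers[k].grid[i, j])


@dataclass
class CubePointCloud:
    """One point per voxel at (cell centroid x, cell centroid y, slot midpoint t)."""

    points: pd.DataFrame  # columns x, y, t, value
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.points)


def build_cube(registry: OutletRegistry, day_type: str, method: str,
               cell_size: float, params: float, config: StudyConfig,
               slot_minutes: int = 30) -> ContextCube:
    """Native cube: one layer per ``slot_minutes`` slot (48 at 30 min)."""
    grid = config.grid(cell_size)
    dmat = decay_matrix(registry, grid, method, params)
    layers = [
        build_layer(registry, day_type, start, method, cell_size, params,
                    grid, _decay=dmat)
        for start in range(0, MINUTES_PER_DAY, slot_minutes)
    ]
    return ContextCube(
        day_type=day_type, method=method, cell_size=cell_size,
        slot_minutes=slot_minutes, layers=layers, grid_spec=grid,
    )


def refine_cube(cube: ContextCube, slot_minutes: int = 10) -> ContextCube:
    """Insert temporally interpolated layers between a coarser cube's originals.

    Original layers are copied unchanged; a layer at fraction f between
    adjacent originals L0 and L1 equals (1-f)·L0 + f·L1 per pixel.  Layers
    after the last original interpolate toward the first (midnight wrap).
    """
    if cube.slot_minutes % slot_minutes != 0:
        raise ValueError(
            f"target slot {slot_minutes} min must divide source slot "
            f"{cube.slot_minutes} min"
        )
    ratio = cube.slot_minutes // slot_minutes
    n0 = len(cube.layers)
    out: list[EnvLayer] = []
    for k in range(n0):
        L0 = cube.layers[k]
        L1 = cube.layers[(k + 1) % n0]
        for m in range(ratio):
            start = L0.slot_start + m * slot_minutes
            if m == 0:
                grid_vals = L0.grid
            else:
                f = m / ratio
                grid_vals = (1.0 - f) * L0.grid + f * L1.grid
            out.append(
                EnvLayer(
                    day_type=L0.day_type, slot_start=start, method=L0.method,
                    cell_size=L0.cell_size, grid=grid_vals, params=L0.params,
                    grid_spec=L0.grid_spec,
                )
            )
    return ContextCube(
        day_type=cube.day_type, method=cube.method, cell_size=cube.cell_size,
        slot_minutes=slot_minutes, layers=out, grid_spec=cube.grid_spec,
    )


def to_point_cloud(cube: ContextCube, drop_zero: bool = False) -> CubePointCloud:
    """Flatten a cube to voxel-centroid points; value copied exactly.

    ``drop_zero`` filters zero-value points (recorded in provenance);
    tunnel intersections are unaffected because dropped points contribute 0
    to the exposure sum.
    """
    cx, cy = cube.grid_spec.centroids()
    n_cells = cube.grid_spec.n_cells
    frames = []
    for layer in cube.layers:
        frames.append(
            pd.DataFrame(
                {
                    "x": cx.ravel(),
                    "y": cy.ravel(),
                    "t": np.full(n_cells, layer.slot_start + cube.slot_minutes / 2),
                    "value": layer.grid.ravel(),
                }
            )
        )
    pts = pd.concat(frames, ignore_index=True)
    if drop_zero:
        pts = pts[pts["value"] != 0.0].reset_index(drop=True)
    return CubePointCloud(
        points=pts,
        provenance={
            "key": cube.key, "day_type": cube.day_type,
            "slot_minutes": cube.slot_minutes, "drop_zero": drop_zero,
        },
    )


def enumerate_cubes(registry: OutletRegistry, config: StudyConfig
                    ) -> dict[tuple[str, float, int, str], ContextCube]:
    """Build the full configured cube menu.

    Keys are (method, cell_size, slot_minutes, day_type); the full default
    menu (3 methods x 3 cell sizes x 2 temporal resolutions x 3 day types)
    yields 54 cubes.  Finer temporal resolutions are refined from the
    coarsest native build so that the 30-min layers are shared.
    """
    base_slot = max(config.temporal_resolutions)
    cubes: dict[tuple[str, float, int, str], ContextCube] = {}
    for method in config.decay_methods:
        params = config.decay_params[method]
        for cell_size in config.spatial_resolutions:
            for day_type in DAY_TYPES:
                native = build_cube(registry, day_type, method, cell_size,
                                    params, config, slot_minutes=base_slot)
                for slot in sorted(config.temporal_resolutions, reverse=True):
                    cube = native if slot == base_slot else refine_cube(native, slot)
                    cubes[(method, cell_size, slot, day_type)] = cube
    return cubes
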