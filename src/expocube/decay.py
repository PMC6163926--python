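"""Time-sliced food-environment raster layers under three distance-decay models.

Each layer maps the influence of the outlets *open at a given minute of a
given day type* onto a regular grid.  An outlet's influence at distance d
(meters, planar) follows one of:

* **KD** — quartic (biweight) kernel, compact support at bandwidth h:
  ``3/(pi h^2) * (1 - (d/h)^2)^2`` for d < h, else 0.  Each outlet's
  surface integrates to 1 over the plane.
* **ISDD** — bounded inverse-square decay ``1 / (1 + (d/d0)^2)``: value 1
  at the outlet, 1/2 at d0, asymptotically (d0/d)^2 — inverse-square
  behaviour without the 1/d^2 singularity at the outlet itself.
* **NEDD** — negative exponential ``exp(-d/d0)``.

A cell's value is the decay weight summed over open outlets, evaluated at
the cell centroid.  Values below 1e-9 are snapped to zero to keep rasters
sparse; the cutoff is recorded in layer sidecars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GridSpec
from .io import OutletRegistry

EVALUATION_CUTOFF = 1e-9

METHODS = ("KD", "ISDD", "NEDD")


@dataclass
class EnvLayer:
    """One time slot's environmental-context raster for one day type."""

    day_type: str
    slot_start: int  # minute of day
    method: str
    cell_size: float
    grid: np.ndarray  # (ny, nx), row 0 southernmost
    params: float  # method scale parameter (m)
    grid_spec: GridSpec | None = None

    def __post_init__(self) -> None:
        if np.any(self.grid < 0):
            raise ValueError("layer values must be non-negative")


def decay_value(method: str, distance, params: float):
    """Decay weight of a single outlet at planar distance(s) in meters."""
    if params <= 0:
        raise ValueError(f"decay scale parameter must be positive, got {params}")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if method == "KD":
        h = params
        u = d / h
        w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0) * (3.0 / (np.pi * h**2))
    elif method == "ISDD":
        w = 1.0 / (1.0 + (d / params) ** 2)
    elif method == "NEDD":
        w = np.exp(-d / params)
    else:
        raise ValueError(f"unknown decay method {method!r}")
    return w if w.shape else float(w)


def open_outlets(registry: OutletRegistry, day_type: str, slot_start: int) -> np.ndarray:
    """Indices of outlets open at ``slot_start`` minutes on a ``day_type`` day."""
    return np.flatnonzero(registry.open_mask(day_type, slot_start))


def decay_matrix(registry: OutletRegistry, grid: GridSpec, method: str,
                 params: float) -> np.ndarray:
    """(n_cells, n_outlets) decay weights from every cell centroid to every outlet.

    Shared across a cube's time slots (distances do not change with time);
    a layer is a masked column sum of this matrix.
    """
    cx, cy = grid.centroids()
    pts = np.column_stack([cx.ravel(), cy.ravel()])
    oc = registry.coords()
    d = np.hypot(
        pts[:, 0][:, None] - oc[None, :, 0], pts[:, 1][:, None] - oc[None, :, 1]
    )
    return decay_value(method, d, params)


def build_layer(registry: OutletRegistry, day_type: str, slot_start: int,
                method: str, cell_size: float, params: float,
                grid: GridSpec, _decay: np.ndarray | None = None) -> EnvLayer:
    """Sum decay surfaces of the open outlets onto the grid for one slot."""
    open_idx = open_outlets(registry, day_type, slot_start)
    if _decay is None:
        _decay = decay_matrix(registry, grid, method, params)
    values = _decay[:, open_idx].sum(axis=1).reshape(grid.ny, grid.nx)
    values[values < EVALUATION_CUTOFF] = 0.0
    return EnvLayer(
        day_type=day_type, slot_start=slot_start, method=method,
        cell_size=cell_size, grid=values, params=params, grid_spec=grid,
    )
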