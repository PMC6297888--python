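"""The 26-layer eco-geographic predictor stack.

Layers 1-19 are the bioclimatic variables; 20-22 solar radiation, wind
speed and water vapor pressure; 23 altitude; 24 slope and 25-26 the two
aspect components, derived here from altitude with Horn's 8-neighbour
gradient method (the default of the R ``terrain`` function).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_grid import KM_PER_DEGREE, GridSpec, RasterLayer

N_BIOCLIM = 19
N_LAYERS = 26

LAYER_NAME_TEMPLATE = "wc2.0_bio_2.5m_{:02d}"

TAG_BIOCLIM = "bioclim"
TAG_CLIMATE = "climate"
TAG_ALTITUDE = "altitude"
TAG_DERIVED = "derived"


@dataclass
class PredictorStack:
    """Ordered, grid-aligned list of (name, layer, source-tag) triples."""

    grid: GridSpec
    layers: list[tuple[str, RasterLayer, str]]

    def __post_init__(self):
        if len(self.layers) != N_LAYERS:
            raise ValueError(f"stack must hold exactly {N_LAYERS} layers, got {len(self.layers)}")
        names = [name for name, _, _ in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for name, layer, _tag in self.layers:
            if layer.grid != self.grid:
                raise ValueError(f"layer {name!r} not aligned to the stack grid")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.layers]

    def layer(self, name: str) -> RasterLayer:
        for n, lyr, _ in self.layers:
            if n == name:
                return lyr
        raise KeyError(name)

    def tags(self) -> list[str]:
        return [tag for _, _, tag in self.layers]

    def values_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, 26) matrix of predictor values; nodata -> NaN."""
        out = np.empty((len(rows), N_LAYERS), dtype=float)
        for j, (_, lyr, _) in enumerate(self.layers):
            v = lyr.values[rows, cols].astype(float)
            v[v == lyr.grid.nodata] = np.nan
            out[:, j] = v
        return out


def _horn_gradients(altitude: RasterLayer) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Horn (8-neighbour) dz/dx (east+) and dz/dy (north+) in m/m.

    Cell sizes convert to metres per row: dx scales with cos(latitude).
    Returns (gx, gy, valid) where valid marks interior cells whose full
    3x3 neighbourhood holds data.
    """
    g = altitude.grid
    z = np.asarray(altitude.values, dtype=float)
    nod = z == g.nodata
    n_rows, n_cols = g.shape

    valid = np.zeros((n_rows, n_cols), dtype=bool)
    gx = np.full((n_rows, n_cols), np.nan)
    gy = np.full((n_rows, n_cols), np.nan)
    if n_rows < 3 or n_cols < 3:
        return gx, gy, valid

    # neighbourhood data check via shifted views
    ok = ~nod
    nb_ok = np.ones((n_rows - 2, n_cols - 2), dtype=bool)
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            nb_ok &= ok[dr : dr + n_rows - 2, dc : dc + n_cols - 2]
    valid[1:-1, 1:-1] = nb_ok

    def sub(dr, dc):
        return z[dr : dr + n_rows - 2, dc : dc + n_cols - 2]

    lat = g.row_center_lats()[1:-1]
    dy_m = g.cell_size_deg * KM_PER_DEGREE * 1000.0
    dx_m = dy_m * np.cos(np.radians(lat))[:, None]

    gx_i = ((sub(0, 2) + 2 * sub(1, 2) + sub(2, 2)) - (sub(0, 0) + 2 * sub(1, 0) + sub(2, 0))) / (8.0 * dx_m)
    gy_i = ((sub(0, 0) + 2 * sub(0, 1) + sub(0, 2)) - (sub(2, 0) + 2 * sub(2, 1) + sub(2, 2))) / (8.0 * dy_m)

    gx[1:-1, 1:-1] = gx_i
    gy[1:-1, 1:-1] = gy_i
    gx[~valid] = np.nan
    gy[~valid] = np.nan
    return gx, gy, valid


def derive_slope(altitude: RasterLayer) -> RasterLayer:
    """Slope in degrees; border and nodata-adjacent cells -> nodata."""
    gx, gy, valid = _horn_gradients(altitude)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    out = np.full(altitude.grid.shape, altitude.grid.nodata, dtype=float)
    out[valid] = slope[valid]
    return RasterLayer(altitude.grid, out, "continuous")


def derive_aspect_components(altitude: RasterLayer) -> tuple[RasterLayer, RasterLayer]:
    """(cos, sin) of the downslope compass direction; flat cells -> (0, 0).

    The compass angle is measured clockwise from north, so a plane dipping
    due south gives (ns, ew) = (-1, 0).
    """
    gx, gy, valid = _horn_gradients(altitude)
    nod = altitude.grid.nodata
    ns = np.full(altitude.grid.shape, nod, dtype=float)
    ew = np.full(altitude.grid.shape, nod, dtype=float)

    mag = np.hypot(gx, gy)
    flat = valid & (mag == 0)
    sloped = valid & (mag > 0)
    # downslope unit vector in (east, north) = (-gx, -gy)/|g|
    theta = np.arctan2(-gx, -gy)  # clockwise-from-north compass angle
    ns[sloped] = np.cos(theta[sloped])
    ew[sloped] = np.sin(theta[sloped])
    ns[flat] = 0.0
    ew[flat] = 0.0
    return (
        RasterLayer(altitude.grid, ns, "continuous"),
        RasterLayer(altitude.grid, ew, "continuous"),
    )


def assemble_stack(
    bioclim_layers: Sequence[RasterLayer],
    solar: RasterLayer,
    wind: RasterLayer,
    vapor: RasterLayer,
    altitude: RasterLayer,
) -> PredictorStack:
    """Build the 26-layer stack; slope and aspect derived internally."""
    if len(bioclim_layers) != N_BIOCLIM:
        raise ValueError(f"expected {N_BIOCLIM} bioclim layers, got {len(bioclim_layers)}")
    grid = altitude.grid
    for lyr in [*bioclim_layers, solar, wind, vapor]:
        if lyr.grid != grid:
            raise ValueError("all input layers must share one grid")

    slope = derive_slope(altitude)
    aspect_ns, aspect_ew = derive_aspect_components(altitude)

    ordered: list[tuple[RasterLayer, str]] = [
        *[(lyr, TAG_BIOCLIM) for lyr in bioclim_layers],
        (solar, TAG_CLIMATE),
        (wind, TAG_CLIMATE),
        (vapor, TAG_CLIMATE),
        (altitude, TAG_ALTITUDE),
        (slope, TAG_DERIVED),
        (aspect_ns, TAG_DERIVED),
        (aspect_ew, TAG_DERIVED),
    ]
    layers = [
        (LAYER_NAME_TEMPLATE.format(i + 1), lyr, tag)
        for i, (lyr, tag) in enumerate(ordered)
    ]
    return PredictorStack(grid=grid, layers=layers)
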