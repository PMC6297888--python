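"""Shared raster-grid and polygon primitives.

All coordinates are lon/lat WGS84. Rasters are north-up: row 0 is the
northernmost row, column 0 the westernmost column. Distances use the mean
Earth radius (6371 km).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: kilometres per degree of arc on a great circle of the mean-radius sphere
KM_PER_DEGREE = EARTH_RADIUS_KM * math.pi / 180.0

#: 2.5 arc minutes in decimal degrees, the pipeline's working resolution
DEFAULT_CELL_SIZE_DEG = 2.5 / 60.0

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat raster grid.

    ``origin_lon``/``origin_lat`` locate the grid's upper-left *corner*;
    the centre of cell ``(r, c)`` is at
    ``(origin_lon + (c + 0.5) * cell_size_deg,
    origin_lat - (r + 0.5) * cell_size_deg)``.
    """

    cell_size_deg: float = DEFAULT_CELL_SIZE_DEG
    origin_lon: float = -180.0
    origin_lat: float = 90.0
    n_rows: int = 1
    n_cols: int = 1
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def row_center_lats(self) -> np.ndarray:
        r = np.arange(self.n_rows)
        return self.origin_lat - (r + 0.5) * self.cell_size_deg

    def col_center_lons(self) -> np.ndarray:
        c = np.arange(self.n_cols)
        return self.origin_lon + (c + 0.5) * self.cell_size_deg


def cell_center(grid: GridSpec, row: int, col: int) -> tuple[float, float]:
    """Return the (lon, lat) of the centre of cell ``(row, col)``."""
    if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
        raise IndexError(f"cell ({row}, {col}) outside grid {grid.shape}")
    lon = grid.origin_lon + (col + 0.5) * grid.cell_size_deg
    lat = grid.origin_lat - (row + 0.5) * grid.cell_size_deg
    return lon, lat


def cell_index(grid: GridSpec, lon: float, lat: float) -> tuple[int, int]:
    """Return the (row, col) of the cell containing (lon, lat).

    Exact inverse of :func:`cell_center` on cell centres. Raises
    :class:`IndexError` for points outside the grid extent.
    """
    col = math.floor((lon - grid.origin_lon) / grid.cell_size_deg)
    row = math.floor((grid.origin_lat - lat) / grid.cell_size_deg)
    if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
        raise IndexError(f"point ({lon}, {lat}) outside grid extent")
    return row, col


def contains_point(grid: GridSpec, lon: float, lat: float) -> bool:
    """True if (lon, lat) falls within the grid's extent."""
    try:
        cell_index(grid, lon, lat)
    except IndexError:
        return False
    return True


def cell_width_km_at_equator(cell_size_deg: float) -> float:
    """Great-circle length (km) of one cell edge along the equator."""
    if cell_size_deg <= 0:
        raise ValueError("cell_size_deg must be positive")
    return cell_size_deg * KM_PER_DEGREE


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km between two lon/lat points."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    a = min(1.0, a)
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def haversine_km_vec(lon1, lat1, lon2, lat2):
    """Vectorised haversine (broadcasts numpy arrays), km."""
    phi1 = np.radians(np.asarray(lat1, dtype=float))
    phi2 = np.radians(np.asarray(lat2, dtype=float))
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass
class RasterLayer:
    """A raster aligned to a :class:`GridSpec`.

    ``semantics`` is one of ``continuous``, ``categorical`` or ``binary``.
    Binary layers may contain only {0, 1, nodata}.
    """

    grid: GridSpec
    values: np.ndarray
    semantics: str = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.semantics not in ("continuous", "categorical", "binary"):
            raise ValueError(f"unknown semantics {self.semantics!r}")
        if self.semantics == "binary":
            v = self.values
            ok = (v == 0) | (v == 1) | (v == self.grid.nodata)
            if not np.all(ok):
                raise ValueError("binary layer contains values outside {0, 1, nodata}")

    @property
    def nodata(self) -> float:
        return self.grid.nodata

    def data_mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return self.values != self.grid.nodata

    def copy(self) -> "RasterLayer":
        return RasterLayer(self.grid, self.values.copy(), self.semantics)


@dataclass
class Polygon:
    """Simple polygon in lon/lat with optional holes and attributes."""

    exterior: list[tuple[float, float]]
    holes: list[list[tuple[float, float]]] = field(default_factory=list)
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exterior = _normalize_ring(self.exterior)
        self.holes = [_normalize_ring(h) for h in self.holes]

    def rings(self) -> list[list[tuple[float, float]]]:
        return [self.exterior, *self.holes]

    def bounds(self) -> tuple[float, float, float, float]:
        xs = [p[0] for p in self.exterior]
        ys = [p[1] for p in self.exterior]
        return min(xs), min(ys), max(xs), max(ys)


def _normalize_ring(ring: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    pts = [(float(x), float(y)) for x, y in ring]
    if len(pts) >= 2 and pts[0] == pts[-1]:
        pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError("polygon ring needs at least 3 distinct vertices")
    for x, y in pts:
        if not (-180.0 <= x <= 180.0 and -90.0 <= y <= 90.0):
            raise ValueError(f"vertex ({x}, {y}) outside lon/lat bounds")
    return pts


def rect_polygon(
    west: float, south: float, east: float, north: float, **attrs
) -> Polygon:
    """Axis-aligned rectangle polygon (a synthgen staple)."""
    return Polygon(
        [(west, south), (east, south), (east, north), (west, north)], attrs=attrs
    )


def _on_segment(px, py, ax, ay, bx, by, eps=1e-12) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if abs(cross) > eps * max(1.0, abs(bx - ax), abs(by - ay)):
        return False
    if min(ax, bx) - eps <= px <= max(ax, bx) + eps and min(ay, by) - eps <= py <= max(ay, by) + eps:
        return True
    return False


def point_in_polygon(lon: float, lat: float, polygon: Polygon) -> bool:
    """Even-odd (ray casting) membership; boundary points count as inside."""
    for ring in polygon.rings():
        n = len(ring)
        for i in range(n):
            ax, ay = ring[i]
            bx, by = ring[(i + 1) % n]
            if _on_segment(lon, lat, ax, ay, bx, by):
                return True
    inside = False
    for ring in polygon.rings():
        n = len(ring)
        for i in range(n):
            ax, ay = ring[i]
            bx, by = ring[(i + 1) % n]
            if (ay > lat) != (by > lat):
                x_cross = ax + (lat - ay) * (bx - ax) / (by - ay)
                if lon < x_cross:
                    inside = not inside
    return inside


def points_in_polygon(lons: np.ndarray, lats: np.ndarray, polygon: Polygon) -> np.ndarray:
    """Vectorised :func:`point_in_polygon` over arrays of points.

    Same even-odd semantics and on-boundary-is-inside convention.
    """
    px = np.asarray(lons, dtype=float)
    py = np.asarray(lats, dtype=float)
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    eps = 1e-12
    for ring in polygon.rings():
        n = len(ring)
        for i in range(n):
            ax, ay = ring[i]
            bx, by = ring[(i + 1) % n]
            scale = eps * max(1.0, abs(bx - ax), abs(by - ay))
            cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
            bbox = (
                (px >= min(ax, bx) - eps)
                & (px <= max(ax, bx) + eps)
                & (py >= min(ay, by) - eps)
                & (py <= max(ay, by) + eps)
            )
            on_edge |= (np.abs(cross) <= scale) & bbox
            crosses = (ay > py) != (by > py)
            if np.any(crosses):
                with np.errstate(divide="ignore", invalid="ignore"):
                    x_cross = ax + (py - ay) * (bx - ax) / (by - ay)
                inside ^= crosses & (px < x_cross)
    return inside | on_edge


# ---------------------------------------------------------------------------
# Plain-text I/O (ESRI-ASCII-style grid; GeoJSON polygons)
# ---------------------------------------------------------------------------

def write_ascii_grid(layer: RasterLayer, path) -> None:
    g = layer.grid
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.origin_lon!r}\n")
        fh.write(f"yllcorner {g.origin_lat - g.n_rows * g.cell_size_deg!r}\n")
        fh.write(f"cellsize {g.cell_size_deg!r}\n")
        fh.write(f"NODATA_value {g.nodata!r}\n")
        np.savetxt(fh, np.asarray(layer.values, dtype=float), fmt="%.10g")


def read_ascii_grid(path, semantics: str = "continuous") -> RasterLayer:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    grid = GridSpec(
        cell_size_deg=cell,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
        n_rows=n_rows,
        n_cols=n_cols,
        nodata=header["nodata_value"],
    )
    return RasterLayer(grid, values, semantics)


def write_geojson(polygons: Iterable[Polygon], path) -> None:
    feats = []
    for poly in polygons:
        coords = [[list(p) for p in poly.exterior] + [list(poly.exterior[0])]]
        for hole in poly.holes:
            coords.append([list(p) for p in hole] + [list(hole[0])])
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": coords},
                "properties": poly.attrs,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_geojson(path) -> list[Polygon]:
    with open(path) as fh:
        doc = json.load(fh)
    polys: list[Polygon] = []
    for feat in doc["features"]:
        geom = feat["geometry"]
        props = feat.get("properties") or {}
        if geom["type"] == "Polygon":
            ringsets = [geom["coordinates"]]
        elif geom["type"] == "MultiPolygon":
            ringsets = geom["coordinates"]
        else:
            raise ValueError(f"unsupported geometry type {geom['type']!r}")
        for rings in ringsets:
            polys.append(
                Polygon(
                    [tuple(p) for p in rings[0]],
                    holes=[[tuple(p) for p in r] for r in rings[1:]],
                    attrs=dict(props),
                )
            )
    return polys
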