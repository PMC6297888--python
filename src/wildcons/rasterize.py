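"""Polygon-to-raster assignment rules and the protected-area filter.

Two rules are provided: *cell center* (a cell takes the category of the
polygon containing its centre — used for ecoregions) and *maximum area*
(a cell takes the category covering the largest fraction of the cell,
estimated on an s x s sub-point lattice — used for protected areas).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_grid import GridSpec, Polygon, RasterLayer, points_in_polygon

logger = logging.getLogger(__name__)

DEFAULT_SUBSAMPLE = 16

WDPA_KEEP_STATUSES = frozenset({"designated", "inscribed", "established"})
WDPA_KEEP_DOMAINS = frozenset({"terrestrial", "coastal"})

CATEGORY_ATTR = "category"
NODATA_CATEGORY = -1


@dataclass
class CategoricalRaster:
    grid: GridSpec
    values: np.ndarray  # integer category ids; NODATA_CATEGORY where unassigned

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")

    def categories_present(self, where: np.ndarray | None = None) -> set[int]:
        v = self.values if where is None else self.values[where]
        return set(int(c) for c in np.unique(v) if c != NODATA_CATEGORY)


def _poly_category(poly: Polygon, index: int) -> int:
    cat = poly.attrs.get(CATEGORY_ATTR)
    return int(cat) if cat is not None else index


def _valid_polys(polygons: Sequence[Polygon]):
    out = []
    for i, poly in enumerate(polygons):
        try:
            poly.bounds()
        except Exception:  # pragma: no cover - defensive
            logger.warning("skipping invalid polygon at index %d", i)
            continue
        out.append((i, poly))
    return out


def rasterize_cell_center(polygons: Sequence[Polygon], grid: GridSpec) -> CategoricalRaster:
    """Assign each cell the category of the polygon containing its centre.

    Overlap ties break toward the lowest polygon index. Cells covered by
    no polygon stay unassigned.
    """
    values = np.full(grid.shape, NODATA_CATEGORY, dtype=int)
    lon_g, lat_g = np.meshgrid(grid.col_center_lons(), grid.row_center_lats())
    for i, poly in _valid_polys(polygons):
        cat = _poly_category(poly, i)
        hit = points_in_polygon(lon_g, lat_g, poly)
        # earlier polygons win ties
        assign = hit & (values == NODATA_CATEGORY)
        values[assign] = cat
    return CategoricalRaster(grid, values)


def rasterize_max_area(
    polygons: Sequence[Polygon], grid: GridSpec, subsample: int = DEFAULT_SUBSAMPLE
) -> CategoricalRaster:
    """Assign each cell the category covering the largest cell fraction.

    Fractions are estimated by testing an evenly spaced ``subsample`` x
    ``subsample`` lattice of points inside each cell. Zero coverage leaves
    the cell unassigned; equal-coverage ties break toward the lowest
    category id.
    """
    if subsample < 4:
        raise ValueError("subsample must be >= 4")
    s = subsample
    size = grid.cell_size_deg
    # one flat lattice of s x s sub-points per cell, whole grid at once
    sub_lons = grid.origin_lon + (np.arange(grid.n_cols * s) + 0.5) * size / s
    sub_lats = grid.origin_lat - (np.arange(grid.n_rows * s) + 0.5) * size / s
    lon_g, lat_g = np.meshgrid(sub_lons, sub_lats)

    best_count = np.zeros(grid.shape, dtype=int)
    best_cat = np.full(grid.shape, NODATA_CATEGORY, dtype=int)

    polys = _valid_polys(polygons)
    cats = sorted({_poly_category(p, i) for i, p in polys})
    for cat in cats:
        members = [p for i, p in polys if _poly_category(p, i) == cat]
        covered = np.zeros(lon_g.shape, dtype=bool)
        for poly in members:
            covered |= points_in_polygon(lon_g, lat_g, poly)
        counts = covered.reshape(grid.n_rows, s, grid.n_cols, s).sum(axis=(1, 3))
        # strict > keeps the lowest category id on ties (cats ascend)
        better = counts > best_count
        best_count[better] = counts[better]
        best_cat[better] = cat
    return CategoricalRaster(grid, best_cat)


def filter_wdpa(polygons: Sequence[Polygon]) -> list[Polygon]:
    """Keep designated/inscribed/established terrestrial or coastal
    reserves; polygons with no status attribute are excluded with a
    warning."""
    kept = []
    for poly in polygons:
        status = poly.attrs.get("status")
        if status is None:
            logger.warning("excluding protected-area polygon with missing status")
            continue
        domain = str(poly.attrs.get("designation_domain", "")).strip().lower()
        if str(status).strip().lower() in WDPA_KEEP_STATUSES and domain in WDPA_KEEP_DOMAINS:
            kept.append(poly)
    return kept


def to_binary_pa_raster(
    filtered_polygons: Sequence[Polygon],
    grid: GridSpec,
    subsample: int = DEFAULT_SUBSAMPLE,
) -> RasterLayer:
    """Binary 1=protected / 0=not-protected raster via the maximum-area
    rule applied to the single category "protected"."""
    single = [
        Polygon(p.exterior, holes=p.holes, attrs={CATEGORY_ATTR: 1})
        for p in filtered_polygons
    ]
    cat = rasterize_max_area(single, grid, subsample=subsample)
    values = (cat.values != NODATA_CATEGORY).astype(float)
    return RasterLayer(grid, values, "binary")
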