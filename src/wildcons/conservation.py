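"""Per-species ex situ and in situ conservation scores.

Three component scores, each 0-100, are computed ex situ (against the
G-record circular buffer) and in situ (against protected areas):

* SRS - sampling representativeness (record counts),
* GRS - geographic representativeness (area coverage of the distribution),
* ERS - ecological representativeness (ecoregion coverage).

Final conservation scores (FCS) are unweighted means: fcs_ex and fcs_in
over their three components, fcs_combined over the two of them. Priority
categories cut fcs_combined at 25 / 50 / 75.

Any score with a zero denominator is 0 (conservative convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_grid import KM_PER_DEGREE, GridSpec, RasterLayer, cell_index
from .occurrences import CountsSummary, OccurrenceRecord
from .rasterize import CategoricalRaster

CATEGORY_THRESHOLDS = (25.0, 50.0, 75.0)
CATEGORY_LABELS = ("urgent", "high", "medium", "low_priority")


@dataclass
class CellAreaModel:
    """Per-row spherical cell areas, km^2, proportional to cos(latitude)."""

    grid: GridSpec

    def row_areas_km2(self) -> np.ndarray:
        edge_km = self.grid.cell_size_deg * KM_PER_DEGREE
        return np.cos(np.radians(self.grid.row_center_lats())) * edge_km**2

    def area_of(self, binary: np.ndarray) -> float:
        """Total area (km^2) of the True/1 cells of a 2-D array."""
        rows = self.row_areas_km2()
        return float((np.asarray(binary, dtype=bool) * rows[:, None]).sum())


@dataclass
class ConservationScores:
    species_id: str
    srs_ex: float
    grs_ex: float
    ers_ex: float
    srs_in: float
    grs_in: float
    ers_in: float
    fcs_ex: float = 0.0
    fcs_in: float = 0.0
    fcs_combined: float = 0.0
    category: str = ""


def srs_ex(counts: CountsSummary) -> float:
    """100 * G / (G + H); 0 when the species has no records."""
    total = counts.g_records + counts.h_records
    if total == 0:
        return 0.0
    return 100.0 * counts.g_records / total


def grs_ex(
    g_buffer: RasterLayer, distribution: RasterLayer, areas: CellAreaModel
) -> float:
    """Area share of the distribution covered by the G-record buffer."""
    _check_grids(g_buffer, distribution)
    dist = distribution.values == 1
    denom = areas.area_of(dist)
    if denom == 0:
        return 0.0
    num = areas.area_of(dist & (g_buffer.values == 1))
    return min(100.0, 100.0 * num / denom)


def ers_ex(
    g_buffer: RasterLayer, distribution: RasterLayer, ecoregions: CategoricalRaster
) -> float:
    """Share of the distribution's ecoregions touched by the G buffer."""
    _check_grids(g_buffer, distribution)
    if ecoregions.grid != distribution.grid:
        raise ValueError("ecoregion raster not aligned with distribution")
    dist = distribution.values == 1
    eco_dist = ecoregions.categories_present(dist)
    if not eco_dist:
        return 0.0
    eco_buf = ecoregions.categories_present(dist & (g_buffer.values == 1))
    return min(100.0, 100.0 * len(eco_buf & eco_dist) / len(eco_dist))


def insitu_scores(
    distribution: RasterLayer,
    pa: RasterLayer,
    ecoregions: CategoricalRaster,
    occurrences: list[OccurrenceRecord],
    areas: CellAreaModel,
) -> tuple[float, float, float]:
    """(srs_in, grs_in, ers_in) against the protected-area layer.

    srs_in is the share of georeferenced occurrences falling in protected
    cells; grs_in and ers_in mirror the ex situ formulas with the
    protected part of the distribution as the numerator.
    """
    _check_grids(pa, distribution)
    if ecoregions.grid != distribution.grid:
        raise ValueError("ecoregion raster not aligned with distribution")
    dist = distribution.values == 1
    protected = dist & (pa.values == 1)

    denom_area = areas.area_of(dist)
    grs = 0.0 if denom_area == 0 else min(100.0, 100.0 * areas.area_of(protected) / denom_area)

    eco_dist = ecoregions.categories_present(dist)
    if not eco_dist:
        ers = 0.0
    else:
        eco_pa = ecoregions.categories_present(protected)
        ers = min(100.0, 100.0 * len(eco_pa & eco_dist) / len(eco_dist))

    geo = [r for r in occurrences if r.has_coords]
    if not geo:
        srs = 0.0
    else:
        in_pa = 0
        for rec in geo:
            try:
                r, c = cell_index(pa.grid, rec.lon, rec.lat)
            except IndexError:
                continue
            if pa.values[r, c] == 1:
                in_pa += 1
        srs = 100.0 * in_pa / len(geo)
    return srs, grs, ers


def categorize(fcs_combined: float) -> str:
    """Priority category from the combined score (25/50/75 cuts)."""
    for cut, label in zip(CATEGORY_THRESHOLDS, CATEGORY_LABELS):
        if fcs_combined < cut:
            return label
    return CATEGORY_LABELS[-1]


def combine_and_categorize(
    species_id: str,
    ex_components: tuple[float, float, float],
    in_components: tuple[float, float, float],
) -> ConservationScores:
    """Assemble the full score record from the six components."""
    for v in (*ex_components, *in_components):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"component score {v} outside [0, 100]")
    fcs_ex = float(np.mean(ex_components))
    fcs_in = float(np.mean(in_components))
    fcs_combined = float(np.mean([fcs_ex, fcs_in]))
    return ConservationScores(
        species_id=species_id,
        srs_ex=ex_components[0],
        grs_ex=ex_components[1],
        ers_ex=ex_components[2],
        srs_in=in_components[0],
        grs_in=in_components[1],
        ers_in=in_components[2],
        fcs_ex=fcs_ex,
        fcs_in=fcs_in,
        fcs_combined=fcs_combined,
        category=categorize(fcs_combined),
    )


def _check_grids(a: RasterLayer, b: RasterLayer) -> None:
    if a.grid != b.grid:
        raise ValueError("rasters are not on the same grid")
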