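"""Occurrence-record ingestion, G/H classification, scrubbing, summaries.

Records are G (germplasm accession from a living ex situ repository) or H
(reference record: herbarium sheet, observation, etc.). Scrubbing removes
records in water, outside the species' native range, or collected before
1950; records without coordinates survive scrubbing (they still count for
sampling scores) but are excluded from modeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .core_grid import GridSpec, Polygon, RasterLayer, cell_index, point_in_polygon

logger = logging.getLogger(__name__)

#: GBIF basis-of-record values mapped to H (everything except living specimen)
GBIF_H_CATEGORIES = frozenset(
    {
        "observation",
        "literature",
        "preserved specimen",
        "human observation",
        "machine observation",
        "material sample",
        "unknown",
        "",
    }
)

YEAR_MIN_DEFAULT = 1950

#: primary rejection reason precedence (first violated wins)
REASON_OFF_GRID = "off-grid"
REASON_WATER = "water"
REASON_NON_NATIVE = "non-native"
REASON_TOO_OLD = "too-old"


@dataclass(frozen=True)
class OccurrenceRecord:
    species_id: str
    lon: float | None = None
    lat: float | None = None
    iso3: str | None = None
    year: int | None = None
    record_type: str = "H"
    native_status: str = "N"

    def __post_init__(self):
        if self.record_type not in ("G", "H"):
            raise ValueError(f"record_type must be G or H, got {self.record_type!r}")
        if self.native_status not in ("N", "I"):
            raise ValueError(f"native_status must be N or I, got {self.native_status!r}")
        if (self.lon is None) != (self.lat is None):
            raise ValueError("lon and lat must be both present or both absent")
        if self.lon is not None:
            if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
                raise ValueError(f"coordinates ({self.lon}, {self.lat}) out of range")

    @property
    def has_coords(self) -> bool:
        return self.lon is not None


@dataclass(frozen=True)
class CountsSummary:
    species_id: str
    total_records: int = 0
    total_with_coords: int = 0
    g_records: int = 0
    g_with_coords: int = 0
    h_records: int = 0
    h_with_coords: int = 0


def classify_record_type(basis_of_record: str, source: str) -> str:
    """Map a record's basis-of-record and source database to G or H."""
    if source == "genesys":
        return "G"
    if source == "cwr":
        label = basis_of_record.strip().upper()
        if label not in ("G", "H"):
            raise ValueError(f"cwr records carry a pre-assigned G/H label, got {basis_of_record!r}")
        return label
    if source == "gbif":
        basis = " ".join(basis_of_record.strip().lower().split())
        if basis == "living specimen":
            return "G"
        if basis not in GBIF_H_CATEGORIES:
            logger.warning("unrecognized gbif basis of record %r; treating as unknown (H)", basis_of_record)
        return "H"
    raise ValueError(f"unknown source {source!r}")


def scrub(
    records: Sequence[OccurrenceRecord],
    land_mask: RasterLayer,
    native_countries: set[str],
    year_min: int = YEAR_MIN_DEFAULT,
    admin_polygons: Sequence[Polygon] | None = None,
) -> tuple[list[OccurrenceRecord], list[tuple[OccurrenceRecord, str]]]:
    """Split records into (kept, rejected-with-reason).

    A record is kept iff (it has no coordinates OR its cell is land) AND
    its country is native AND (year absent OR year >= year_min). Each
    rejected record carries one primary reason, in fixed precedence
    off-grid > water > non-native > too-old. The country of a record
    lacking an iso3 code is resolved by point-in-polygon against
    ``admin_polygons`` (features attributed with ``iso3``); if it cannot
    be resolved the native-range test is not applied.
    """
    if land_mask.semantics != "binary":
        raise ValueError("land_mask must be a binary layer")
    kept: list[OccurrenceRecord] = []
    rejected: list[tuple[OccurrenceRecord, str]] = []
    for rec in records:
        reason = _primary_violation(rec, land_mask, native_countries, year_min, admin_polygons)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return kept, rejected


def _primary_violation(rec, land_mask, native_countries, year_min, admin_polygons):
    iso3 = rec.iso3
    if rec.has_coords:
        try:
            r, c = cell_index(land_mask.grid, rec.lon, rec.lat)
        except IndexError:
            return REASON_OFF_GRID
        if land_mask.values[r, c] != 1:
            return REASON_WATER
        if iso3 is None and admin_polygons is not None:
            iso3 = _country_of_point(rec.lon, rec.lat, admin_polygons)
    if iso3 is not None and iso3 not in native_countries:
        return REASON_NON_NATIVE
    if rec.year is not None and rec.year < year_min:
        return REASON_TOO_OLD
    return None


def _country_of_point(lon, lat, admin_polygons) -> str | None:
    for poly in admin_polygons:
        if point_in_polygon(lon, lat, poly):
            return poly.attrs.get("iso3")
    return None


def summarize(records: Sequence[OccurrenceRecord]) -> CountsSummary:
    """Per-species record counts (total / G / H, with and without coords)."""
    species_ids = {r.species_id for r in records}
    if len(species_ids) > 1:
        raise ValueError(f"records span multiple species: {sorted(species_ids)}")
    sid = species_ids.pop() if species_ids else ""
    g = [r for r in records if r.record_type == "G"]
    h = [r for r in records if r.record_type == "H"]
    return CountsSummary(
        species_id=sid,
        total_records=len(records),
        total_with_coords=sum(r.has_coords for r in records),
        g_records=len(g),
        g_with_coords=sum(r.has_coords for r in g),
        h_records=len(h),
        h_with_coords=sum(r.has_coords for r in h),
    )


# ---------------------------------------------------------------------------
# CSV I/O (one file per species; columns per the occurrence data contract)
# ---------------------------------------------------------------------------

OCCURRENCE_COLUMNS = ["species_id", "lon", "lat", "iso3", "year", "record_type", "native_status"]


def records_to_frame(records: Iterable[OccurrenceRecord]) -> pd.DataFrame:
    rows = [
        {
            "species_id": r.species_id,
            "lon": r.lon,
            "lat": r.lat,
            "iso3": r.iso3,
            "year": r.year,
            "record_type": r.record_type,
            "native_status": r.native_status,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[OccurrenceRecord]:
    records = []
    for row in df.itertuples(index=False):
        lon = None if pd.isna(row.lon) else float(row.lon)
        lat = None if pd.isna(row.lat) else float(row.lat)
        iso3 = None if (pd.isna(row.iso3) or row.iso3 == "") else str(row.iso3).upper()
        year = None if pd.isna(row.year) else int(row.year)
        records.append(
            OccurrenceRecord(
                species_id=str(row.species_id),
                lon=lon,
                lat=lat,
                iso3=iso3,
                year=year,
                record_type=str(row.record_type),
                native_status=str(row.native_status),
            )
        )
    return records


def write_occurrences_csv(records: Iterable[OccurrenceRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_occurrences_csv(path) -> list[OccurrenceRecord]:
    return frame_to_records(pd.read_csv(path))


def counts_to_frame(summaries: Iterable[CountsSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
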