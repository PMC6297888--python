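"""Synthetic world generator with recorded ground truth.

Emits every input contract of the pipeline at desk scale: species/use/
country tables, per-species occurrence CSVs with planted violations,
a 26-layer predictor stack, a land mask with ocean cells, cell-aligned
rectangular country / ecoregion / protected-area polygon layers, and an
M49-style classification table. Countries are vertical strips of the
land area, ecoregions horizontal bands, the protected area a southern
block — so every membership and area has a closed form.

Everything is driven by one seed; the same seed reproduces the world
byte-for-byte.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_grid import (
    GridSpec,
    Polygon,
    RasterLayer,
    cell_center,
    rect_polygon,
    write_ascii_grid,
    write_geojson,
)
from .occurrences import OccurrenceRecord, write_occurrences_csv
from .predictors import (
    LAYER_NAME_TEMPLATE,
    N_BIOCLIM,
    PredictorStack,
    assemble_stack,
)
from .rasterize import CATEGORY_ATTR, CategoricalRaster
from .taxa import SpeciesEntry

USE_VOCAB = ("food", "medicine", "forage", "fiber", "timber", "environmental")
EXCLUDED_VOCAB = ("weed", "poisonous", "ornamental", "potential_genetic_resource_only")

#: iso3-style code guaranteed not to be any synthetic country
FOREIGN_ISO3 = "ZZZ"


@dataclass
class NicheSpec:
    predictor: str
    optimum: float
    breadth: float


@dataclass
class WorldConfig:
    n_rows: int = 60
    n_cols: int = 60
    cell_size_deg: float = 0.5
    origin_lon: float = -15.0
    origin_lat: float = 15.0
    ocean_cols: int = 6
    n_countries: int = 4
    n_ecoregions: int = 5
    pa_fraction: float = 0.25
    n_species: int = 6
    n_g: int = 20
    n_h: int = 40
    n_no_coords: int = 0
    n_water: int = 0
    n_pre1950: int = 0
    n_non_native: int = 0
    n_excluded_use_species: int = 1
    n_cultivated_species: int = 1
    niches: list[NicheSpec] | None = None
    #: "smooth" fields share broad spatial trends (realistic collinearity);
    #: "independent" draws non-planted layers as iid noise, making
    #: single-variable niches identifiable for parameter-recovery checks
    predictor_style: str = "smooth"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.pa_fraction <= 1.0):
            raise ValueError("pa_fraction must be in [0, 1]")
        for name in ("n_g", "n_h", "n_no_coords", "n_water", "n_pre1950", "n_non_native"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ocean_cols >= self.n_cols:
            raise ValueError("ocean covers the whole grid")
        if self.n_countries > self.n_cols - self.ocean_cols:
            raise ValueError("more countries than land columns")
        if self.n_ecoregions > self.n_rows:
            raise ValueError("more ecoregions than rows")
        if self.n_water + self.n_pre1950 + self.n_non_native > self.n_g + self.n_h:
            raise ValueError("more planted violations than records")


@dataclass
class SpeciesTruth:
    niche: NicheSpec
    native_countries: set[str]
    n_total: int
    expected_kept: int
    expected_rejections: dict[str, int]
    selected: bool


@dataclass
class GroundTruth:
    species: dict[str, SpeciesTruth] = field(default_factory=dict)
    country_codes: list[str] = field(default_factory=list)
    ecoregion_ids: list[int] = field(default_factory=list)
    pa_land_fraction: float = 0.0


@dataclass
class World:
    config: WorldConfig
    grid: GridSpec
    land_mask: RasterLayer
    stack: PredictorStack
    country_polys: list[Polygon]
    country_of_cell: np.ndarray  # index into country_codes, -1 for ocean
    ecoregion_polys: list[Polygon]
    ecoregions: CategoricalRaster
    pa_polys: list[Polygon]
    pa_raster: RasterLayer
    entries: list[SpeciesEntry]
    occurrences: dict[str, list[OccurrenceRecord]]
    m49_table: pd.DataFrame
    truth: GroundTruth


def _country_codes(n: int) -> list[str]:
    letters = string.ascii_uppercase
    codes = ["".join(t) for t in itertools.product(letters, repeat=3)]
    picked = [c for c in codes if c != FOREIGN_ISO3][:n]
    return picked


def _smooth_field(grid: GridSpec, rng: np.random.Generator, base: float, amp: float) -> np.ndarray:
    """Deterministic smooth surface: low-order trend + sinusoids."""
    lat = grid.row_center_lats()[:, None]
    lon = grid.col_center_lons()[None, :]
    latn = (lat - lat.mean()) / max(1e-9, float(np.ptp(lat)) / 2)
    lonn = (lon - lon.mean()) / max(1e-9, float(np.ptp(lon)) / 2)
    a = rng.uniform(-1, 1, size=6)
    f = rng.uniform(0.5, 2.0, size=2)
    p = rng.uniform(0, 2 * np.pi, size=2)
    surf = (
        a[0] * latn
        + a[1] * lonn
        + a[2] * latn * lonn
        + a[3] * np.sin(f[0] * np.pi * latn + p[0])
        + a[4] * np.cos(f[1] * np.pi * lonn + p[1])
        + a[5] * 0.2 * np.sin(2 * np.pi * (latn + lonn))
    )
    return base + amp * surf


def _build_stack(
    grid: GridSpec, rng: np.random.Generator, style: str = "smooth"
) -> PredictorStack:
    lat = grid.row_center_lats()[:, None]
    bio1 = 28.0 - 0.6 * np.abs(lat) + np.zeros(grid.shape)  # latitudinal gradient
    bioclim = [RasterLayer(grid, bio1, "continuous")]
    for _ in range(N_BIOCLIM - 1):
        if style == "independent":
            field_vals = rng.normal(100.0, 40.0, size=grid.shape)
        else:
            field_vals = _smooth_field(grid, rng, 100.0, 40.0)
        bioclim.append(RasterLayer(grid, field_vals, "continuous"))
    def aux_field(base, amp):
        if style == "independent":
            return rng.normal(base, amp / 2, size=grid.shape)
        return _smooth_field(grid, rng, base, amp)

    solar = RasterLayer(grid, aux_field(15000.0, 3000.0), "continuous")
    wind = RasterLayer(grid, aux_field(4.0, 1.5), "continuous")
    vapor = RasterLayer(grid, aux_field(1.8, 0.5), "continuous")
    lon = grid.col_center_lons()[None, :]
    altitude = RasterLayer(
        grid,
        500.0 + 8.0 * lon + 200.0 * np.sin(lon / 4.0) + 3.0 * lat + np.zeros(grid.shape),
        "continuous",
    )
    return assemble_stack(bioclim, solar, wind, vapor, altitude)


def generate_world(config: WorldConfig, out_dir: str | Path | None = None) -> World:
    """Build the synthetic world; optionally write all file artifacts."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    grid = GridSpec(
        cell_size_deg=cfg.cell_size_deg,
        origin_lon=cfg.origin_lon,
        origin_lat=cfg.origin_lat,
        n_rows=cfg.n_rows,
        n_cols=cfg.n_cols,
    )
    size = cfg.cell_size_deg

    # land mask: ocean strip on the west
    mask_vals = np.ones(grid.shape)
    mask_vals[:, : cfg.ocean_cols] = 0.0
    land_mask = RasterLayer(grid, mask_vals, "binary")

    # countries: vertical strips of land columns, cell-edge aligned
    codes = _country_codes(cfg.n_countries)
    land_cols = cfg.n_cols - cfg.ocean_cols
    bounds_cols = np.linspace(cfg.ocean_cols, cfg.n_cols, cfg.n_countries + 1).round().astype(int)
    country_polys = []
    country_of_cell = np.full(grid.shape, -1, dtype=int)
    south = cfg.origin_lat - cfg.n_rows * size
    for i, code in enumerate(codes):
        west = cfg.origin_lon + bounds_cols[i] * size
        east = cfg.origin_lon + bounds_cols[i + 1] * size
        country_polys.append(rect_polygon(west, south, east, cfg.origin_lat, iso3=code))
        country_of_cell[:, bounds_cols[i] : bounds_cols[i + 1]] = i

    # ecoregions: horizontal bands over the full grid, ids 1..n
    bounds_rows = np.linspace(0, cfg.n_rows, cfg.n_ecoregions + 1).round().astype(int)
    ecoregion_polys = []
    eco_vals = np.zeros(grid.shape, dtype=int)
    for i in range(cfg.n_ecoregions):
        north = cfg.origin_lat - bounds_rows[i] * size
        south_i = cfg.origin_lat - bounds_rows[i + 1] * size
        east = cfg.origin_lon + cfg.n_cols * size
        ecoregion_polys.append(
            rect_polygon(cfg.origin_lon, south_i, east, north, **{CATEGORY_ATTR: i + 1})
        )
        eco_vals[bounds_rows[i] : bounds_rows[i + 1], :] = i + 1
    ecoregions = CategoricalRaster(grid, eco_vals)

    # protected area: southern block of land rows sized to pa_fraction
    pa_rows = int(round(cfg.pa_fraction * cfg.n_rows))
    pa_vals = np.zeros(grid.shape)
    pa_polys: list[Polygon] = []
    if pa_rows > 0:
        r0 = cfg.n_rows - pa_rows
        north = cfg.origin_lat - r0 * size
        west = cfg.origin_lon + cfg.ocean_cols * size
        east = cfg.origin_lon + cfg.n_cols * size
        pa_polys.append(
            rect_polygon(
                west, south, east, north,
                status="Designated", designation_domain="terrestrial",
                **{CATEGORY_ATTR: 1},
            )
        )
        pa_vals[r0:, cfg.ocean_cols :] = 1.0
    pa_raster = RasterLayer(grid, pa_vals, "binary")

    stack = _build_stack(grid, rng, style=cfg.predictor_style)

    # species table with planted selection labels
    truth = GroundTruth(
        country_codes=codes,
        ecoregion_ids=list(range(1, cfg.n_ecoregions + 1)),
        pa_land_fraction=float(pa_vals[mask_vals == 1].mean()) if (mask_vals == 1).any() else 0.0,
    )
    entries: list[SpeciesEntry] = []
    occurrences: dict[str, list[OccurrenceRecord]] = {}
    niche_field = stack.layer(LAYER_NAME_TEMPLATE.format(1)).values

    for s in range(cfg.n_species):
        sid = f"SP{s + 1:04d}"
        excluded_only = s < cfg.n_excluded_use_species
        cultivated = (not excluded_only) and s < cfg.n_excluded_use_species + cfg.n_cultivated_species
        if excluded_only:
            uses = set(rng.choice(EXCLUDED_VOCAB, size=2, replace=False))
        else:
            uses = set(rng.choice(USE_VOCAB, size=int(rng.integers(1, 3)), replace=False))
            if rng.random() < 0.3:
                uses.add(str(rng.choice(EXCLUDED_VOCAB)))
        n_native = int(rng.integers(1, cfg.n_countries + 1))
        native = set(rng.choice(codes, size=n_native, replace=False).tolist())
        introduced = set(rng.choice(codes, size=1).tolist()) - native

        if cfg.niches is not None:
            niche = cfg.niches[s % len(cfg.niches)]
        else:
            vals = niche_field[mask_vals == 1]
            niche = NicheSpec(
                predictor=LAYER_NAME_TEMPLATE.format(1),
                optimum=float(rng.uniform(vals.min(), vals.max())),
                breadth=float((vals.max() - vals.min()) / 6.0),
            )

        entry = SpeciesEntry(
            species_id=sid,
            name=f"Synthetica species{s + 1}",
            author=f"Auth. {s + 1}",
            uses=uses,
            native_countries=native,
            introduced_countries=introduced,
            strictly_cultivated=cultivated,
        )
        entries.append(entry)

        recs, rejections = _sample_records(
            sid, niche, stack, land_mask, country_of_cell, codes, native, cfg, rng
        )
        occurrences[sid] = recs
        n_total = len(recs)
        truth.species[sid] = SpeciesTruth(
            niche=niche,
            native_countries=native,
            n_total=n_total,
            expected_kept=n_total - sum(rejections.values()),
            expected_rejections=rejections,
            selected=bool(uses - set(EXCLUDED_VOCAB)) and not cultivated,
        )

    m49 = _m49_table(codes)

    world = World(
        config=cfg,
        grid=grid,
        land_mask=land_mask,
        stack=stack,
        country_polys=country_polys,
        country_of_cell=country_of_cell,
        ecoregion_polys=ecoregion_polys,
        ecoregions=ecoregions,
        pa_polys=pa_polys,
        pa_raster=pa_raster,
        entries=entries,
        occurrences=occurrences,
        m49_table=m49,
        truth=truth,
    )
    if out_dir is not None:
        write_world(world, Path(out_dir))
    return world


def sample_species_occurrences(
    niche: NicheSpec,
    stack: PredictorStack,
    mask: RasterLayer,
    n_g: int,
    n_h: int,
    seed: int,
    allowed: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Draw ``n_g + n_h`` cells with probability proportional to a Gaussian
    response of the niche predictor over mask=1 cells (optionally further
    restricted by the boolean ``allowed`` array). Returns (row, col) pairs;
    the first ``n_g`` are the germplasm (G) draws."""
    eligible = mask.values == 1
    if allowed is not None:
        eligible = eligible & allowed
    rows, cols = np.nonzero(eligible)
    if len(rows) == 0:
        raise ValueError("no eligible land cells to sample occurrences from")
    vals = stack.layer(niche.predictor).values[rows, cols]
    w = np.exp(-((vals - niche.optimum) ** 2) / (2.0 * niche.breadth**2))
    if w.sum() == 0:
        w = np.ones_like(w)
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n_g + n_h, replace=True, p=p)
    return [(int(rows[i]), int(cols[i])) for i in idx]


def _sample_records(sid, niche, stack, land_mask, country_of_cell, codes, native, cfg, rng):
    native_idx = {codes.index(c) for c in native}
    allowed = np.isin(country_of_cell, list(native_idx))
    n_geo = cfg.n_g + cfg.n_h
    cells = sample_species_occurrences(
        niche, stack, land_mask, cfg.n_g, cfg.n_h,
        seed=int(rng.integers(0, 2**31)), allowed=allowed,
    )
    grid = land_mask.grid
    recs: list[OccurrenceRecord] = []
    for j, (r, c) in enumerate(cells):
        lon, lat = cell_center(grid, r, c)
        jit = rng.uniform(-0.4, 0.4, size=2) * grid.cell_size_deg
        year = int(rng.integers(1960, 2016)) if rng.random() > 0.1 else None
        recs.append(
            OccurrenceRecord(
                species_id=sid,
                lon=lon + jit[0],
                lat=lat + jit[1],
                iso3=codes[country_of_cell[r, c]],
                year=year,
                record_type="G" if j < cfg.n_g else "H",
                native_status="N",
            )
        )

    # planted violations on disjoint suffix slices; each trips exactly one rule
    rejections = {"water": 0, "non-native": 0, "too-old": 0}
    ocean_cells = np.argwhere(land_mask.values == 0)
    pos = n_geo
    for _ in range(cfg.n_water):
        pos -= 1
        r, c = ocean_cells[rng.integers(0, len(ocean_cells))]
        lon, lat = cell_center(grid, int(r), int(c))
        old = recs[pos]
        recs[pos] = OccurrenceRecord(
            sid, lon, lat, old.iso3, old.year if old.year else 1990, old.record_type, "N"
        )
        rejections["water"] += 1
    for _ in range(cfg.n_non_native):
        pos -= 1
        old = recs[pos]
        recs[pos] = OccurrenceRecord(
            sid, old.lon, old.lat, FOREIGN_ISO3, old.year if old.year else 1990,
            old.record_type, "I",
        )
        rejections["non-native"] += 1
    for _ in range(cfg.n_pre1950):
        pos -= 1
        old = recs[pos]
        recs[pos] = OccurrenceRecord(
            sid, old.lon, old.lat, old.iso3, int(rng.integers(1900, 1950)),
            old.record_type, "N",
        )
        rejections["too-old"] += 1

    # coordinate-free records (survive scrubbing, excluded from modeling)
    for _ in range(cfg.n_no_coords):
        recs.append(
            OccurrenceRecord(sid, None, None, sorted(native)[0], 2000, "H", "N")
        )
    return recs, rejections


def _m49_table(codes: list[str]) -> pd.DataFrame:
    rows = []
    n = len(codes)
    for i, code in enumerate(codes):
        region = "RegionWest" if i < (n + 1) // 2 else "RegionEast"
        sub = f"Sub{(i // 2) + 1:02d}"
        rows.append(
            {"iso3": code, "country_name": f"Country {code}", "sub_region": sub, "region": region}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File emission (the exact layouts the CLIs consume)
# ---------------------------------------------------------------------------

def write_world(world: World, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    names = pd.DataFrame(
        [
            {
                "species_id": e.species_id,
                "name": e.name,
                "author": e.author,
                "strictly_cultivated": e.strictly_cultivated,
            }
            for e in world.entries
        ]
    )
    names.to_csv(out_dir / "names.csv", index=False)
    uses = pd.DataFrame(
        [
            {"species_id": e.species_id, "use_category": u}
            for e in world.entries
            for u in sorted(e.uses)
        ]
    )
    uses.to_csv(out_dir / "uses.csv", index=False)
    dist_rows = []
    for e in world.entries:
        dist_rows += [
            {"species_id": e.species_id, "iso3": c, "status": "N"}
            for c in sorted(e.native_countries)
        ]
        dist_rows += [
            {"species_id": e.species_id, "iso3": c, "status": "I"}
            for c in sorted(e.introduced_countries)
        ]
    pd.DataFrame(dist_rows).to_csv(out_dir / "distributions.csv", index=False)

    occ_dir = out_dir / "occurrences"
    occ_dir.mkdir(exist_ok=True)
    for sid, recs in world.occurrences.items():
        write_occurrences_csv(recs, occ_dir / f"{sid}.csv")

    pred_dir = out_dir / "predictors"
    pred_dir.mkdir(exist_ok=True)
    for name, layer, _tag in world.stack.layers:
        write_ascii_grid(layer, pred_dir / f"{name}.asc")
    write_ascii_grid(world.land_mask, out_dir / "mask.asc")

    write_geojson(world.country_polys, out_dir / "countries.geojson")
    write_geojson(world.ecoregion_polys, out_dir / "ecoregions.geojson")
    write_geojson(world.pa_polys, out_dir / "protected_areas.geojson")
    world.m49_table.to_csv(out_dir / "m49.csv", index=False)
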