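"""End-to-end orchestration: taxa selection -> scrub -> SDM -> scores ->
indicator. Operates on in-memory worlds (synthetic or loaded from the
file contracts) and is fully deterministic for a fixed seed."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import conservation, indicator, occurrences, sdm, taxa
from .conservation import CellAreaModel, ConservationScores
from .core_grid import RasterLayer
from .rasterize import CategoricalRaster
from .synthgen import World


@dataclass
class PipelineConfig:
    seed: int = 0
    n_background: int = 1000
    k_folds: int = 5
    regularization: float = 1.0


def score_species(
    species_id: str,
    records: list[occurrences.OccurrenceRecord],
    native_countries: set[str],
    land_mask: RasterLayer,
    stack,
    pa: RasterLayer,
    ecoregions: CategoricalRaster,
    config: PipelineConfig,
) -> tuple[ConservationScores, sdm.SDMOutput | None]:
    """Scrub one species' records and compute its nine scores."""
    kept, _rejected = occurrences.scrub(records, land_mask, native_countries)
    counts = occurrences.summarize(kept)
    geo = [(r.lon, r.lat) for r in kept if r.has_coords]
    g_geo = [(r.lon, r.lat) for r in kept if r.has_coords and r.record_type == "G"]

    areas = CellAreaModel(land_mask.grid)
    srs = conservation.srs_ex(counts)

    if not geo:
        zeros = conservation.combine_and_categorize(species_id, (srs, 0.0, 0.0), (0.0, 0.0, 0.0))
        return zeros, None

    output = sdm.run_species_sdm(
        species_id,
        geo,
        stack,
        land_mask,
        seed=config.seed,
        n_background=config.n_background,
        k=config.k_folds,
        reg=config.regularization,
    )
    distribution = output.presence

    if g_geo:
        g_buffer = sdm.ca50(g_geo, land_mask.grid, land_mask)
    else:
        g_buffer = RasterLayer(
            land_mask.grid, np.zeros(land_mask.grid.shape), "binary"
        )

    grs = conservation.grs_ex(g_buffer, distribution, areas)
    ers = conservation.ers_ex(g_buffer, distribution, ecoregions)
    srs_in, grs_in, ers_in = conservation.insitu_scores(
        distribution, pa, ecoregions, kept, areas
    )
    scores = conservation.combine_and_categorize(
        species_id, (srs, grs, ers), (srs_in, grs_in, ers_in)
    )
    return scores, output


def run_full(world: World, config: PipelineConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the whole pipeline on a world; returns (scores, indicator) frames."""
    config = config or PipelineConfig()
    selected = taxa.select_useful_wild(world.entries)

    all_scores: list[ConservationScores] = []
    for entry in selected:
        scores, _out = score_species(
            entry.species_id,
            world.occurrences[entry.species_id],
            entry.native_countries,
            world.land_mask,
            world.stack,
            world.pa_raster,
            world.ecoregions,
            config,
        )
        all_scores.append(scores)

    scores_df = pd.DataFrame([s.__dict__ for s in all_scores])
    scopes = indicator.load_m49(world.m49_table)
    indicator_df = indicator.compute_indicator(selected, all_scores, scopes)
    return scores_df, indicator_df
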