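"""Species/use/country tables and selection of useful wild species.

Input tables are long-format CSVs keyed by ``species_id``: a names table
(one row per species), a uses table (one row per species x use category)
and a distributions table (one row per species x country x status).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

_ISO3_RE = re.compile(r"^[A-Za-z]{3}$")

#: use categories excluded from the indicator by default
DEFAULT_EXCLUDED_USES = frozenset(
    {"weed", "poisonous", "ornamental", "potential_genetic_resource_only"}
)


@dataclass
class SpeciesEntry:
    species_id: str
    name: str = ""
    author: str = ""
    uses: set[str] = field(default_factory=set)
    native_countries: set[str] = field(default_factory=set)
    introduced_countries: set[str] = field(default_factory=set)
    strictly_cultivated: bool = False
    standardized_name: str | None = None
    name_standardization_flag: str = ""

    @property
    def resolved_name(self) -> str:
        return self.standardized_name or self.name


@dataclass
class SelectionConfig:
    excluded_use_categories: frozenset[str] = DEFAULT_EXCLUDED_USES
    exclude_strictly_cultivated: bool = True


def load_wep_tables(
    names_table: pd.DataFrame,
    uses_table: pd.DataFrame,
    distributions_table: pd.DataFrame,
) -> list[SpeciesEntry]:
    """Join the three long-format tables into one entry per species.

    Row multiplicity collapses into sets. Species ids present only in the
    uses or distributions table are reported as orphans (warning) and
    dropped; rows with malformed ISO3 codes are rejected with a log entry.
    """
    entries: dict[str, SpeciesEntry] = {}
    for row in names_table.itertuples(index=False):
        sid = str(row.species_id)
        if sid in entries:
            raise ValueError(f"duplicate species_id {sid!r} in names table")
        entries[sid] = SpeciesEntry(
            species_id=sid,
            name=str(getattr(row, "name", "")),
            author=str(getattr(row, "author", "") or ""),
            strictly_cultivated=_as_bool(getattr(row, "strictly_cultivated", False)),
        )

    orphans: set[str] = set()
    for row in uses_table.itertuples(index=False):
        sid = str(row.species_id)
        entry = entries.get(sid)
        if entry is None:
            orphans.add(sid)
            continue
        use = str(row.use_category).strip()
        if use:
            entry.uses.add(use)

    for row in distributions_table.itertuples(index=False):
        sid = str(row.species_id)
        entry = entries.get(sid)
        if entry is None:
            orphans.add(sid)
            continue
        iso3 = str(row.iso3).strip().upper()
        if not _ISO3_RE.match(iso3):
            logger.warning("rejecting distribution row for %s: bad iso3 %r", sid, row.iso3)
            continue
        status = str(getattr(row, "status", "N")).strip().upper() or "N"
        if status == "I":
            entry.introduced_countries.add(iso3)
        else:
            entry.native_countries.add(iso3)

    if orphans:
        logger.warning(
            "%d species_id(s) in uses/distributions absent from names table: %s",
            len(orphans),
            sorted(orphans),
        )
    return list(entries.values())


def load_wep_csvs(names_csv, uses_csv, distributions_csv) -> list[SpeciesEntry]:
    return load_wep_tables(
        pd.read_csv(names_csv, dtype=str).fillna(""),
        pd.read_csv(uses_csv, dtype=str).fillna(""),
        pd.read_csv(distributions_csv, dtype=str).fillna(""),
    )


def select_useful_wild(
    entries: list[SpeciesEntry], config: SelectionConfig | None = None
) -> list[SpeciesEntry]:
    """Keep species with at least one non-excluded use that are not
    strictly cultivated. Order-preserving and idempotent."""
    config = config or SelectionConfig()
    selected = []
    for entry in entries:
        if config.exclude_strictly_cultivated and entry.strictly_cultivated:
            continue
        if entry.uses - set(config.excluded_use_categories):
            selected.append(entry)
    return selected


def apply_name_standardization(
    entries: list[SpeciesEntry], mapping_table: dict[str, str] | pd.DataFrame
) -> list[SpeciesEntry]:
    """Fill ``standardized_name`` from a precomputed raw->accepted mapping.

    Unmapped names keep the raw name and are flagged. Synonyms mapping to
    one accepted name are merged into a single entry (union of uses and
    country sets), keeping the first entry's species_id.
    """
    if isinstance(mapping_table, pd.DataFrame):
        mapping = dict(
            zip(mapping_table["raw_name"].astype(str), mapping_table["standardized_name"].astype(str))
        )
    else:
        mapping = dict(mapping_table)

    by_std: dict[str, SpeciesEntry] = {}
    out: list[SpeciesEntry] = []
    for entry in entries:
        std = mapping.get(entry.name)
        if std is None:
            entry.standardized_name = None
            entry.name_standardization_flag = "unmapped"
            out.append(entry)
            continue
        entry.standardized_name = std
        entry.name_standardization_flag = "mapped"
        prior = by_std.get(std)
        if prior is None:
            by_std[std] = entry
            out.append(entry)
        else:
            logger.info(
                "merging %s into %s (both standardize to %r)",
                entry.species_id,
                prior.species_id,
                std,
            )
            prior.uses |= entry.uses
            prior.native_countries |= entry.native_countries
            prior.introduced_countries |= entry.introduced_countries
    return out


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("1", "true", "t", "yes", "y")
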