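"""Aggregation of species scores to country / sub-region / region / global
indicator values using native-range membership and M49-style scopes."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .conservation import CATEGORY_LABELS, ConservationScores
from .taxa import SpeciesEntry

GLOBAL_SCOPE_ID = "global"

LEVELS = ("country", "sub_region", "region", "global")


@dataclass
class ScopeDefinition:
    scope_id: str
    level: str
    member_countries: set[str]

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown scope level {self.level!r}")


@dataclass
class IndicatorResult:
    scope_id: str
    level: str
    n_species: int
    mean_fcs_ex: float | None
    mean_fcs_in: float | None
    mean_fcs_combined: float | None
    category_counts: dict[str, int] = field(default_factory=dict)
    n_missing_scores: int = 0


def species_for_scope(
    entries: list[SpeciesEntry], scope: ScopeDefinition, known_countries: set[str] | None = None
) -> set[str]:
    """Species whose native countries intersect the scope's members."""
    if known_countries is not None:
        unknown = scope.member_countries - known_countries
        if unknown:
            raise ValueError(f"scope {scope.scope_id} has unknown countries: {sorted(unknown)}")
    return {
        e.species_id for e in entries if e.native_countries & scope.member_countries
    }


def aggregate(
    scores: list[ConservationScores], scope_species: set[str], scope: ScopeDefinition
) -> IndicatorResult:
    """Unweighted means of the FCS values over the scope's species.

    Scope species without a score row are counted as missing and excluded
    from the means. An empty scope yields undefined (None) means.
    """
    by_id = {s.species_id: s for s in scores}
    present = [by_id[sid] for sid in sorted(scope_species) if sid in by_id]
    missing = len(scope_species) - len(present)

    counts = {label: 0 for label in CATEGORY_LABELS}
    for s in present:
        counts[s.category] += 1

    if present:
        mean_ex = sum(s.fcs_ex for s in present) / len(present)
        mean_in = sum(s.fcs_in for s in present) / len(present)
        mean_comb = sum(s.fcs_combined for s in present) / len(present)
    else:
        mean_ex = mean_in = mean_comb = None
    return IndicatorResult(
        scope_id=scope.scope_id,
        level=scope.level,
        n_species=len(present),
        mean_fcs_ex=mean_ex,
        mean_fcs_in=mean_in,
        mean_fcs_combined=mean_comb,
        category_counts=counts,
        n_missing_scores=missing,
    )


def load_m49(classification: pd.DataFrame) -> list[ScopeDefinition]:
    """Scopes from a table with iso3 / sub_region / region columns.

    Emits one country scope per row, one scope per sub-region and region,
    and the global scope. A country listed in two regions (or two
    sub-regions) is an error.
    """
    seen: dict[str, tuple[str, str]] = {}
    for row in classification.itertuples(index=False):
        iso3 = str(row.iso3).strip().upper()
        sub = str(row.sub_region).strip()
        reg = str(row.region).strip()
        if iso3 in seen and seen[iso3] != (sub, reg):
            raise ValueError(f"country {iso3} assigned to two regions")
        seen[iso3] = (sub, reg)

    scopes = [
        ScopeDefinition(iso3, "country", {iso3}) for iso3 in sorted(seen)
    ]
    subs: dict[str, set[str]] = {}
    regs: dict[str, set[str]] = {}
    for iso3, (sub, reg) in seen.items():
        subs.setdefault(sub, set()).add(iso3)
        regs.setdefault(reg, set()).add(iso3)
    scopes += [ScopeDefinition(sub, "sub_region", members) for sub, members in sorted(subs.items())]
    scopes += [ScopeDefinition(reg, "region", members) for reg, members in sorted(regs.items())]
    scopes.append(ScopeDefinition(GLOBAL_SCOPE_ID, "global", set(seen)))
    return scopes


def load_m49_csv(path) -> list[ScopeDefinition]:
    return load_m49(pd.read_csv(path, dtype=str))


def compute_indicator(
    entries: list[SpeciesEntry],
    scores: list[ConservationScores],
    scopes: list[ScopeDefinition],
) -> pd.DataFrame:
    """One indicator row per scope, as a tidy DataFrame."""
    rows = []
    for scope in scopes:
        members = species_for_scope(entries, scope)
        res = aggregate(scores, members, scope)
        row = {
            "scope_id": res.scope_id,
            "level": res.level,
            "n_species": res.n_species,
            "mean_fcs_ex": res.mean_fcs_ex,
            "mean_fcs_in": res.mean_fcs_in,
            "mean_fcs_combined": res.mean_fcs_combined,
            "n_missing_scores": res.n_missing_scores,
        }
        for label in CATEGORY_LABELS:
            row[f"n_{label}"] = res.category_counts.get(label, 0)
        rows.append(row)
    return pd.DataFrame(rows)
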