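"""Record filtering, polygon merging, range-PA overlap and coverage summaries.

This is the gap-analysis core: which species' ranges share positive-area
intersection with at least one protected area, and how threat statuses break
down between the protected and unprotected groups.  "No minimum area
threshold" means any positive-area overlap counts; pure boundary contact
(zero-area intersection) does not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from shapely import STRtree, union_all
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .core import (
    ConsistencyError,
    DD_OR_NE,
    IUCN_STATUSES,
    KM_PER_DEGREE,
    ProtectedArea,
    SpeciesRange,
    THREATENED_OR_EXTINCT,
    assign_size_class,
)
from .world import REMOVABLE_STATUS_TERMS

logger = logging.getLogger(__name__)


def round_percent(numerator: float, denominator: float) -> float:
    """Percentage rounded half-up to one decimal, the reporting convention.

    ``round_percent(1115, 7094) == 15.7``.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def filter_pa_records(pas: list[ProtectedArea]) -> list[ProtectedArea]:
    """Drop PA records whose status text marks them as not actually protected.

    A record is removed when its ``status_text`` contains any of the standard
    exclusion substrings ("not protected", "degazetted", "proposed",
    "recommended", "in preparation", "unset"), case-insensitively.  Survivor
    order is preserved.
    """
    out = []
    for p in pas:
        text = (p.status_text or "").lower()
        if any(term in text for term in REMOVABLE_STATUS_TERMS):
            continue
        out.append(p)
    return out


def _valid_geometry(pa: ProtectedArea) -> BaseGeometry:
    g = pa.geometry
    if g.is_valid:
        return g
    repaired = make_valid(g)
    if not repaired.is_valid or repaired.is_empty:
        raise ValueError(f"{pa.pa_id}: invalid geometry could not be repaired")
    logger.warning("repaired invalid geometry for %s", pa.pa_id)
    return repaired


def merge_overlapping_pas(pas: list[ProtectedArea]) -> list[ProtectedArea]:
    """Union connected components of the positive-area overlap graph.

    PAs whose polygons overlap with positive area are merged into a single
    record: geometry union, area fields recomputed from the union (marine
    area as the sum of members', capped by the union area), earliest
    establishment year, ids concatenated with ``+``.  Edge-touching polygons
    (zero-area intersection) are not merged.  Idempotent.
    """
    if not pas:
        return []
    geoms = [_valid_geometry(p) for p in pas]
    tree = STRtree(geoms)
    parent = list(range(len(pas)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    left, right = tree.query(geoms, predicate="intersects")
    for i, j in zip(left.tolist(), right.tolist()):
        if i < j and geoms[i].intersection(geoms[j]).area > 0.0:
            union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(pas)):
        groups.setdefault(find(i), []).append(i)

    merged: list[ProtectedArea] = []
    # deterministic order: groups by their first member's input position
    for members in sorted(groups.values(), key=lambda m: m[0]):
        if len(members) == 1:
            p = pas[members[0]]
            merged.append(p)
            continue
        parts = [pas[i] for i in members]
        geom = union_all([geoms[i] for i in members])
        area = geom.area
        marine = min(sum(p.marine_area_km2 for p in parts), area)
        years = [p.year for p in parts if p.year is not None]
        merged.append(
            ProtectedArea(
                pa_id="+".join(p.pa_id for p in parts),
                geometry=geom,
                status_text=parts[0].status_text,
                year=min(years) if years else None,
                category=parts[0].category,
                area_km2=area,
                marine_area_km2=marine,
                terrestrial_area_km2=area - marine,
            )
        )
    return merged


def terrestrial_clip(
    pa: ProtectedArea, land_mask: BaseGeometry
) -> ProtectedArea | None:
    """Clip a PA to a land mask, recomputing its marine/terrestrial split.

    Returns ``None`` (with a log entry) when the PA is entirely marine; such
    records are dropped from terrestrial analyses.
    """
    if not land_mask.is_valid:
        raise ValueError("land mask geometry is invalid")
    clipped = pa.geometry.intersection(land_mask)
    if clipped.is_empty or clipped.area == 0.0:
        logger.warning("%s: entirely marine, dropped from terrestrial analyses",
                       pa.pa_id)
        return None
    terrestrial = clipped.area
    return ProtectedArea(
        pa_id=pa.pa_id,
        geometry=clipped,
        status_text=pa.status_text,
        year=pa.year,
        category=pa.category,
        area_km2=pa.area_km2,
        marine_area_km2=pa.area_km2 - terrestrial,
        terrestrial_area_km2=terrestrial,
    )


@dataclass
class OverlapTable:
    """Sparse PA x species incidence from positive-area intersection."""

    entries: set[tuple[str, str]]
    species_universe: list[str]
    pa_universe: list[str]

    def __post_init__(self) -> None:
        sp = set(self.species_universe)
        pa = set(self.pa_universe)
        for pa_id, species_id in self.entries:
            if pa_id not in pa:
                raise ConsistencyError(f"entry references unknown PA {pa_id!r}")
            if species_id not in sp:
                raise ConsistencyError(
                    f"entry references unknown species {species_id!r}"
                )

    def protected_species(self) -> set[str]:
        """Species appearing in at least one (PA, species) pair."""
        return {s for _, s in self.entries}

    def species_by_pa(self) -> dict[str, set[str]]:
        d: dict[str, set[str]] = {p: set() for p in self.pa_universe}
        for pa_id, species_id in self.entries:
            d[pa_id].add(species_id)
        return d

    def to_frame(self) -> pd.DataFrame:
        """Long-format (pa_id, species_id) table, sorted for determinism."""
        return pd.DataFrame(
            sorted(self.entries), columns=["pa_id", "species_id"]
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, species_universe: list[str], pa_universe: list[str]
    ) -> "OverlapTable":
        entries = set(zip(df["pa_id"].astype(str), df["species_id"].astype(str)))
        return cls(entries, species_universe, pa_universe)


def intersect_ranges_pas(
    ranges: list[SpeciesRange], pas: list[ProtectedArea]
) -> OverlapTable:
    """Compute the PA x species incidence table.

    A pair is present iff the geometries share positive-area intersection;
    boundary touching does not count.  Uses an STR-tree over the ranges so
    the candidate set is near-linear in the number of matching pairs.
    """
    entries: set[tuple[str, str]] = set()
    if ranges and pas:
        geoms = [r.geometry for r in ranges]
        tree = STRtree(geoms)
        for p in pas:
            for idx in tree.query(p.geometry, predicate="intersects").tolist():
                if p.geometry.intersection(geoms[idx]).area > 0.0:
                    entries.add((p.pa_id, ranges[idx].species_id))
    return OverlapTable(
        entries=entries,
        species_universe=[r.species_id for r in ranges],
        pa_universe=[p.pa_id for p in pas],
    )


@dataclass
class CoverageSummary:
    """Protected/unprotected species counts with status breakdowns.

    Percentages (one-decimal, half-up) are derived properties of the counts.
    """

    n_total: int
    n_protected: int
    n_unprotected: int
    protected_status_counts: dict[str, int] = field(default_factory=dict)
    unprotected_status_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_protected + self.n_unprotected != self.n_total:
            raise ValueError("protected + unprotected must equal total")
        if sum(self.protected_status_counts.values()) != self.n_protected:
            raise ValueError("protected status counts do not sum to group total")
        if sum(self.unprotected_status_counts.values()) != self.n_unprotected:
            raise ValueError("unprotected status counts do not sum to group total")

    @property
    def percent_unprotected(self) -> float:
        return round_percent(self.n_unprotected, self.n_total)

    @property
    def percent_protected(self) -> float:
        return round_percent(self.n_protected, self.n_total)

    def _group_percent(self, counts: dict[str, int], total: int,
                       statuses: frozenset[str]) -> float:
        if total == 0:
            return float("nan")
        return round_percent(sum(counts.get(s, 0) for s in statuses), total)

    @property
    def percent_te_protected(self) -> float:
        """Share of threatened-or-extinct statuses among protected species."""
        return self._group_percent(
            self.protected_status_counts, self.n_protected, THREATENED_OR_EXTINCT
        )

    @property
    def percent_te_unprotected(self) -> float:
        return self._group_percent(
            self.unprotected_status_counts, self.n_unprotected, THREATENED_OR_EXTINCT
        )

    @property
    def percent_ddne_protected(self) -> float:
        """Share of data-deficient / not-evaluated among protected species."""
        return self._group_percent(
            self.protected_status_counts, self.n_protected, DD_OR_NE
        )

    @property
    def percent_ddne_unprotected(self) -> float:
        return self._group_percent(
            self.unprotected_status_counts, self.n_unprotected, DD_OR_NE
        )

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_protected": self.n_protected,
            "n_unprotected": self.n_unprotected,
            "percent_protected": self.percent_protected,
            "percent_unprotected": self.percent_unprotected,
            "percent_te_protected": self.percent_te_protected,
            "percent_te_unprotected": self.percent_te_unprotected,
            "percent_ddne_protected": self.percent_ddne_protected,
            "percent_ddne_unprotected": self.percent_ddne_unprotected,
            "protected_status_counts": dict(self.protected_status_counts),
            "unprotected_status_counts": dict(self.unprotected_status_counts),
        }


def coverage_summary(
    overlap: OverlapTable, ranges: list[SpeciesRange]
) -> CoverageSummary:
    """Summarise protection status of every species in the universe.

    A species is protected iff it appears in at least one overlap entry.
    """
    status_by_id = {r.species_id: r.status for r in ranges}
    unknown = set(overlap.species_universe) - set(status_by_id)
    if unknown:
        raise ConsistencyError(
            f"overlap table references species absent from ranges: "
            f"{sorted(unknown)[:5]}"
        )
    protected = overlap.protected_species()
    prot_counts = {s: 0 for s in IUCN_STATUSES}
    unprot_counts = {s: 0 for s in IUCN_STATUSES}
    n_prot = n_unprot = 0
    for sid in overlap.species_universe:
        status = status_by_id[sid]
        if sid in protected:
            prot_counts[status] += 1
            n_prot += 1
        else:
            unprot_counts[status] += 1
            n_unprot += 1
    return CoverageSummary(
        n_total=len(overlap.species_universe),
        n_protected=n_prot,
        n_unprotected=n_unprot,
        protected_status_counts=prot_counts,
        unprotected_status_counts=unprot_counts,
    )


def pa_attribute_table(
    overlap: OverlapTable,
    pas: list[ProtectedArea],
    ranges: list[SpeciesRange],
    km_per_degree: float = KM_PER_DEGREE,
) -> pd.DataFrame:
    """Per-PA covariate table feeding the GLMs.

    Columns: pa_id, richness, n_threatened (T&E statuses), prop_threatened
    (NaN when richness is 0), abs_latitude_deg of the geometry centroid,
    ln_area of the terrestrial area, year, category, size_class.  PAs with
    non-positive terrestrial area are excluded with a log entry.
    """
    status_by_id = {r.species_id: r.status for r in ranges}
    species = overlap.species_by_pa()
    rows = []
    for p in pas:
        if p.terrestrial_area_km2 <= 0:
            logger.warning("%s: non-positive terrestrial area, excluded", p.pa_id)
            continue
        sp = species.get(p.pa_id, set())
        richness = len(sp)
        n_threat = sum(status_by_id[s] in THREATENED_OR_EXTINCT for s in sp)
        rows.append(
            {
                "pa_id": p.pa_id,
                "richness": richness,
                "n_threatened": n_threat,
                "prop_threatened": (n_threat / richness) if richness else math.nan,
                "abs_latitude_deg": abs(p.geometry.centroid.y) / km_per_degree,
                "ln_area": math.log(p.terrestrial_area_km2),
                "year": p.year,
                "category": p.category,
                "size_class": assign_size_class(p.terrestrial_area_km2),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pa_id", "richness", "n_threatened", "prop_threatened",
            "abs_latitude_deg", "ln_area", "year", "category", "size_class",
        ],
    )
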