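"""Shared domain types for the gap-analysis pipeline.

Everything lives in a flat planar coordinate system measured in kilometres.
Latitude in degrees is recovered from the y coordinate as ``y / km_per_degree``
(default 111.32 km per degree), so areas are true areas and no projection
machinery is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from shapely.geometry.base import BaseGeometry

#: Canonical IUCN Red List status codes used throughout.
IUCN_STATUSES = ("LC", "NT", "VU", "EN", "CR", "EW", "EX", "DD", "NE")

#: Threatened-or-extinct (T&E) statuses.
THREATENED_OR_EXTINCT = frozenset({"VU", "EN", "CR", "EW", "EX"})

#: Data deficient or not evaluated.
DD_OR_NE = frozenset({"DD", "NE"})

#: Default latitude mapping: kilometres of northing per degree of latitude.
KM_PER_DEGREE = 111.32

#: Terrestrial-area threshold (km^2) below which a PA counts as a microreserve.
MICRORESERVE_KM2 = 10.0

#: Five decade size classes of PA terrestrial area, half-open [lo, hi).
SIZE_CLASS_BOUNDS: dict[str, tuple[float, float]] = {
    "0-10": (0.0, 10.0),
    "10-100": (10.0, 100.0),
    "100-1000": (100.0, 1000.0),
    "1000-10000": (1000.0, 10000.0),
    "10000-100000": (10000.0, 100000.0),
}

SIZE_CLASS_LABELS = tuple(SIZE_CLASS_BOUNDS)

#: Label for PAs at or above 100,000 km^2; excluded from accumulation analyses.
OVERSIZE_LABEL = "oversize"


class ConfigurationError(ValueError):
    """Raised for invalid world or analysis configuration."""


class SchemaError(ValueError):
    """Raised when a tabular input is missing required columns."""


class GeoJSONError(ValueError):
    """Raised when a GeoJSON input cannot be parsed; names the feature."""


class ConsistencyError(ValueError):
    """Raised when linked inputs reference ids the other side does not know."""


def assign_size_class(terrestrial_area_km2: float) -> str:
    """Assign a PA terrestrial area to its decade size class.

    Intervals are half-open, closed on the left: an area of exactly 10 km^2
    falls in ``"10-100"`` (the <10 km^2 microreserve definition excludes it
    from the smallest class).  Areas >= 100,000 km^2 get the ``"oversize"``
    label and are excluded from the accumulation analysis.
    """
    a = float(terrestrial_area_km2)
    if math.isnan(a) or a < 0:
        raise ValueError(f"terrestrial area must be >= 0, got {terrestrial_area_km2}")
    for label, (lo, hi) in SIZE_CLASS_BOUNDS.items():
        if lo <= a < hi:
            return label
    return OVERSIZE_LABEL


@dataclass
class SpeciesRange:
    """One species' geographic range.

    Attributes
    ----------
    species_id : str
        Unique identifier.
    taxon_class : str
        Taxonomic class label (e.g. ``"amphibia"``).
    geometry : shapely geometry
        (Multi)polygon in planar km.
    area_km2 : float
        Range area; must agree with the geometric area to 0.1 % relative
        tolerance.
    status : str
        IUCN Red List category code.
    """

    species_id: str
    taxon_class: str
    geometry: BaseGeometry
    area_km2: float
    status: str = "NE"

    def validate(self) -> None:
        if self.status not in IUCN_STATUSES:
            raise ValueError(f"{self.species_id}: unknown status {self.status!r}")
        if self.area_km2 <= 0:
            raise ValueError(f"{self.species_id}: non-positive area {self.area_km2}")
        geom_area = self.geometry.area
        if not math.isclose(self.area_km2, geom_area, rel_tol=1e-3):
            raise ValueError(
                f"{self.species_id}: area_km2={self.area_km2} disagrees with "
                f"geometry area {geom_area}"
            )
        if not self.geometry.is_valid:
            raise ValueError(f"{self.species_id}: invalid geometry")

    @property
    def centroid_abs_latitude(self) -> float:
        """|latitude| of the range centroid in degrees (default mapping)."""
        return abs(self.geometry.centroid.y) / KM_PER_DEGREE


@dataclass
class ProtectedArea:
    """One protected-area record mirroring the WDPA attribute schema.

    ``terrestrial_area_km2`` is the PA area less its marine area; all size
    classification and accumulation sampling use the terrestrial area.
    """

    pa_id: str
    geometry: BaseGeometry
    status_text: str = "Designated"
    year: int | None = None
    category: str = "Not Reported"
    area_km2: float = 0.0
    marine_area_km2: float = 0.0
    terrestrial_area_km2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.terrestrial_area_km2 is None:
            self.terrestrial_area_km2 = self.area_km2 - self.marine_area_km2

    def validate(self) -> None:
        if self.marine_area_km2 < 0:
            raise ValueError(f"{self.pa_id}: negative marine area")
        expected = self.area_km2 - self.marine_area_km2
        if not math.isclose(self.terrestrial_area_km2, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"{self.pa_id}: terrestrial_area_km2 must equal "
                f"area_km2 - marine_area_km2 ({expected})"
            )
        if self.terrestrial_area_km2 < 0:
            raise ValueError(f"{self.pa_id}: negative terrestrial area")

    @property
    def size_class(self) -> str:
        return assign_size_class(self.terrestrial_area_km2)

    @property
    def is_microreserve(self) -> bool:
        return self.terrestrial_area_km2 < MICRORESERVE_KM2
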