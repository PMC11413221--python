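"""Regional summaries, richness rasterization, binned tables, time trends.

Tabular counterparts of the study's summary figures: per-region PA size and
coverage breakdowns, a richness raster (counts of overlapping range polygons
per cell, written as Esri ASCII grid text), rectangular 2-D bin counts (the
tabular stand-in for hexbin heatmaps), and 5-year establishment trends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .core import (
    MICRORESERVE_KM2,
    ProtectedArea,
    SpeciesRange,
    THREATENED_OR_EXTINCT,
)
from .coverage import OverlapTable, round_percent

logger = logging.getLogger(__name__)


@dataclass
class RegionSpec:
    """A named analysis region (user-supplied polygon)."""

    region_id: str
    geometry: BaseGeometry
    name: str = ""

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise ValueError(f"region {self.region_id!r}: invalid geometry")


def _check_region_overlaps(regions: list[RegionSpec]) -> None:
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            if regions[i].geometry.intersection(regions[j].geometry).area > 0:
                logger.warning(
                    "regions %s and %s overlap; species will be counted in both",
                    regions[i].region_id, regions[j].region_id,
                )


def regional_summary(
    pas: list[ProtectedArea],
    ranges: list[SpeciesRange],
    overlap: OverlapTable,
    regions: list[RegionSpec],
) -> pd.DataFrame:
    """Per-region PA size and species-coverage summary.

    PAs are assigned to the first region (input order) containing their
    centroid; species are assigned to every region their range intersects
    with positive area.  Protection status comes from the global overlap
    table, so a single region containing everything reproduces the global
    coverage summary.  PAs falling in no region are reported via a warning.
    """
    _check_region_overlaps(regions)
    protected = overlap.protected_species()
    status_by_id = {r.species_id: r.status for r in ranges}

    pa_region: dict[str, str | None] = {}
    for p in pas:
        c = p.geometry.centroid
        assigned = None
        for reg in regions:  # first region in input order wins ties
            if reg.geometry.covers(c):
                assigned = reg.region_id
                break
        pa_region[p.pa_id] = assigned
    uncovered = [pid for pid, r in pa_region.items() if r is None]
    if uncovered:
        logger.warning("%d PA(s) fall in no region: %s%s",
                       len(uncovered), uncovered[:5],
                       "..." if len(uncovered) > 5 else "")

    rows = []
    for reg in regions:
        reg_pas = [p for p in pas if pa_region[p.pa_id] == reg.region_id]
        median_area = (
            float(np.median([p.terrestrial_area_km2 for p in reg_pas]))
            if reg_pas
            else float("nan")
        )
        reg_species = [
            r.species_id
            for r in ranges
            if r.geometry.intersection(reg.geometry).area > 0
        ]
        n_prot = sum(s in protected for s in reg_species)
        n_unprot = len(reg_species) - n_prot
        n_te_prot = sum(
            s in protected and status_by_id[s] in THREATENED_OR_EXTINCT
            for s in reg_species
        )
        n_te_unprot = sum(
            s not in protected and status_by_id[s] in THREATENED_OR_EXTINCT
            for s in reg_species
        )
        rows.append(
            {
                "region_id": reg.region_id,
                "name": reg.name,
                "n_pas": len(reg_pas),
                "median_pa_terrestrial_km2": median_area,
                "n_species": len(reg_species),
                "n_protected": n_prot,
                "n_unprotected": n_unprot,
                "percent_unprotected": (
                    round_percent(n_unprot, len(reg_species))
                    if reg_species
                    else float("nan")
                ),
                "n_te_protected": n_te_prot,
                "n_te_unprotected": n_te_unprot,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RichnessRaster:
    """Grid of per-cell counts of overlapping range polygons.

    ``cells[0, 0]`` is the north-west cell (rows written top-down, as in the
    Esri ASCII grid dialect); ``(xllcorner, yllcorner)`` is the lower-left
    corner of the grid.
    """

    xllcorner: float
    yllcorner: float
    cell_size_km: float
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int)
        if self.cell_size_km <= 0:
            raise ValueError("cell size must be positive")
        if np.any(self.cells < 0):
            raise ValueError("cell counts must be >= 0")

    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]

    def cell_box(self, row: int, col: int):
        x0 = self.xllcorner + col * self.cell_size_km
        y1 = self.yllcorner + (self.n_rows - row) * self.cell_size_km
        return box(x0, y1 - self.cell_size_km, x0 + self.cell_size_km, y1)

    def to_ascii(self, path: str | Path) -> None:
        """Write as an Esri ASCII grid (plain text)."""
        lines = [
            f"ncols {self.n_cols}",
            f"nrows {self.n_rows}",
            f"xllcorner {self.xllcorner!r}",
            f"yllcorner {self.yllcorner!r}",
            f"cellsize {self.cell_size_km!r}",
            "NODATA_value -9999",
        ]
        lines += [" ".join(str(v) for v in row) for row in self.cells]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_ascii(cls, path: str | Path) -> "RichnessRaster":
        text = Path(path).read_text().splitlines()
        header = {}
        i = 0
        while i < len(text) and text[i].split()[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        }:
            k, v = text[i].split(maxsplit=1)
            header[k.lower()] = v
            i += 1
        cells = np.array(
            [[int(v) for v in line.split()] for line in text[i:] if line.strip()]
        )
        return cls(
            xllcorner=float(header["xllcorner"]),
            yllcorner=float(header["yllcorner"]),
            cell_size_km=float(header["cellsize"]),
            cells=cells,
        )


def rasterize_richness(
    ranges: list[SpeciesRange],
    xllcorner: float,
    yllcorner: float,
    cell_size_km: float,
    n_rows: int,
    n_cols: int,
    status_filter: set[str] | frozenset[str] | None = None,
) -> RichnessRaster:
    """Count, per cell, the ranges intersecting it with positive area.

    ``status_filter`` restricts to species in those statuses (e.g. the
    threatened-or-extinct set for a threatened-richness raster).
    """
    if cell_size_km <= 0:
        raise ValueError("cell size must be positive")
    raster = RichnessRaster(
        xllcorner, yllcorner, cell_size_km, np.zeros((n_rows, n_cols), dtype=int)
    )
    selected = [
        r for r in ranges if status_filter is None or r.status in status_filter
    ]
    if not selected:
        return raster
    geoms = [r.geometry for r in selected]
    tree = STRtree(geoms)
    cells = raster.cells
    for row in range(n_rows):
        for col in range(n_cols):
            cell = raster.cell_box(row, col)
            count = 0
            for idx in tree.query(cell, predicate="intersects").tolist():
                if cell.intersection(geoms[idx]).area > 0:
                    count += 1
            cells[row, col] = count
    return raster


def binned_summary(
    records: pd.DataFrame,
    x_field: str,
    y_field: str,
    x_bins,
    y_bins,
) -> pd.DataFrame:
    """Counts of records per rectangular 2-D bin.

    ``x_bins`` / ``y_bins`` are monotone edge sequences (K+1 edges for K
    bins) or an int for equal-width bins over the data range.  Bins are
    half-open, closed on the left/bottom: a record exactly on an interior
    edge belongs to the higher bin, and records at or beyond the last edge
    are out of range.  The output is a long-format table (one row per bin)
    whose counts sum to the number of in-range records.
    """
    for f in (x_field, y_field):
        if not pd.api.types.is_numeric_dtype(records[f]):
            raise TypeError(f"field {f!r} is not numeric")
    x = records[x_field].to_numpy(dtype=float)
    y = records[y_field].to_numpy(dtype=float)

    def edges(bins, v):
        if np.isscalar(bins):
            return np.linspace(v.min(), v.max(), int(bins) + 1)
        e = np.asarray(bins, dtype=float)
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be increasing, length >= 2")
        return e

    ex, ey = edges(x_bins, x), edges(y_bins, y)
    ix = np.digitize(x, ex)  # 1..K inside; 0 or K+1 out of range
    iy = np.digitize(y, ey)
    ok = (ix >= 1) & (ix <= ex.size - 1) & (iy >= 1) & (iy <= ey.size - 1)

    counts = np.zeros((ex.size - 1, ey.size - 1), dtype=int)
    np.add.at(counts, (ix[ok] - 1, iy[ok] - 1), 1)
    rows = []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            rows.append(
                {
                    f"{x_field}_left": ex[i], f"{x_field}_right": ex[i + 1],
                    f"{y_field}_left": ey[j], f"{y_field}_right": ey[j + 1],
                    "count": counts[i, j],
                }
            )
    return pd.DataFrame(rows)


def time_trend_table(
    pas: list[ProtectedArea],
    overlap: OverlapTable,
    bin_years: int = 5,
    micro_threshold_km2: float = MICRORESERVE_KM2,
) -> pd.DataFrame:
    """Establishment trends in ``bin_years``-year bins.

    Per bin: the number of species-containing PAs established (all sizes,
    and microreserves only), plus the cumulative number of distinct species
    covered by PAs established up to the bin's end (again all sizes and
    microreserves only).  PAs with no establishment year are excluded with a
    logged count.
    """
    species_by_pa = overlap.species_by_pa()
    recs = []
    n_missing = 0
    for p in pas:
        if p.year is None or (isinstance(p.year, float) and np.isnan(p.year)):
            n_missing += 1
            continue
        sp = species_by_pa.get(p.pa_id, set())
        if not sp:
            continue
        recs.append((int(p.year), p.terrestrial_area_km2 < micro_threshold_km2, sp))
    if n_missing:
        logger.warning("%d PA record(s) had no establishment year; excluded",
                       n_missing)
    if not recs:
        return pd.DataFrame(
            columns=["bin_start", "bin_end", "n_pas", "n_micro",
                     "cum_species", "cum_species_micro"]
        )
    y0 = min(r[0] for r in recs)
    y1 = max(r[0] for r in recs)
    start = (y0 // bin_years) * bin_years
    rows = []
    seen_all: set[str] = set()
    seen_micro: set[str] = set()
    for b0 in range(start, y1 + 1, bin_years):
        b1 = b0 + bin_years - 1
        in_bin = [r for r in recs if b0 <= r[0] <= b1]
        for _, is_micro, sp in in_bin:
            seen_all |= sp
            if is_micro:
                seen_micro |= sp
        rows.append(
            {
                "bin_start": b0,
                "bin_end": b1,
                "n_pas": len(in_bin),
                "n_micro": sum(r[1] for r in in_bin),
                "cum_species": len(seen_all),
                "cum_species_micro": len(seen_micro),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_missing_year"] = n_missing
    return df


def load_regions_geojson(path: str | Path) -> list[RegionSpec]:
    """Read regions from a GeoJSON FeatureCollection with region_id/name."""
    import json

    from shapely.geometry import shape

    data = json.loads(Path(path).read_text())
    regions = []
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties", {})
        regions.append(
            RegionSpec(
                region_id=str(props.get("region_id", f"region_{i}")),
                geometry=shape(feat["geometry"]),
                name=str(props.get("name", "")),
            )
        )
    return regions
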