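"""Serialization: GeoJSON FeatureCollections + CSV attribute tables.

Coordinates are planar km (not geographic degrees), but the container format
is plain RFC 7946 GeoJSON so that standard tooling can open the files.  JSON
floats round-trip exactly (shortest-repr encoding), so
``load_world(serialize_world(...))`` reproduces geometries bit for bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .core import GeoJSONError, ProtectedArea, SchemaError, SpeciesRange

RANGES_GEOJSON = "ranges.geojson"
PAS_GEOJSON = "pas.geojson"
SPECIES_CSV = "species.csv"
PAS_CSV = "pa_attributes.csv"

SPECIES_COLUMNS = ["species_id", "taxon_class", "area_km2", "status"]
PA_COLUMNS = [
    "pa_id",
    "status_text",
    "year",
    "category",
    "area_km2",
    "marine_area_km2",
    "terrestrial_area_km2",
]


def _feature(geom, properties: dict) -> dict:
    return {"type": "Feature", "properties": properties, "geometry": mapping(geom)}


def _write_feature_collection(features: list[dict], path: Path) -> None:
    fc = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(fc, sort_keys=True, separators=(",", ":")) + "\n")


def _read_feature_collection(path: Path) -> list[dict]:
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise GeoJSONError(f"{path}: not valid JSON: {exc}") from exc
    if data.get("type") != "FeatureCollection" or "features" not in data:
        raise GeoJSONError(f"{path}: not a GeoJSON FeatureCollection")
    return data["features"]


def _feature_geometry(feat: dict, idx: int, path: Path):
    try:
        return shape(feat["geometry"])
    except Exception as exc:  # noqa: BLE001 - re-raised with feature context
        ident = feat.get("properties", {}).get("species_id") or feat.get(
            "properties", {}
        ).get("pa_id") or f"feature #{idx}"
        raise GeoJSONError(f"{path}: bad geometry in {ident}: {exc}") from exc


def serialize_world(
    ranges: list[SpeciesRange], pas: list[ProtectedArea], out_dir: str | Path
) -> None:
    """Write a world as two GeoJSON FeatureCollections plus two CSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _write_feature_collection(
        [
            _feature(
                r.geometry,
                {
                    "species_id": r.species_id,
                    "taxon_class": r.taxon_class,
                    "area_km2": r.area_km2,
                    "status": r.status,
                },
            )
            for r in ranges
        ],
        out / RANGES_GEOJSON,
    )
    _write_feature_collection(
        [
            _feature(
                p.geometry,
                {
                    "pa_id": p.pa_id,
                    "status_text": p.status_text,
                    "year": p.year,
                    "category": p.category,
                    "area_km2": p.area_km2,
                    "marine_area_km2": p.marine_area_km2,
                    "terrestrial_area_km2": p.terrestrial_area_km2,
                },
            )
            for p in pas
        ],
        out / PAS_GEOJSON,
    )
    pd.DataFrame(
        [[r.species_id, r.taxon_class, r.area_km2, r.status] for r in ranges],
        columns=SPECIES_COLUMNS,
    ).to_csv(out / SPECIES_CSV, index=False)
    pd.DataFrame(
        [
            [p.pa_id, p.status_text, p.year, p.category, p.area_km2,
             p.marine_area_km2, p.terrestrial_area_km2]
            for p in pas
        ],
        columns=PA_COLUMNS,
    ).to_csv(out / PAS_CSV, index=False)


def _check_schema(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def load_world(
    in_dir: str | Path,
) -> tuple[list[SpeciesRange], list[ProtectedArea]]:
    """Load a serialized world; inverse of :func:`serialize_world`.

    Geometry and attributes come from the GeoJSON; the CSV tables are
    validated against the expected schema so that downstream tabular
    consumers fail loudly here rather than mid-analysis.
    """
    src = Path(in_dir)
    sp_csv = pd.read_csv(src / SPECIES_CSV) if (src / SPECIES_CSV).exists() else None
    if sp_csv is not None:
        _check_schema(sp_csv, SPECIES_COLUMNS, src / SPECIES_CSV)
    pa_csv = pd.read_csv(src / PAS_CSV) if (src / PAS_CSV).exists() else None
    if pa_csv is not None:
        _check_schema(pa_csv, PA_COLUMNS, src / PAS_CSV)

    ranges = []
    for i, feat in enumerate(_read_feature_collection(src / RANGES_GEOJSON)):
        props = feat.get("properties", {})
        geom = _feature_geometry(feat, i, src / RANGES_GEOJSON)
        try:
            ranges.append(
                SpeciesRange(
                    species_id=props["species_id"],
                    taxon_class=props["taxon_class"],
                    geometry=geom,
                    area_km2=float(props["area_km2"]),
                    status=props["status"],
                )
            )
        except KeyError as exc:
            raise GeoJSONError(
                f"{src / RANGES_GEOJSON}: feature #{i} missing property {exc}"
            ) from exc

    pas = []
    for i, feat in enumerate(_read_feature_collection(src / PAS_GEOJSON)):
        props = feat.get("properties", {})
        geom = _feature_geometry(feat, i, src / PAS_GEOJSON)
        try:
            pas.append(
                ProtectedArea(
                    pa_id=props["pa_id"],
                    geometry=geom,
                    status_text=props["status_text"],
                    year=props["year"],
                    category=props["category"],
                    area_km2=float(props["area_km2"]),
                    marine_area_km2=float(props["marine_area_km2"]),
                    terrestrial_area_km2=float(props["terrestrial_area_km2"]),
                )
            )
        except KeyError as exc:
            raise GeoJSONError(
                f"{src / PAS_GEOJSON}: feature #{i} missing property {exc}"
            ) from exc
    return ranges, pas
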