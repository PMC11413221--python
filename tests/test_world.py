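"""Synthetic world generator: distributions, determinism, serialization."""

import json
import math

import numpy as np
import pytest
from scipy import stats

from pagap import (
    ConfigurationError,
    GeoJSONError,
    SchemaError,
    WorldConfig,
    load_world,
    serialize_world,
)
from pagap.config import Extent
from pagap.world import (
    REMOVABLE_STATUS_TERMS,
    assign_threat_status,
    generate_pa_network,
    generate_species_ranges,
    generate_world,
)


def _cfg(**kw):
    base = dict(
        seed=1,
        species_counts={"amphibia": 100},
        range_size_lognormal={"amphibia": (math.log(4.0), 0.0)},
        richness_gradient=0.0,
        pa_counts_per_size_class={},
        dd_fraction=0.0,
    )
    base.update(kw)
    return WorldConfig(**base)


class TestRangeGeneration:
    def test_degenerate_lognormal_gives_constant_areas(self):
        ranges = generate_species_ranges(_cfg(), "amphibia",
                                         np.random.default_rng(0))
        assert len(ranges) == 100
        for r in ranges:
            # clipping at the extent can only shrink a disc
            assert r.area_km2 <= 4.0 + 1e-9
            assert r.area_km2 == pytest.approx(r.geometry.area)
        unclipped = [r for r in ranges if r.area_km2 > 3.999]
        assert len(unclipped) >= 95  # discs of ~2 km radius rarely hit the edge

    def test_lognormal_median_recovered(self, ranges_10k):
        areas = [r.area_km2 for r in ranges_10k]
        assert np.median(areas) == pytest.approx(1.0, rel=0.05)

    def test_unknown_class_raises(self):
        with pytest.raises(ConfigurationError):
            generate_species_ranges(_cfg(), "aves", np.random.default_rng(0))

    def test_area_matches_geometry_invariant(self, small_world):
        ranges, _ = small_world
        for r in ranges:
            r.validate()

    def test_gradient_pulls_centroids_toward_equator(self):
        kw = dict(species_counts={"amphibia": 5000},
                  range_size_lognormal={"amphibia": (0.0, 0.5)})
        flat = _cfg(richness_gradient=0.0, **kw)
        graded = _cfg(richness_gradient=0.1, **kw)
        lat_flat = [
            r.centroid_abs_latitude
            for r in generate_species_ranges(flat, "amphibia",
                                             np.random.default_rng(3))
        ]
        lat_graded = [
            r.centroid_abs_latitude
            for r in generate_species_ranges(graded, "amphibia",
                                             np.random.default_rng(3))
        ]
        assert np.mean(lat_graded) < np.mean(lat_flat)

    def test_clustering_reduces_nearest_neighbor_distance(self):
        kw = dict(species_counts={"amphibia": 500})
        plain = generate_species_ranges(_cfg(**kw), "amphibia",
                                        np.random.default_rng(5))
        clustered = generate_species_ranges(
            _cfg(cluster_intensity=4.0, **kw), "amphibia",
            np.random.default_rng(5),
        )

        def mean_nn(ranges):
            pts = np.array([[r.geometry.centroid.x, r.geometry.centroid.y]
                            for r in ranges])
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            return d.min(1).mean()

        assert mean_nn(clustered) < mean_nn(plain)


class TestThreatAssignment:
    def test_logistic_intercept_only_gives_half(self, ranges_10k):
        out = assign_threat_status(ranges_10k, (0.0, 0.0, 0.0),
                                   np.random.default_rng(11))
        frac = np.mean([r.status in {"VU", "EN", "CR"} for r in out])
        se = math.sqrt(0.25 / len(out))
        assert abs(frac - 0.5) <= 3 * se

    def test_negative_area_slope_gives_negative_correlation(self, ranges_10k):
        out = assign_threat_status(ranges_10k, (0.0, -1.0, 0.0),
                                   np.random.default_rng(12))
        areas = [r.area_km2 for r in out]
        threat = [r.status in {"VU", "EN", "CR"} for r in out]
        rho, _ = stats.spearmanr(areas, threat)
        assert rho < 0

    def test_saturated_negative_intercept_gives_no_threatened(self, ranges_10k):
        out = assign_threat_status(ranges_10k[:500], (-30.0, 0.0, 0.0),
                                   np.random.default_rng(13))
        assert all(r.status == "LC" for r in out)

    def test_dd_fraction_relabels_expected_count(self, ranges_10k):
        out = assign_threat_status(ranges_10k[:1000], (0.0, 0.0, 0.0),
                                   np.random.default_rng(14), dd_fraction=0.2)
        assert sum(r.status == "DD" for r in out) == 200

    def test_inputs_not_mutated(self, ranges_10k):
        before = [r.status for r in ranges_10k[:50]]
        assign_threat_status(ranges_10k[:50], (0.0, 0.0, 0.0),
                             np.random.default_rng(1))
        assert [r.status for r in ranges_10k[:50]] == before


class TestPANetwork:
    def test_counts_and_area_bounds_per_class(self):
        cfg = _cfg(pa_counts_per_size_class={"0-10": 50})
        pas = generate_pa_network(cfg, np.random.default_rng(0))
        assert len(pas) == 50
        assert all(0 < p.area_km2 < 10 for p in pas)
        assert all(p.size_class == "0-10" for p in pas)

    def test_no_removable_status_when_fraction_zero(self):
        cfg = _cfg(pa_counts_per_size_class={"0-10": 40, "10-100": 10},
                   removable_status_fraction=0.0)
        pas = generate_pa_network(cfg, np.random.default_rng(1))
        for p in pas:
            assert not any(t in p.status_text.lower()
                           for t in REMOVABLE_STATUS_TERMS)

    def test_all_removable_when_fraction_one(self):
        cfg = _cfg(pa_counts_per_size_class={"0-10": 30},
                   removable_status_fraction=1.0)
        pas = generate_pa_network(cfg, np.random.default_rng(2))
        for p in pas:
            assert any(t in p.status_text.lower()
                       for t in REMOVABLE_STATUS_TERMS)

    def test_years_and_categories_respect_config(self):
        cfg = _cfg(pa_counts_per_size_class={"10-100": 200},
                   pa_year_range=(1950, 1960),
                   category_labels=[("II", 1.0)])
        pas = generate_pa_network(cfg, np.random.default_rng(3))
        assert all(1950 <= p.year <= 1960 for p in pas)
        assert all(p.category == "II" for p in pas)

    def test_pa_exceeding_extent_is_configuration_error(self):
        cfg = _cfg(extent=Extent(0, 0, 200, 200),
                   pa_counts_per_size_class={"10000-100000": 1})
        with pytest.raises(ConfigurationError):
            generate_pa_network(cfg, np.random.default_rng(4))

    def test_same_seed_identical_network(self):
        cfg = _cfg(pa_counts_per_size_class={"0-10": 20, "100-1000": 5},
                   removable_status_fraction=0.3)
        a = generate_pa_network(cfg, np.random.default_rng(9))
        b = generate_pa_network(cfg, np.random.default_rng(9))
        for pa, pb in zip(a, b):
            assert pa.pa_id == pb.pa_id
            assert pa.geometry.equals_exact(pb.geometry, 0)
            assert (pa.year, pa.category, pa.status_text) == \
                   (pb.year, pb.category, pb.status_text)


class TestSerialization:
    def test_round_trip_identity(self, tmp_path, small_world):
        ranges, pas = small_world
        serialize_world(ranges[:3], pas[:2], tmp_path)
        r2, p2 = load_world(tmp_path)
        assert len(r2) == 3 and len(p2) == 2
        for a, b in zip(ranges[:3], r2):
            assert a.species_id == b.species_id
            assert a.taxon_class == b.taxon_class
            assert a.status == b.status
            assert a.area_km2 == b.area_km2
            assert a.geometry.equals_exact(b.geometry, 0)
        for a, b in zip(pas[:2], p2):
            assert a.pa_id == b.pa_id
            assert (a.status_text, a.year, a.category) == \
                   (b.status_text, b.year, b.category)
            assert a.area_km2 == b.area_km2
            assert a.terrestrial_area_km2 == b.terrestrial_area_km2
            assert a.geometry.equals_exact(b.geometry, 0)

    def test_same_seed_byte_identical_geojson(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        serialize_world(*generate_world(small_config), d1)
        serialize_world(*generate_world(small_config), d2)
        for name in ("ranges.geojson", "pas.geojson", "species.csv",
                     "pa_attributes.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_empty_world_round_trips(self, tmp_path):
        serialize_world([], [], tmp_path)
        ranges, pas = load_world(tmp_path)
        assert ranges == [] and pas == []
        fc = json.loads((tmp_path / "ranges.geojson").read_text())
        assert fc == {"type": "FeatureCollection", "features": []}

    def test_missing_status_column_is_schema_error(self, tmp_path, small_world):
        ranges, pas = small_world
        serialize_world(ranges[:3], pas[:2], tmp_path)
        csv = tmp_path / "species.csv"
        lines = csv.read_text().splitlines()
        header = lines[0].split(",")
        keep = [i for i, h in enumerate(header) if h != "status"]
        csv.write_text("\n".join(
            ",".join(line.split(",")[i] for i in keep) for line in lines
        ))
        with pytest.raises(SchemaError, match="status"):
            load_world(tmp_path)

    def test_malformed_geometry_names_feature(self, tmp_path, small_world):
        ranges, pas = small_world
        serialize_world(ranges[:2], pas[:1], tmp_path)
        fc = json.loads((tmp_path / "ranges.geojson").read_text())
        fc["features"][1]["geometry"] = {"type": "Polygon"}  # no coordinates
        (tmp_path / "ranges.geojson").write_text(json.dumps(fc))
        with pytest.raises(GeoJSONError, match=ranges[1].species_id):
            load_world(tmp_path)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"extent": Extent(0, 0, -1, 10)},
            {"richness_gradient": -0.1},
            {"dd_fraction": 1.5},
            {"removable_status_fraction": -0.2},
            {"pa_counts_per_size_class": {"0-5": 3}},
            {"pa_year_range": (2000, 1990)},
            {"range_size_lognormal": {"amphibia": (0.0, -1.0)}},
            {"species_counts": {"reptilia": 5}},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            _cfg(**kw)

    def test_yaml_round_trip(self, tmp_path, small_config):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        loaded = WorldConfig.from_yaml(path)
        assert loaded == small_config

    def test_seed_mandatory_in_yaml(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("species_counts: {amphibia: 5}\n")
        with pytest.raises(ConfigurationError, match="seed"):
            WorldConfig.from_yaml(path)
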