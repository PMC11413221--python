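"""Bootstrap species-accumulation curves and rate ratios."""

import math

import numpy as np
import pytest

from pagap import (
    AccumulationConfig,
    AccumulationCurve,
    OverlapTable,
    accumulate_ensemble,
    accumulate_once,
    rate_ratio,
)
from pagap.accumulation import curves_to_frame, replicate_rngs
from conftest import square_pa


def _pa(pa_id, area, x0=0.0, y0=0.0):
    return square_pa(pa_id, x0, y0, math.sqrt(area))


def _overlap(species_by_pa, species_universe=None):
    entries = {(p, s) for p, sp in species_by_pa.items() for s in sp}
    universe = sorted({s for sp in species_by_pa.values() for s in sp})
    if species_universe is not None:
        universe = species_universe
    return OverlapTable(entries, universe, list(species_by_pa))


class TestSingleRun:
    def test_single_pa_saturation(self):
        pa = _pa("p", 5.0)
        curve = accumulate_once([pa], {"p": {"A", "B", "C"}}, 12.0,
                                np.random.default_rng(0))
        assert list(curve.breakpoints) == pytest.approx([5.0, 10.0, 15.0])
        assert list(curve.values) == [3.0, 3.0, 3.0]

    def test_final_draw_overshoots_and_is_included(self):
        pa = _pa("p", 7.0)
        curve = accumulate_once([pa], {"p": {"A"}}, 10.0,
                                np.random.default_rng(0))
        assert curve.breakpoints[-1] == pytest.approx(14.0)

    def test_coupon_collector_expectation(self):
        pas = [_pa("p1", 1.0), _pa("p2", 1.0, x0=5)]
        lists = {"p1": {"A"}, "p2": {"B"}}
        finals = []
        rngs = replicate_rngs(123, 1, 10_000)[0]
        for rng in rngs:
            c = accumulate_once(pas, lists, 4.0, rng)
            assert len(c.values) == 4  # unit areas: exactly 4 draws
            finals.append(c.values[-1])
        finals = np.asarray(finals)
        expected = 2 * (1 - 0.5**4)  # 1.875
        se = finals.std(ddof=1) / math.sqrt(finals.size)
        assert abs(finals.mean() - expected) <= 3 * se

    def test_first_draw_unbiased_for_mean_richness(self):
        pas = [_pa(f"p{i}", 2.0, x0=4 * i) for i in range(4)]
        lists = {"p0": set(), "p1": {"A"}, "p2": {"A", "B"},
                 "p3": {"A", "B", "C"}}
        rngs = replicate_rngs(7, 1, 10_000)[0]
        firsts = np.array([
            accumulate_once(pas, lists, 2.0, rng).values[0] for rng in rngs
        ])
        se = firsts.std(ddof=1) / math.sqrt(firsts.size)
        assert abs(firsts.mean() - 1.5) <= 3 * se

    def test_same_seed_identical_sequence(self):
        pas = [_pa(f"p{i}", 1 + i, x0=9 * i) for i in range(5)]
        lists = {p.pa_id: {f"s{i}"} for i, p in enumerate(pas)}
        a = accumulate_once(pas, lists, 50.0, np.random.default_rng(42))
        b = accumulate_once(pas, lists, 50.0, np.random.default_rng(42))
        assert np.array_equal(a.breakpoints, b.breakpoints)
        assert np.array_equal(a.values, b.values)

    def test_zero_area_pa_excluded_with_warning(self):
        pas = [_pa("p", 1.0), square_pa("z", 5, 5, 1.0,
                                        area_km2=0.0, marine_area_km2=0.0,
                                        terrestrial_area_km2=0.0)]
        with pytest.warns(UserWarning, match="zero-area"):
            accumulate_once(pas, {"p": {"A"}, "z": set()}, 3.0,
                            np.random.default_rng(0))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            accumulate_once([], {}, 5.0, np.random.default_rng(0))

    def test_curve_monotone_and_bounded(self):
        rng = np.random.default_rng(11)
        pas = [_pa(f"p{i}", float(rng.uniform(0.5, 3)), x0=8 * i)
               for i in range(10)]
        lists = {p.pa_id: {f"s{j}" for j in rng.integers(0, 15, 3)}
                 for p in pas}
        curve = accumulate_once(pas, lists, 40.0, rng)
        assert np.all(np.diff(curve.values) >= 0)
        universe = {s for sp in lists.values() for s in sp}
        assert curve.values[-1] <= len(universe)


class TestEnsemble:
    def test_single_replicate_consistent_with_accumulate_once(self):
        pas = [_pa(f"p{i}", 2.0 + i, x0=10 * i) for i in range(4)]
        overlap = _overlap({p.pa_id: {f"s{i}"} for i, p in enumerate(pas)})
        cfg = AccumulationConfig(seed=5, n_replicates=1,
                                 target_area_km2=20.0, area_grid=10)
        curves = accumulate_ensemble(pas, overlap, cfg)
        label = pas[0].size_class
        # replicate the ensemble's substream construction
        rng = replicate_rngs(5, len(cfg.size_class_scheme), 1)[0][0]
        lists = {p.pa_id: overlap.species_by_pa()[p.pa_id] for p in pas}
        single = accumulate_once(pas, lists, 20.0, rng)
        grid = 20.0 * np.arange(1, 11) / 10
        assert curves[label].values == pytest.approx(single.evaluate(grid))

    def test_degenerate_world_all_species_everywhere(self):
        # side lengths 1, 8, 16 give bit-exact areas 1, 64, 256
        pas = [_pa("a", 1.0), _pa("b", 64.0, x0=20),
               _pa("c", 256.0, x0=60)]
        all_sp = {"x", "y", "z"}
        overlap = _overlap({p.pa_id: all_sp for p in pas})
        cfg = AccumulationConfig(seed=1, n_replicates=5,
                                 target_area_km2=400.0, area_grid=8)
        curves = accumulate_ensemble(pas, overlap, cfg)
        for label, curve in curves.items():
            first_area = {"0-10": 1.0, "10-100": 64.0, "100-1000": 256.0}[label]
            for a, v in zip(curve.breakpoints, curve.values):
                if a >= first_area:
                    assert v == 3.0

    def test_empty_class_omitted_with_warning(self, caplog):
        pas = [_pa("a", 1.0)]
        overlap = _overlap({"a": {"x"}})
        cfg = AccumulationConfig(seed=2, n_replicates=2,
                                 target_area_km2=5.0, area_grid=4)
        with caplog.at_level("WARNING"):
            curves = accumulate_ensemble(pas, overlap, cfg)
        assert set(curves) == {"0-10"}
        assert "no PAs" in caplog.text

    def test_beta_diversity_ordering_small_beats_large(self):
        # disjoint single-species PAs; small PAs 10x more numerous per unit
        # area, so the microreserve curve dominates everywhere
        pas = [_pa(f"m{i}", 5.0, x0=10 * i) for i in range(40)]
        pas += [_pa(f"L{i}", 20_000.0, x0=500 * i, y0=300) for i in range(4)]
        species = {p.pa_id: {f"sp_{p.pa_id}"} for p in pas}
        overlap = _overlap(species)
        cfg = AccumulationConfig(seed=99, n_replicates=200,
                                 target_area_km2=20_000.0, area_grid=25)
        curves = accumulate_ensemble(pas, overlap, cfg)
        small, large = curves["0-10"], curves["10000-100000"]
        interior = slice(0, 24)
        assert np.all(small.values[interior] > large.values[interior])

    def test_ensemble_pure_function_of_seed(self):
        pas = [_pa(f"p{i}", 1.0 + i, x0=10 * i) for i in range(5)]
        overlap = _overlap({p.pa_id: {f"s{i % 3}"}
                            for i, p in enumerate(pas)})
        cfg = AccumulationConfig(seed=31, n_replicates=20,
                                 target_area_km2=30.0, area_grid=12)
        c1 = accumulate_ensemble(pas, overlap, cfg)
        c2 = accumulate_ensemble(pas, overlap, cfg)
        for label in c1:
            assert np.array_equal(c1[label].values, c2[label].values)


class TestCurveType:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            AccumulationCurve(np.array([1.0, 1.0]), np.array([0.0, 1.0]),
                              "0-10")
        with pytest.raises(ValueError):
            AccumulationCurve(np.array([1.0, 2.0]), np.array([2.0, 1.0]),
                              "0-10")

    def test_step_evaluation_right_continuous(self):
        c = AccumulationCurve(np.array([1.0, 2.0, 3.0]),
                              np.array([1.0, 4.0, 5.0]), "0-10",
                              target_area_km2=3.0, n_species_universe=10)
        assert c.evaluate([0.5, 1.0, 1.5, 2.0, 9.0]) == pytest.approx(
            [0.0, 1.0, 1.0, 4.0, 5.0]
        )


class TestRateRatio:
    def _curves(self):
        grid = np.array([1.0, 2.0, 3.0, 4.0])
        a = AccumulationCurve(grid, np.array([2.0, 4.0, 6.0, 8.0]), "0-10",
                              n_species_universe=10, target_area_km2=4.0)
        b = AccumulationCurve(grid, np.array([1.0, 2.0, 3.0, 4.0]),
                              "10-100", n_species_universe=10,
                              target_area_km2=4.0)
        return a, b

    def test_identical_curves_unit_ratio(self):
        a, _ = self._curves()
        for method, param in [("species_at_area_fraction", 0.5),
                              ("area_to_coverage", 0.4)]:
            assert rate_ratio(a, a, method, param).value == pytest.approx(1.0)

    def test_proportional_curves(self):
        a, b = self._curves()
        for param in (0.25, 0.5, 1.0):
            r = rate_ratio(a, b, "species_at_area_fraction", param)
            assert r.value == pytest.approx(2.0)

    def test_hand_evaluated_fixture(self):
        a, b = self._curves()
        # level 0.3*10 = 3 species: a first reaches 3 at area 2, b at area 3
        r = rate_ratio(a, b, "area_to_coverage", 0.3)
        assert r.value == pytest.approx(3.0 / 2.0)
        assert r.detail["area_a"] == 2.0 and r.detail["area_b"] == 3.0

    def test_unreached_coverage_infinite_sentinel(self):
        a, b = self._curves()
        with pytest.warns(UserWarning, match="never reached"):
            r = rate_ratio(a, b, "area_to_coverage", 0.9)
        assert math.isinf(r.value) or math.isnan(r.value)

    def test_mismatched_targets_rejected(self):
        a, b = self._curves()
        c = AccumulationCurve(np.array([1.0]), np.array([1.0]), "0-10",
                              n_species_universe=10, target_area_km2=9.0)
        with pytest.raises(ValueError):
            rate_ratio(a, c)

    def test_curves_frame_long_format(self):
        a, b = self._curves()
        df = curves_to_frame({"0-10": a, "10-100": b})
        assert list(df.columns) == ["size_class", "area_km2", "mean_species"]
        assert len(df) == 8
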