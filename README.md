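# pagap — protected-area gap analysis for small-range taxa

`pagap` is a tested, reusable implementation of a protected-area (PA) gap
analysis pipeline of the kind used to ask how well a PA network covers a
taxon dominated by small geographic ranges (amphibians being the canonical
case), and whether very small reserves — *microreserves*, terrestrial area
< 10 km² — add species to a growing network faster than large ones.

It is aimed at conservation biogeographers and macroecologists who want the
full analysis chain runnable and checkable without multi-gigabyte WDPA/IUCN
downloads: every stage works on a synthetic world with the statistical
structure the real analyses assume, and accepts real-data exports in the
same GeoJSON + CSV schema.

## What it computes

* **Synthetic biogeography** (`pagap.world`): species ranges as discs with
  log-normal areas per taxon class, range centers following a latitudinal
  richness gradient (density ∝ e^(−g·|lat|)), logistic threat statuses
  P(threatened) = logistic(a + b·ln A + c·|lat|), and a PA network of
  squares in five decade size classes (0–10 … 10,000–100,000 km²) with
  WDPA-style attributes. Pure function of `(config, seed)`.
* **Coverage accounting** (`pagap.coverage`): record filtering by status
  text ("proposed", "degazetted", …), union-merge of overlapping PA
  polygons, the sparse PA × species incidence table from positive-area
  intersection (no minimum overlap threshold), protected/unprotected status
  breakdowns, and the per-PA covariate table (richness, threatened count,
  |latitude|, ln area, year, category, size class).
* **Range-size statistics** (`pagap.range_stats`): group medians,
  Kruskal–Wallis and pairwise Wilcoxon rank-sum tests (continuity-corrected
  normal approximation, tie-corrected variance), and the counting rule for
  species whose range a single reserve of area *r* would majority-cover
  (area < 2r).
* **GLMs** (`pagap.glm`): a richness-weighted binomial (logit) GLM of the
  proportion of a PA's species that are threatened, and a negative-binomial
  (log link) GLM of species richness with dispersion θ estimated jointly;
  AIC model selection over a marginality-respecting candidate suite
  including the null model; McFadden pseudo-R²; and the e^β − 1 percent
  change back-transform.
* **Bootstrap accumulation** (`pagap.accumulation`): per size class, sample
  PAs with replacement until a common cumulative-area target, track
  distinct species, average many replicates on an equal-area grid, and
  compare classes with rate ratios (species at an area fraction, or area to
  reach a coverage level).
* **Reporting** (`pagap.reporting`): regional summaries, richness rasters
  (Esri ASCII grid text), rectangular 2-D bin tables, and 5-year
  establishment time trends.

## Worked example

```python
from pagap import (WorldConfig, generate_world, filter_pa_records,
                   merge_overlapping_pas, intersect_ranges_pas,
                   coverage_summary, AccumulationConfig, accumulate_ensemble,
                   rate_ratio, range_stats_report)

cfg = WorldConfig(seed=7)                       # default synthetic world
ranges, pas = generate_world(cfg)
pas = merge_overlapping_pas(filter_pa_records(pas))
overlap = intersect_ranges_pas(ranges, pas)
summary = coverage_summary(overlap, ranges)
print(f"unprotected: {summary.n_unprotected} ({summary.percent_unprotected}%)")

rep = range_stats_report(ranges, reserve_area_km2=10.0)
print("majority-protectable:", rep["majority_protectable"]["all"])

acc = AccumulationConfig(seed=11, n_replicates=200, area_grid=100)
curves = accumulate_ensemble(pas, overlap, acc)
r = rate_ratio(curves["0-10"], curves["10000-100000"],
               "species_at_area_fraction", 0.05)
print(f"microreserve speedup vs largest class: {r.value:.1f}x")
```

prints (seed 7):

```
unprotected: 688 (86.0%)
majority-protectable: 160
microreserve speedup vs largest class: 27.8x
```

688 of the 800 synthetic species (86.0%) touch no PA — the default world
deliberately has a sparse network, so most small-range species fall through
it. 160 species have ranges under 20 km², i.e. a single 10 km² reserve
would cover a strict majority of their range. At 5% of the common
cumulative-area target, the mean accumulation curve of the 0–10 km² class
sits ~28× higher than that of the 10,000–100,000 km² class: with high beta
diversity, many small reserves cover species far faster per km² than a few
giant ones.

The same pipeline is scriptable from the shell:

```bash
pagap simulate --config world.yaml --out-dir world/
pagap coverage --world-dir world/ --out-dir cov/
pagap range-stats --world-dir world/ --out-dir stats/
pagap glm --pa-table cov/pa_table.csv --response richness --out-dir glm/
pagap accumulate --world-dir world/ --seed 3 --replicates 1000 --out-dir acc/
pagap report --world-dir world/ --out-dir report/
```

Every run writes a `manifest.json` (config hash, versions, seed).

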