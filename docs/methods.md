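# Methods

## Coordinate system and the synthetic world

All geometry lives in a planar coordinate system measured in kilometres,
with latitude recovered as `lat = y / km_per_degree` (111.32 km/degree by
default). This mirrors an equal-area projection workflow: areas are true
areas, so range sizes, PA sizes and overlap areas carry the same semantics
as real-world equal-area computations, without projection machinery. The
world is a rectangle (default 3000 × 3000 km centred on the equator,
spanning roughly ±13.5° latitude).

Species ranges are regular 64-gon discs — close enough to circles for any
biogeographic purpose while keeping polygon areas in closed form (the
64-gon's area is exact, so `area_km2` equals the geometric area by
construction). Range areas are log-normal per taxon class; the default
single class uses ln-area ~ Normal(μ = 4.6, σ = 2.0), i.e. a median range
of ~100 km² with a long upper tail, which is the qualitative shape of
empirical terrestrial-vertebrate range-size distributions where the
amphibian-like class has the smallest median. Range centers follow a
latitudinal richness gradient with density ∝ exp(−g·|lat|) (default
g = 0.05/degree, a mild equatorward concentration), sampled by rejection
against the uniform envelope. An optional clustering knob places a fraction
c/(1+c) of centers as Gaussian jitter (σ = 2% of the extent) around earlier
centers; no empirical calibration exists for it, so the default is 0.

Threat statuses come from a logistic model: P(threatened) =
logistic(a + b·ln A + c·|lat|) with defaults (a, b, c) = (1.0, −0.35, 0),
making small-range species markedly more likely to be threatened — the
empirical pattern the range-statistics comparisons presuppose. Threatened
species are split uniformly among VU/EN/CR (downstream analyses only use
the threatened/non-threatened dichotomy); the rest are LC. A `dd_fraction`
(default 0.25, matching the DD+NE share implied by published global
tallies: (641+1244)/7094 ≈ 0.27) is then relabelled DD at random,
independent of threat — real DD assignment is *not* independent of threat,
which is one reason synthetic coverage breakdowns should not be read as
predictions about real networks.

PAs are axis-aligned squares (closed-form area; easy brute-force oracles).
Per decade size class the configured count is drawn with area log-uniform
within the class bounds (the 0–10 km² class draws from [0.01, 10) km²;
0.01 km² is the smallest record we consider meaningful). Establishment
years are uniform over 1860–2020; management-category labels are sampled
by configurable weights; a configurable fraction of records receives a
removable status text ("Proposed", "Degazetted", …) to exercise the record
filter. Generated PAs are fully terrestrial; the marine split is exercised
through `terrestrial_clip` with an explicit land mask.

The default network (500/200/120/60/12 PAs across the five classes,
~760,000 km² ≈ 8% of the extent) is sparse relative to the ~15% of real
land under protection, and species richness per PA is far below real
counts. Everything downstream is therefore a *structural* test bed: it
preserves the qualitative regularities (log-normal ranges, gradient,
threat–range-size link, size-class mix) but none of the magnitudes of the
global system. Passing tests demonstrate the correctness of the
operations, not the real-world values of coverage percentages or model
coefficients.

Determinism: generation is a pure function of the config (which carries a
mandatory seed). Classes are generated from independent `SeedSequence`
substreams in sorted name order, the PA network from a final substream, so
adding a taxon class does not perturb the others.

## Coverage accounting

Record filtering removes any PA whose status text contains one of the
standard exclusion substrings, case-insensitively (real status
capitalization varies). Overlapping PA polygons are merged: connected
components of the positive-area overlap graph are unioned into single
records, with area fields recomputed from the union, the earliest
establishment year kept (year enters models as "establishment"; earliest
is the conservative choice), and member ids concatenated. Polygons that
touch only along an edge are *not* merged — and likewise a range touching
a PA only along a boundary is *not* protected. Requiring strictly positive
intersection area is the numerically stable reading of "no minimum area
threshold": a 2-D intersection with no lower bound on its size.

Percentages in coverage summaries are rounded half-up to one decimal —
the convention that reproduces the published one-decimal tallies (a small
number of published figures are inconsistent with any single rounding rule
applied to their printed inputs; we do not chase them).

The per-PA covariate table records richness, threatened count (statuses
VU/EN/CR/EW/EX), proportion threatened (undefined, NaN, at zero richness —
such rows are excluded from GLM fitting), |latitude| of the geometry
centroid, ln terrestrial area, year, category, and decade size class.
Size-class intervals are half-open, closed on the left, so exactly 10 km²
is not a microreserve.

## Rank statistics

The class comparisons use the field-standard nonparametric chain:
Kruskal–Wallis across groups (tie-corrected, chi-square reference), then
pairwise two-sided Wilcoxon rank-sum tests with midranks, tie-corrected
variance and 0.5 continuity correction. The normal approximation is used
at every sample size — matching the stated method rather than switching to
exact small-sample p-values; exhaustive enumeration serves as a test
oracle only (agreement within 0.05 at n = 5+5). Degenerate all-tied input
returns the null-mean statistic with p = 1. No multiple-testing adjustment
is applied across pairwise tests (the workflow we mirror reports
unadjusted tests). Computation is delegated to scipy behind the module
interface.

The "majority protectable" rule counts species whose range area is
strictly below twice the reserve area: a reserve of area r then covers
> 50% of the range. "Majority" is read strictly; a range of exactly 2r is
not counted. The status filter is an explicit argument (EN only, the full
threatened set, or none) because published counts of this kind are
ambiguous about which statuses they include.

## GLMs

The threat-composition model is a binomial GLM with logit link. By default
the outcome is the count pair (threatened, non-threatened) per PA — i.e.
the proportion weighted by richness, which is the coherent binomial
likelihood for a proportion that arises from counts. An unweighted mode
regressing the bare proportion is provided since published descriptions of
such models often leave the weighting unstated. The richness model is a
negative-binomial (NB2) GLM with log link; the dispersion θ (= 1/α) is
estimated jointly by maximum likelihood (Poisson-warm-started BFGS, via
statsmodels), and AIC counts θ as an estimated parameter. Equidispersed
data drive θ → ∞; the fit is returned with a recorded warning rather than
an error, while zero-variance counts (no identifiable dispersion) raise.

Model selection minimises AIC over a candidate suite: every
marginality-respecting subset of {|latitude|, ln area, year, category},
optionally augmented with the latitude × ln-area and ln-area × year
interactions when their mains are present, plus the mandatory null model.
The exact suite behind published "full suite of models" phrasings is never
listed, so ours is the systematic closure of the reported terms. Category
enters as treatment-coded dummies with the most frequent level as
reference (the coding is rarely stated; the most frequent level is the
stable choice). Records with category "Not Applicable", "Not Assigned" or
"Not Reported" are excluded from fitting. McFadden pseudo-R² is
1 − ℓ/ℓ₀ against the same-family intercept-only fit, exactly 0 for the
null model against itself. `percent_change(β) = 100·(e^β − 1)` is the
back-transform used to express log/logit-scale coefficients as percent
changes per covariate unit.

Validation is by parameter recovery at n = 2000 PAs: a known binomial
ln-area slope of −0.4 is recovered within ±0.08, and a known NB latitude
slope of −0.03 (θ = 2) within ±0.01, each in ≥ 90% of 100 seeded
replicates. No real-data coefficient is asserted anywhere: published
values depend on the withheld global dataset.

## Bootstrap accumulation

Within each size class, PAs are drawn uniformly with replacement; after
each draw the cumulative terrestrial area and the cumulative count of
distinct species are recorded; sampling stops at the first draw whose
cumulative area reaches the common target (the final draw may overshoot
and is included — excluding it would bias against large PAs). The default
target is the total terrestrial area of all in-scheme PAs, and the default
replicate count is 1000. Per-replicate curves are right-continuous step
functions (the count jumps when a draw completes); the ensemble evaluates
each on a shared grid of equally spaced areas spanning (0, target] —
last-breakpoint-at-or-before evaluation — and averages pointwise, so
curves from different classes are only ever compared at identical
cumulative areas. Replicates use `SeedSequence` substreams per
(class, replicate), making the full ensemble a pure function of inputs and
seed. Internally only the first occurrence of a PA in the draw sequence
can add species, so the distinct count is computed from cumulative sums
plus a union sweep over distinct PAs — algebraically identical to the
draw-by-draw loop.

Two rate-ratio formalizations are provided, because the "k× faster"
phrasing in the literature never defines one: the ratio of mean species
counts at a fixed fraction of the target area, and the (inverted) ratio of
areas at which each curve first reaches a fixed coverage level. Both are
reported with the grid points used. For scaled-down worlds the early-area
comparison should use a fraction no smaller than the largest single PA
relative to the target, since a class whose every member exceeds the
comparison area has an empty curve there (the acceptance run uses 5% of
the target). Published global ratios are not reproducible from synthetic
worlds — they depend on the real network's composition — and are not
asserted.

## Reporting

Regions are user-supplied polygons. A PA belongs to the region containing
its centroid (first region in input order on boundary ties), which keeps
area statistics un-double-counted; a species belongs to every region its
range positively intersects, which matches "richness of the region"
semantics; the two conventions are documented rather than claimed
equivalent to any published assignment. Richness rasters count, per cell,
the ranges with positive-area intersection, and are written as Esri ASCII
grid text. Hexagonal binning is replaced by rectangular binning in tabular
output (counts per bin carry the analysis; hexagons are a rendering
choice); bins are half-open, closed on the left/bottom, so a record on an
interior edge belongs to the higher bin. Time trends bin establishment
years into 5-year units and track both the per-bin count of
species-containing PAs and the cumulative distinct species covered, each
for all PAs and for microreserves only.

## Problem sizes

The bundled examples and the acceptance run use: a 3000 × 3000 km world
with 800 species and ~900 PAs; 1000 bootstrap replicates on a 200-point
grid; 10,000 replicates for the closed-form sampler check; and 20–100
replicates of n = 2000 for GLM recovery. These sizes give stable means
(Monte Carlo error well inside every stated tolerance) while the whole
suite runs in well under half an hour on one core.

## Known limitations

* The synthetic world has no coastlines, no countries, no spherical
  geometry, no temporal dynamics, and statuses independent of the DD
  relabelling; it validates operations, not real-world magnitudes.
* Merged PAs inherit the first member's status text and category — real
  merged complexes have no single right answer here.
* The NB fit reports θ up to 10¹² before declaring equidispersion; values
  above ~10³ should be read as "Poisson-consistent", not as estimates.
* Rasterization is exact for the polygon sizes used here but iterates
  cells; very large grids would want a scanline approach.
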