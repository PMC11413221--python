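"""Synthetic biogeography generator.

Generates species ranges, threat statuses and a protected-area network with
the statistical structure the downstream analyses assume:

* range areas are log-normal per taxon class (the class emulating amphibians
  gets the smallest median);
* range centers follow a latitudinal richness gradient, density proportional
  to exp(-g * |lat|), optionally spatially clustered;
* threat probability decreases with range area through a logistic model;
* PAs are squares with areas log-uniform within each decade size class,
  establishment years uniform over a configured span, weighted
  management-category labels, and an optional fraction of records carrying a
  removable status text.

Ranges are regular 64-gon discs and PAs are axis-aligned squares so that
areas are controlled in closed form and brute-force oracles stay easy.
Everything is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import Polygon, box

from .config import WorldConfig
from .core import (
    ConfigurationError,
    ProtectedArea,
    SIZE_CLASS_BOUNDS,
    SpeciesRange,
    THREATENED_OR_EXTINCT,
)

#: Status-text vocabulary that the record filter removes (case-insensitive).
REMOVABLE_STATUS_TERMS = (
    "not protected",
    "degazetted",
    "proposed",
    "recommended",
    "in preparation",
    "unset",
)

#: Vertex count of the regular polygon approximating a disc.
DISC_VERTICES = 64

#: Smallest PA area (km^2) drawn in the 0-10 size class (log-uniform lower
#: bound; the class interval itself is closed at 0).
MIN_PA_AREA_KM2 = 0.01

_THREATENED_DRAW = ("VU", "EN", "CR")


def _disc(cx: float, cy: float, area: float, n: int = DISC_VERTICES) -> Polygon:
    """Regular n-gon centred at (cx, cy) with exact polygon area ``area``."""
    r = math.sqrt(2.0 * area / (n * math.sin(2.0 * math.pi / n)))
    theta = 2.0 * math.pi * np.arange(n) / n
    return Polygon(np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)]))


def _sample_gradient_y(config: WorldConfig, rng: np.random.Generator) -> float:
    """Draw a y coordinate with density proportional to exp(-g |y| / kpd).

    Rejection sampling against the uniform envelope; the mode is the point of
    the extent closest to the equator.
    """
    ext = config.extent
    g = config.richness_gradient
    if g == 0.0:
        return float(rng.uniform(ext.y_min, ext.y_max))
    y_mode = min(max(0.0, ext.y_min), ext.y_max)
    f_max = math.exp(-g * abs(y_mode) / config.km_per_degree)
    while True:
        y = float(rng.uniform(ext.y_min, ext.y_max))
        if rng.uniform() < math.exp(-g * abs(y) / config.km_per_degree) / f_max:
            return y


def generate_species_ranges(
    config: WorldConfig, class_name: str, rng: np.random.Generator
) -> list[SpeciesRange]:
    """Generate the configured number of species ranges for one taxon class.

    Each range is a 64-gon disc whose area is drawn from the class's
    log-normal; discs crossing the extent boundary are clipped and their
    areas recomputed.  Centers follow the latitudinal gradient; with
    ``cluster_intensity`` c > 0, a fraction c/(1+c) of centers is jittered
    around earlier centers instead of drawn fresh.

    Statuses are initialised to ``NE``; use :func:`assign_threat_status`.
    """
    if class_name not in config.species_counts:
        raise ConfigurationError(f"unknown taxon class {class_name!r}")
    n = config.species_counts[class_name]
    mu, sigma = config.range_size_lognormal[class_name]
    ext = config.extent
    world = box(ext.x_min, ext.y_min, ext.x_max, ext.y_max)
    p_cluster = config.cluster_intensity / (1.0 + config.cluster_intensity)
    jitter = 0.02 * min(ext.width, ext.height)

    ranges: list[SpeciesRange] = []
    centers: list[tuple[float, float]] = []
    for i in range(n):
        area = float(np.exp(rng.normal(mu, sigma)))
        if centers and rng.uniform() < p_cluster:
            px, py = centers[int(rng.integers(len(centers)))]
            cx = float(np.clip(px + rng.normal(0.0, jitter), ext.x_min, ext.x_max))
            cy = float(np.clip(py + rng.normal(0.0, jitter), ext.y_min, ext.y_max))
        else:
            cx = float(rng.uniform(ext.x_min, ext.x_max))
            cy = _sample_gradient_y(config, rng)
        centers.append((cx, cy))
        geom = _disc(cx, cy, area)
        if not world.contains(geom):
            geom = geom.intersection(world)
        ranges.append(
            SpeciesRange(
                species_id=f"{class_name}_{i:05d}",
                taxon_class=class_name,
                geometry=geom,
                area_km2=geom.area,
                status="NE",
            )
        )
    return ranges


def assign_threat_status(
    ranges: list[SpeciesRange],
    threat_model: tuple[float, float, float],
    rng: np.random.Generator,
    dd_fraction: float = 0.0,
    km_per_degree: float | None = None,
) -> list[SpeciesRange]:
    """Assign IUCN statuses from a logistic threat model.

    A species is threatened with probability
    ``logistic(a + b * ln(area) + c * |lat of centroid|)``; threatened
    species get VU/EN/CR uniformly, the rest LC.  Finally a ``dd_fraction``
    of species (chosen at random, without replacement) is relabelled DD.

    Returns new :class:`SpeciesRange` records; inputs are not mutated.
    """
    from .core import KM_PER_DEGREE

    kpd = km_per_degree if km_per_degree is not None else KM_PER_DEGREE
    a, b, c = threat_model
    out: list[SpeciesRange] = []
    for r in ranges:
        if r.area_km2 <= 0:
            raise ValueError(f"{r.species_id}: area must be > 0")
        lat = abs(r.geometry.centroid.y) / kpd
        eta = a + b * math.log(r.area_km2) + c * lat
        p = 1.0 / (1.0 + math.exp(-eta)) if eta > -500 else 0.0
        if rng.uniform() < p:
            status = _THREATENED_DRAW[int(rng.integers(3))]
        else:
            status = "LC"
        out.append(
            SpeciesRange(r.species_id, r.taxon_class, r.geometry, r.area_km2, status)
        )
    n_dd = int(round(dd_fraction * len(out)))
    if n_dd:
        for idx in rng.choice(len(out), size=n_dd, replace=False):
            out[idx].status = "DD"
    return out


def generate_pa_network(
    config: WorldConfig, rng: np.random.Generator
) -> list[ProtectedArea]:
    """Generate the configured PA network: squares per decade size class.

    Per class, areas are log-uniform within the class bounds (the 0-10 class
    uses ``MIN_PA_AREA_KM2`` as the lower bound of the log-uniform draw);
    establishment years are uniform integers in ``pa_year_range``; categories
    are sampled by weight; a ``removable_status_fraction`` of records gets a
    status text from :data:`REMOVABLE_STATUS_TERMS`, the rest "Designated".
    Generated PAs are fully terrestrial (marine area 0).
    """
    ext = config.extent
    labels = [label for label, _ in config.category_labels]
    weights = np.asarray([w for _, w in config.category_labels], dtype=float)
    weights = weights / weights.sum()
    y0, y1 = config.pa_year_range

    pas: list[ProtectedArea] = []
    k = 0
    for label in SIZE_CLASS_BOUNDS:
        count = config.pa_counts_per_size_class.get(label, 0)
        lo, hi = SIZE_CLASS_BOUNDS[label]
        lo = max(lo, MIN_PA_AREA_KM2)
        if count and math.sqrt(hi) > min(ext.width, ext.height):
            raise ConfigurationError(
                f"size class {label!r} can exceed the extent "
                f"({ext.width} x {ext.height} km)"
            )
        for _ in range(count):
            area = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
            side = math.sqrt(area)
            cx = float(rng.uniform(ext.x_min + side / 2, ext.x_max - side / 2))
            cy = float(rng.uniform(ext.y_min + side / 2, ext.y_max - side / 2))
            geom = box(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
            if rng.uniform() < config.removable_status_fraction:
                term = REMOVABLE_STATUS_TERMS[
                    int(rng.integers(len(REMOVABLE_STATUS_TERMS)))
                ]
                status_text = term.title()
            else:
                status_text = "Designated"
            pas.append(
                ProtectedArea(
                    pa_id=f"pa_{k:05d}",
                    geometry=geom,
                    status_text=status_text,
                    year=int(rng.integers(y0, y1 + 1)),
                    category=labels[int(rng.choice(len(labels), p=weights))],
                    area_km2=area,
                    marine_area_km2=0.0,
                    terrestrial_area_km2=area,
                )
            )
            k += 1
    return pas


def generate_world(
    config: WorldConfig,
) -> tuple[list[SpeciesRange], list[ProtectedArea]]:
    """Generate all classes' ranges (with statuses) and the PA network.

    Deterministic given the config (which carries the seed).  Classes are
    generated in sorted name order from independent substreams so that adding
    a class does not perturb the others.
    """
    ss = np.random.SeedSequence(config.seed)
    class_names = sorted(config.species_counts)
    streams = ss.spawn(len(class_names) + 1)
    ranges: list[SpeciesRange] = []
    for name, child in zip(class_names, streams[:-1]):
        rng = np.random.default_rng(child)
        rs = generate_species_ranges(config, name, rng)
        ranges.extend(
            assign_threat_status(
                rs,
                config.threat_model,
                rng,
                dd_fraction=config.dd_fraction,
                km_per_degree=config.km_per_degree,
            )
        )
    pas = generate_pa_network(config, np.random.default_rng(streams[-1]))
    return ranges, pas


def threatened_fraction(ranges: list[SpeciesRange]) -> float:
    """Fraction of species with a threatened-or-extinct status."""
    if not ranges:
        return float("nan")
    return sum(r.status in THREATENED_OR_EXTINCT for r in ranges) / len(ranges)
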