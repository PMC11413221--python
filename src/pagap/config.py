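"""World configuration for the synthetic biogeography generator.

A :class:`WorldConfig` pins down every stochastic ingredient of a synthetic
world — species counts and range-size distributions per taxon class, the
latitudinal richness gradient, the threat model, and the protected-area
network composition — together with a mandatory seed, so that generation is a
pure function of the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .core import ConfigurationError, KM_PER_DEGREE, SIZE_CLASS_LABELS


@dataclass(frozen=True)
class Extent:
    """Axis-aligned world rectangle in planar km."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min


@dataclass
class WorldConfig:
    """Full specification of a synthetic world.

    Parameters
    ----------
    seed : int
        Mandatory; all generation derives from it.
    extent : Extent or 4-tuple
        World rectangle (x_min, y_min, x_max, y_max) in km.  y = 0 is the
        equator.
    km_per_degree : float
        Latitude mapping: degrees = y / km_per_degree.
    species_counts : dict
        Taxon class name -> number of species to generate.
    range_size_lognormal : dict
        Taxon class name -> (mu, sigma) of ln(range area in km^2).
    richness_gradient : float
        g >= 0; range-center density is proportional to exp(-g * |lat|)
        (lat in degrees), producing more species near the equator.
    cluster_intensity : float
        c >= 0; with probability c / (1 + c) a new range center is jittered
        around a previously placed one instead of drawn fresh, giving
        spatially clustered centers (0 = no clustering).
    threat_model : tuple
        (a, b, c): a species is threatened with probability
        logistic(a + b * ln(area) + c * |lat|); b < 0 makes small-range
        species more likely to be threatened.
    dd_fraction : float
        Fraction of species relabelled DD (data deficient) at random after
        threat assignment.
    pa_counts_per_size_class : dict
        Size-class label -> number of PAs to generate in that class.
    pa_year_range : tuple
        (min_year, max_year) of establishment years, sampled uniformly.
    category_labels : list of (label, weight)
        IUCN management-category labels with sampling weights.
    removable_status_fraction : float
        Fraction of PA records given a status text drawn from the standard
        exclusion vocabulary ("Proposed", "Degazetted", ...); the remainder
        are "Designated".
    """

    seed: int
    extent: Extent = Extent(0.0, -1500.0, 3000.0, 1500.0)
    km_per_degree: float = KM_PER_DEGREE
    species_counts: dict[str, int] = field(
        default_factory=lambda: {"amphibia": 800}
    )
    range_size_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"amphibia": (4.6, 2.0)}
    )
    richness_gradient: float = 0.05
    cluster_intensity: float = 0.0
    threat_model: tuple[float, float, float] = (1.0, -0.35, 0.0)
    dd_fraction: float = 0.25
    pa_counts_per_size_class: dict[str, int] = field(
        default_factory=lambda: {
            "0-10": 500,
            "10-100": 200,
            "100-1000": 120,
            "1000-10000": 60,
            "10000-100000": 12,
        }
    )
    pa_year_range: tuple[int, int] = (1860, 2020)
    category_labels: list[tuple[str, float]] = field(
        default_factory=lambda: [
            ("Ia", 0.05),
            ("II", 0.15),
            ("IV", 0.25),
            ("V", 0.2),
            ("Not Reported", 0.35),
        ]
    )
    removable_status_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.extent, Extent):
            self.extent = Extent(*self.extent)
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.extent.width <= 0 or self.extent.height <= 0:
            raise ConfigurationError("extent must have positive width and height")
        if self.km_per_degree <= 0:
            raise ConfigurationError("km_per_degree must be positive")
        for cls, n in self.species_counts.items():
            if n < 0:
                raise ConfigurationError(f"negative species count for {cls!r}")
            if cls not in self.range_size_lognormal:
                raise ConfigurationError(
                    f"class {cls!r} has no range_size_lognormal entry"
                )
        for cls, (mu, sigma) in self.range_size_lognormal.items():
            if sigma < 0:
                raise ConfigurationError(f"sigma must be >= 0 for class {cls!r}")
        if self.richness_gradient < 0:
            raise ConfigurationError("richness_gradient must be >= 0")
        if self.cluster_intensity < 0:
            raise ConfigurationError("cluster_intensity must be >= 0")
        if not 0.0 <= self.dd_fraction <= 1.0:
            raise ConfigurationError("dd_fraction must be in [0, 1]")
        if not 0.0 <= self.removable_status_fraction <= 1.0:
            raise ConfigurationError("removable_status_fraction must be in [0, 1]")
        for label, n in self.pa_counts_per_size_class.items():
            if label not in SIZE_CLASS_LABELS:
                raise ConfigurationError(f"unknown PA size-class label {label!r}")
            if n < 0:
                raise ConfigurationError(f"negative PA count for class {label!r}")
        y0, y1 = self.pa_year_range
        if y1 < y0:
            raise ConfigurationError("pa_year_range max < min")
        if not self.category_labels:
            raise ConfigurationError("category_labels must be nonempty")
        if any(w < 0 for _, w in self.category_labels):
            raise ConfigurationError("category weights must be >= 0")
        if sum(w for _, w in self.category_labels) <= 0:
            raise ConfigurationError("category weights must sum to > 0")

    # -- YAML round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["extent"] = [self.extent.x_min, self.extent.y_min,
                       self.extent.x_max, self.extent.y_max]
        d["range_size_lognormal"] = {
            k: list(v) for k, v in self.range_size_lognormal.items()
        }
        d["threat_model"] = list(self.threat_model)
        d["pa_year_range"] = list(self.pa_year_range)
        d["category_labels"] = [list(t) for t in self.category_labels]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        d = dict(d)
        if "seed" not in d:
            raise ConfigurationError("config is missing the mandatory 'seed'")
        if "extent" in d:
            d["extent"] = Extent(*d["extent"])
        if "range_size_lognormal" in d:
            d["range_size_lognormal"] = {
                k: tuple(v) for k, v in d["range_size_lognormal"].items()
            }
        if "threat_model" in d:
            d["threat_model"] = tuple(d["threat_model"])
        if "pa_year_range" in d:
            d["pa_year_range"] = tuple(d["pa_year_range"])
        if "category_labels" in d:
            d["category_labels"] = [tuple(t) for t in d["category_labels"]]
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorldConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)
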