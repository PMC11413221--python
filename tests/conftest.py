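import numpy as np
import pytest
from shapely.geometry import box

from pagap import ProtectedArea, SpeciesRange, WorldConfig
from pagap.world import generate_world


def square_range(species_id, x0, y0, side, status="LC", taxon_class="amphibia"):
    """Axis-aligned square species range (test geometry factory)."""
    geom = box(x0, y0, x0 + side, y0 + side)
    return SpeciesRange(species_id, taxon_class, geom, geom.area, status)


def square_pa(pa_id, x0, y0, side, **kwargs):
    geom = box(x0, y0, x0 + side, y0 + side)
    area = geom.area
    defaults = dict(status_text="Designated", year=1980, category="II",
                    area_km2=area, marine_area_km2=0.0,
                    terrestrial_area_km2=area)
    defaults.update(kwargs)
    return ProtectedArea(pa_id, geom, **defaults)


@pytest.fixture(scope="session")
def small_config():
    return WorldConfig(
        seed=42,
        species_counts={"amphibia": 120},
        pa_counts_per_size_class={
            "0-10": 60, "10-100": 25, "100-1000": 15,
            "1000-10000": 8, "10000-100000": 2,
        },
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def ranges_10k():
    """10,000 log-normal(0, 1) ranges for distributional-recovery checks."""
    cfg = WorldConfig(
        seed=2024,
        species_counts={"amphibia": 10_000},
        range_size_lognormal={"amphibia": (0.0, 1.0)},
        richness_gradient=0.0,
        pa_counts_per_size_class={},
        dd_fraction=0.0,
    )
    from pagap.world import generate_species_ranges

    rng = np.random.default_rng(7)
    return generate_species_ranges(cfg, "amphibia", rng)
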