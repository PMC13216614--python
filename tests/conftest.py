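import numpy as np
import pandas as pd
import pytest

from oceangap import synthworld
from oceangap.rasters import Raster


def small_world_config(**kw):
    base = dict(raster_resolution=5.0, n_species=120, n_records=6000, seed=7)
    base.update(kw)
    return synthworld.WorldConfig(**base)


@pytest.fixture(scope="session")
def small_config():
    return small_world_config()


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(bathymetry, layers, registry, truth, occurrences) at reduced size."""
    return synthworld.generate_dataset(small_config)


@pytest.fixture(scope="session")
def grid3():
    from oceangap.geogrid import build_grid
    return build_grid(3)


@pytest.fixture()
def flat_bathy():
    """10x10 all-ocean raster over the whole globe (36° cells are too big;
    use a 10x10 regional raster helper instead where georeference matters)."""
    return Raster(np.full((10, 10), 3000.0), lat_min=0.0, lon_min=0.0,
                  resolution=1.0)


def record_frame(**overrides):
    """One-row internal-format occurrence table with valid defaults."""
    base = dict(raw_name="Genus000 species0a0000", latitude=10.0, longitude=20.0,
                depth=50.0, coord_uncertainty=100.0, basis="HumanObservation",
                status="present", phylum="Mollusca", kingdom="Animalia",
                dataset_id="d1", event_date="2000-01-01")
    base.update(overrides)
    return pd.DataFrame([base])
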