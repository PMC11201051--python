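import numpy as np
import pandas as pd
import pytest

from nichemax.grid_io import EnvGrid, GridHeader, align_stack
from nichemax.maxent import TrainConfig
from nichemax.occurrence import OccurrenceSet


@pytest.fixture
def header3():
    """3x3 grid of 1-degree cells over lon [100,103], lat [30,33]."""
    return GridHeader(ncols=3, nrows=3, xllcorner=100.0, yllcorner=30.0,
                      cellsize=1.0)


@pytest.fixture
def grid3(header3):
    vals = np.arange(9, dtype=float).reshape(3, 3)
    return EnvGrid(header3, "a", vals)


def make_occ(lonlat, source="synthetic"):
    lon, lat = zip(*lonlat)
    return OccurrenceSet(pd.DataFrame({
        "species": "virtual", "longitude": lon, "latitude": lat,
        "source": source}))


@pytest.fixture(scope="session")
def small_niche_setup():
    """6-layer 40x40 landscape, 2-variable niche, 300 presences.

    Session-scoped: several model-level tests reuse the same fitted
    world (deterministic by seed).
    """
    import nichemax as nm
    header = nm.default_header(40)
    stack = nm.make_env_stack(6, header=header, seed=1)
    niche = nm.make_niche(stack, ["env01", "env02"], seed=2)
    occ = nm.sample_occurrences(niche.true_suitability(stack), 300, seed=3)
    return stack, niche, occ


@pytest.fixture(scope="session")
def small_fit(small_niche_setup):
    import nichemax as nm
    stack, niche, occ = small_niche_setup
    cfg = TrainConfig(seed=4, background_size=1600)
    model, data = nm.fit(stack, occ, cfg)
    return model, data, cfg
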