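import numpy as np
import pandas as pd
import pytest

from nichediverge import synthgen
from nichediverge.occurrences import OccurrenceSet
from nichediverge.raster import ClimateStack, GridTransform


@pytest.fixture(scope="session")
def small_stack():
    return synthgen.make_climate_stack(50, 50, layer_names=["BIO10", "BIO12"],
                                       spatial_range=4.0, seed=11)


@pytest.fixture(scope="session")
def seven_layer_stack():
    return synthgen.make_climate_stack(60, 60, seed=12)


@pytest.fixture(scope="session")
def virtual_species(small_stack):
    return synthgen.make_virtual_species(small_stack, {"BIO10": 2.0}, name="vsp")


def make_occurrences(taxon, lons, lats):
    return OccurrenceSet(pd.DataFrame({"taxon": taxon, "lon": lons, "lat": lats}))


def gradient_stack(n=40, steep=8.0, wiggle=0.4, seed=0):
    """Sharp sigmoid climate transition along a wiggly north-south boundary."""
    rng = np.random.default_rng(seed)
    tr = GridTransform(-1.0, 1.0, 2.0 / n, 2.0 / n)
    rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    lon, lat = tr.cell_center(rows, cols)
    boundary = lon + wiggle * np.sin(3 * np.pi * lat)
    b10 = np.tanh(steep * boundary) + 0.05 * rng.standard_normal((n, n))
    b12 = 0.05 * rng.standard_normal((n, n))
    grid = np.stack([b10, b12], axis=2)
    return ClimateStack(["BIO10", "BIO12"], grid, tr), boundary
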