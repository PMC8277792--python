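import numpy as np
import pytest

from alpshift import synthetic as syn
from alpshift.grids import Grid


@pytest.fixture(scope="session")
def small_dem() -> Grid:
    return syn.make_dem(
        24, 24, cell_size=100.0,
        relief={"base_elev": 400.0, "amplitude": 3000.0, "n_ridges": 3},
        seed=11,
    )


@pytest.fixture(scope="session")
def flat_dem() -> Grid:
    return Grid(np.full((20, 20), 1500.0), cell_size=100.0)


@pytest.fixture(scope="session")
def warming_climate(small_dem):
    """40 noise-free warming years on the small DEM."""
    return syn.make_climate_series(
        small_dem,
        years=list(range(1961, 2001)),
        lapse_rate=0.0065,
        warming_rate=0.04,
        noise_sd=0.0,
        prec_noise_frac=0.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def mid_elevation_species():
    """A thermally constrained species with its optimum around 2000 m."""
    return syn.SpeciesSpec(
        name="midalp",
        thermal_optimum=14.0 - 0.0065 * 2000.0,
        thermal_breadth=0.8,
        prec_optimum=1200.0 * (1.0 + 0.0004 * 2000.0),
        prec_breadth=3000.0,
        records_per_year=30.0,
    )
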