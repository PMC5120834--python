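import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ensdm.grids import EnvStack, Grid
from ensdm.landscape import derive_topo_vars, make_climate_surfaces, make_dem
from ensdm.preprocess import ModelTable

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dem() -> Grid:
    return make_dem((32, 32), cell_size=100.0, seed=7)


@pytest.fixture(scope="session")
def small_env(small_dem) -> EnvStack:
    """Climate + topographic stack on a 32x32 island, as the pipeline builds it."""
    topo = derive_topo_vars(small_dem)
    clim = make_climate_surfaces(small_dem, seed=11)
    layers = dict(clim.layers)
    for name, g in topo.layers.items():
        layers.setdefault(name, g)
    return EnvStack(layers=layers, period="present", rcm="observed", excluded=clim.excluded)


@pytest.fixture()
def flat_land_grid() -> Grid:
    """All-land flat grid: handy uniform template."""
    return Grid(np.zeros((20, 20)), cell_size=1.0)


def make_separable_table(n: int = 400, cut: float = 0.6, seed: int = 0, k_noise: int = 0):
    """Label is a deterministic threshold of one covariate (plus optional noise columns)."""
    rng = np.random.default_rng(seed)
    x = rng.random(n)
    data = {"x0": x}
    for j in range(k_noise):
        data[f"noise{j}"] = rng.standard_normal(n)
    y = (x > cut).astype(int)
    return ModelTable(covariates=pd.DataFrame(data), label=y, species="toy")


@pytest.fixture()
def separable_table() -> ModelTable:
    return make_separable_table()
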