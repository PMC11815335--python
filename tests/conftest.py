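import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from bayrsf.habitat import SeagrassLayer
from bayrsf.raster import Raster


@pytest.fixture
def square_patch_layer():
    """1 km x 1 km seagrass square centred on the origin."""
    sq = Polygon([(-500, -500), (500, -500), (500, 500), (-500, 500)])
    return SeagrassLayer(survey_year=2020, patches=sq)


@pytest.fixture
def small_raster():
    """10 x 10 grid, 100 m cells, values = row-major cell index."""
    vals = np.arange(100, dtype=float).reshape(10, 10)
    return Raster(values=vals, x0=0.0, y0=0.0, cell=100.0)


@pytest.fixture
def fix_csv(tmp_path):
    path = tmp_path / "fixes.csv"
    pd.DataFrame(
        {
            "id": ["a", "a", "b"],
            "timestamp": [
                "2021-06-02T01:00:00Z",
                "2021-06-01T01:00:00Z",
                "2021-06-01T12:00:00Z",
            ],
            "lon": [10.0, 20.0, 30.0],
            "lat": [1.0, 2.0, 3.0],
            "residual": [1.0, 2.0, 3.0],
            "n_sats": [9, 8, np.nan],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def reduced_scenario_params():
    from bayrsf.simulate import ScenarioParams

    return ScenarioParams(n_individuals=5, duration_days=45.0)
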