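import pandas as pd
import pytest

from vineflux.core import CanopyGeometry, PhysicalConstants
from vineflux.synthetic import SyntheticConfig, generate_season


@pytest.fixture(scope="session")
def constants():
    return PhysicalConstants()


@pytest.fixture()
def geometry():
    """Default open-hedgerow geometry (1.8 m rows, 0.5-1.5 m x 0.4 m canopy)."""
    return CanopyGeometry(
        lai_series=pd.Series(
            [1.0, 1.5], index=pd.to_datetime(["2020-07-01", "2020-09-01"])
        ),
        porosity_series=pd.Series(
            [0.35, 0.25], index=pd.to_datetime(["2020-07-01", "2020-09-01"])
        ),
    )


@pytest.fixture(scope="session")
def noise_free_season():
    """Two-week noise-free synthetic season (forward model run exactly)."""
    config = SyntheticConfig(
        start="2020-07-01", end="2020-07-14",
        noise_sd_sapflow=0.0, n_vines=1, seed=11,
    )
    return generate_season(config)


@pytest.fixture(scope="session")
def default_season_gbs():
    """Pooled unfiltered conductance table for the full default season."""
    from tests.test_synthetic import _invert_all_vines

    season = generate_season(SyntheticConfig(seed=0))
    records = _invert_all_vines(season)
    return records[~records["filtered"]]


@pytest.fixture(scope="session")
def noisy_season():
    """Four-week season with 10% lognormal sap-flow noise."""
    config = SyntheticConfig(
        start="2020-07-01", end="2020-07-28",
        noise_sd_sapflow=0.1, n_vines=1, seed=7,
    )
    return generate_season(config)
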