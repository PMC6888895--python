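import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import oxilake as ox

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from oxilake.synthetic import _ne_hypsometry, _south_hypsometry


@pytest.fixture(scope="session")
def ne_geometry() -> ox.LakeGeometry:
    """Northeast-basin-like fixture: 2.01 km^2 surface, 6 m SML."""
    return ox.derive_geometry(_ne_hypsometry(), 6.0)


@pytest.fixture(scope="session")
def south_geometry() -> ox.LakeGeometry:
    """South-basin-like fixture: 1.12 km^2 surface, 6 m SML."""
    return ox.derive_geometry(_south_hypsometry(), 6.0)


@pytest.fixture(scope="session")
def enclosure_geometry() -> ox.LakeGeometry:
    """9-m-diameter vertical-walled experimental enclosure, 6 m SML."""
    return ox.cylinder_geometry(np.pi * 4.5**2, 20.0, 6.0)


@pytest.fixture
def stratified_cfg() -> ox.BalanceConfig:
    return ox.BalanceConfig(season="stratified", alpha=0.3)


def components(f_s, f_l, f_z, unit="nmol l-1 d-1", **kw) -> ox.FluxComponentSet:
    """Shorthand for a component set from (mean, sd) pairs."""
    return ox.FluxComponentSet(
        F_S=ox.FluxComponent(*f_s, unit), F_L=ox.FluxComponent(*f_l, unit),
        F_z=ox.FluxComponent(*f_z, unit), **kw)


@pytest.fixture(scope="session")
def linear_hypsometry() -> pd.DataFrame:
    return pd.DataFrame({"depth_m": [0.0, 10.0, 20.0],
                         "area_m2": [1e6, 0.6e6, 0.1e6]})
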