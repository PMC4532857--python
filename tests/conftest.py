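import numpy as np
import pytest

from bogcascade import MonthlyClimate, TopographicCell, make_climate


@pytest.fixture
def topo():
    return TopographicCell(slope_deg=5.0, aspect_deg=90.0, elevation_m=420.0)


@pytest.fixture
def climate_8y():
    """Eight years of South-Pennines-like climate (seeded)."""
    return make_climate(1359.0, years=8, seed=11)


@pytest.fixture
def flat_climate():
    """Deterministic repeating annual cycle (no noise), 6 years."""
    return make_climate(1359.0, years=6, seed=0, precip_cv=0.0, temp_sd_c=0.0)
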