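import math

import numpy as np
import pytest

from sectorsim.agents import CellGroup

RHO_AREA = 200.0


def make_cells(x, y, biomass=None, color=None, strain=None, rho_area=RHO_AREA,
               color_names=("RED", "BLUE")):
    """Hand-rolled cell container for unit tests."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if biomass is None:
        biomass = np.full(n, rho_area * math.pi * 1.0**2)
    biomass = np.asarray(biomass, dtype=float)
    color = np.zeros(n, np.int64) if color is None else np.asarray(color, np.int64)
    strain = np.zeros(n, np.int64) if strain is None else np.asarray(strain, np.int64)
    return CellGroup(
        x=x, y=y, biomass=biomass, color=color, strain=strain,
        ids=np.arange(n, dtype=np.int64), growth_rate=np.zeros(n),
        active=np.ones(n, dtype=bool), rho_area=rho_area,
        color_names=color_names, next_id=n,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
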