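import numpy as np
import pytest

from soilrisk.fields import MaternFieldParams
from soilrisk.universe import GroundTruth, SimConfig, simulate_universe


@pytest.fixture(scope="session")
def small_universe():
    """A 10x10-area universe (50x50 km) with a true exposure effect of
    RR = 1.2 per unit log concentration; shared across read-only tests."""
    cfg = SimConfig(
        nx=10,
        ny=10,
        cell_km=5.0,
        n_samples=300,
        truth=GroundTruth(
            beta=np.log(1.2),
            sigma_u=0.1,
            sigma_v=0.1,
            field=MaternFieldParams(practical_range=20.0, marginal_sd=0.6),
            sigma_x=0.3,
        ),
    )
    return simulate_universe(cfg, seed=11)


@pytest.fixture(scope="session")
def medium_universe():
    """The default 20x20 desk-scale universe under the same truth."""
    cfg = SimConfig(
        truth=GroundTruth(
            beta=np.log(1.2),
            sigma_u=0.1,
            sigma_v=0.1,
            field=MaternFieldParams(practical_range=20.0, marginal_sd=0.6),
            sigma_x=0.3,
        )
    )
    return simulate_universe(cfg, seed=5)


@pytest.fixture(scope="session")
def square_mesh():
    """Mesh over a 50x50 km square with a coarser 25 km extension ring."""
    from soilrisk.mesh import build_mesh

    return build_mesh([(0, 0), (50, 0), (50, 50), (0, 50)], 6.0, extension_width=25.0)
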