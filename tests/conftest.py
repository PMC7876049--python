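import numpy as np
import pytest

from helixhop.lattice_geometry import LatticeGeometry
from helixhop.synthetic_data import SimConfig, make_cohort


@pytest.fixture(scope="session")
def geom13():
    return LatticeGeometry.for_protofilaments(13)


@pytest.fixture(scope="session")
def geom14():
    return LatticeGeometry.for_protofilaments(14)


@pytest.fixture(scope="session")
def m2_like_cohort(geom13):
    """Strongly forward/left-biased cohort with 8% trap occupancy.

    k = 45 /s, preferences (0.1, 0.8, 0.01, 0.05, 0.01, 0.01, 0.01, 0.01):
    dominant forward stepping with a leftward bias, the regime of a dimeric
    plus-end motor making occasional protofilament switches.
    """
    k_total = 45.0
    p = np.array([0.1, 0.8, 0.01, 0.05, 0.01, 0.01, 0.01, 0.01])
    cfg = SimConfig(geometry=geom13, rates=tuple(k_total * p),
                    trap_on_rate=1 / 11.5, trap_off_rate=1.0,
                    duration=30.0, n_tracks=36, seed=5, window_s=0.3)
    trajs, truths = make_cohort(cfg)
    return cfg, trajs, truths, k_total, p
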