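import numpy as np
import pandas as pd
import pytest

from syngameon.model_core import Community, MatingParams
from syngameon.spatial import StemTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Tiny community for fast object-level runs."""
    return MatingParams(
        n_species=2,
        initial_abundances=(6, 3),
        plc=0.5,
        self_success=0.25,
        hybrid_success=0.25,
        fecundity=6,
        mortality_rate=0.2,
        n_events=20,
    )


@pytest.fixture
def small_community(small_params):
    return Community.from_abundances(small_params.initial_abundances)


@pytest.fixture
def toy_stems():
    """Six stems with hand-placed coordinates in a 100 m square.

    Layout around focal stem 0 at (50, 50): stem 1 conspecific at 10 m,
    stem 2 congeneric at 20 m, stem 3 other genus at 5 m, stem 4
    conspecific at exactly 25 m (boundary), stem 5 far away.
    """
    df = pd.DataFrame(
        {
            "stem_id": [0, 1, 2, 3, 4, 5],
            "x": [50.0, 60.0, 50.0, 55.0, 75.0, 95.0],
            "y": [50.0, 50.0, 70.0, 50.0, 50.0, 95.0],
            "species": ["Sa", "Sa", "Sb", "Tc", "Sa", "Sb"],
            "genus": ["S", "S", "S", "T", "S", "S"],
        }
    )
    return StemTable(df, width=100.0, height=100.0)
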