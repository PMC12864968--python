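import numpy as np
import pytest

from pouchchar.study import KINETICS, TIME_GRID_MIN
from pouchchar.synthetic import DissolutionScenario, gen_dissolution


@pytest.fixture
def time_grid():
    return np.asarray(TIME_GRID_MIN)


@pytest.fixture
def noise_free_profiles():
    """One noise-free replicate set per product at the reference (M0, k)."""
    out = {}
    for product, (m0, k) in KINETICS.items():
        sc = DissolutionScenario(product, m0, k, M0_cv=0.0, k_cv=0.0,
                                 noise_sd=0.0, n_replicates=3, seed=0)
        out[product] = gen_dissolution(sc)
    return out
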