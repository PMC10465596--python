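import numpy as np
import pytest

from glomnet import PopulationSpec, make_connectome
from glomnet.glomerular import assign_synapses


@pytest.fixture(scope="session")
def small_population():
    """A small but complete synthetic AL: 6 glomeruli, 4 planted patchy LNs,
    20 other LNs, plus the filter-stage distractors."""
    spec = PopulationSpec(n_glomeruli=6, n_patchy_lns=4, n_other_lns=20, seed=1)
    cn, truth = make_connectome(spec)
    return cn, truth, spec


@pytest.fixture(scope="session")
def small_assigned(small_population):
    cn, truth, spec = small_population
    return assign_synapses(cn)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
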