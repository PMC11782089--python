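import numpy as np
import pandas as pd
import pytest

from targetdecon import meltcurve as mc
from targetdecon import synthetic as syn


@pytest.fixture(scope="session")
def small_tpp():
    """Noise-free 12-protein dataset with 2 stabilized proteins."""
    return syn.gen_tpp(n_proteins=12, n_shifted=2, delta_tm=3.0, noise_cv=0.0, seed=42)


@pytest.fixture(scope="session")
def noisy_tpp_results():
    """NPARC results for a noisy 60-protein dataset with 6 shifted proteins."""
    ds, truth = syn.gen_tpp(n_proteins=60, n_shifted=6, delta_tm=3.0, noise_cv=0.05, seed=5)
    fc = mc.scale_to_reference(mc.sum_total_normalize(ds))
    return mc.run_nparc(fc), truth


@pytest.fixture
def path_graph_db():
    """Interaction database for the path graph a-b-c-d."""
    from targetdecon import permnet as pn

    edges = pd.DataFrame({"A": ["a", "b", "c"], "B": ["b", "c", "d"]})
    return pn.filter_interactions(edges)
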