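import numpy as np
import pandas as pd
import pytest

from antagwas import simdata
from antagwas.panel import GenotypePanel


@pytest.fixture(scope="session")
def small_config():
    return simdata.SimConfig(n_lines=80, snps_per_arm=120, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simdata.simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_fitness(small_panel, small_config):
    return simdata.simulate_fitness(small_panel, small_config)


def make_panel(genotypes, positions=None, arm="2L", lines=None,
               dp=None, gq=None):
    """Hand-built panel for toy tests."""
    g = np.asarray(genotypes, dtype=float)
    n, m = g.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    sites = pd.DataFrame({
        "arm": [arm] * m if isinstance(arm, str) else arm,
        "pos": positions,
        "ref": ["A"] * m,
        "alt": ["T"] * m,
    })
    if lines is None:
        lines = [f"L{i:03d}" for i in range(n)]
    return GenotypePanel(lines=lines, sites=sites, genotypes=g, dp=dp, gq=gq)
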