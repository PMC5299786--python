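import numpy as np
import pandas as pd
import pytest

import funcvar as fv


@pytest.fixture
def toy_profile() -> fv.GeneProfile:
    data = pd.DataFrame(
        [[2.0, 3.0, 5.0, 0.0],
         [1.0, 1.0, 1.0, 1.0],
         [10.0, 0.0, 0.0, 2.0]],
        index=["s1", "s2", "s3"],
        columns=["KO1", "KO2", "KO3", "KO4"])
    return fv.GeneProfile(data)


@pytest.fixture
def toy_map() -> fv.PathwayMap:
    return fv.PathwayMap([("KO1", "P1"), ("KO1", "P2"), ("KO2", "P1"),
                          ("KO3", "P2"), ("KO4", "P1")])


@pytest.fixture(scope="session")
def small_world() -> fv.SyntheticWorld:
    return fv.simulate_world(seed=11)


@pytest.fixture(scope="session")
def cohort_world() -> fv.SyntheticWorld:
    # enough accessory genes for 36 individuals x 25 signature genes
    return fv.simulate_world(n_genes=1060, n_core=50, n_blocks=10, seed=5)
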