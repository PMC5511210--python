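import numpy as np
import pandas as pd
import pytest

import neuronet as nn


@pytest.fixture(scope="session")
def small_dataset():
    """300 genes, one 60-gene module, a few DE genes, RIN/PMI effects."""
    cfg = nn.SimulationConfig(
        n_genes=300,
        module_spec=[nn.ModuleSpec(60, 0.6, status_shift=1.0)],
        de_spec=nn.DESpec(n_de=20, log2fc=1.0, fraction_up=0.6),
        covariate_effects={
            "rin": nn.CovariateEffect(0.5, 0.6),
            "pmi": nn.CovariateEffect(0.5, 0.5),
        },
        seed=7,
    )
    return nn.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """600 independent genes, no planted structure."""
    cfg = nn.SimulationConfig(n_genes=600, seed=3)
    return nn.simulate_dataset(cfg)


@pytest.fixture()
def toy_counts():
    counts = pd.DataFrame(
        [[0, 1], [2, 3], [4, 5]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return nn.CountMatrix.from_counts(counts)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
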