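import numpy as np
import pandas as pd
import pytest

from passig.datamodel import ExpressionMatrix
from passig.sim import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small paired-biopsy cohort with 2 driver pathways, for fast tests."""
    cfg = SimulationConfig(n_genes=400, n_pathways=10, pathway_size_min=15,
                           pathway_size_max=30, n_patients=40,
                           n_driver_pathways=2, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions (2000 genes, 100 patients, 3 drivers)."""
    return simulate_cohort(SimulationConfig(seed=11))


def nb_matrix(rng, n_genes, n_samples, mu=None, phi=0.2, prefix="S"):
    """Null NB count matrix helper shared across test modules."""
    if mu is None:
        mu = np.exp2(rng.normal(4, 2, size=n_genes))
    lam = rng.gamma(1.0 / phi, np.asarray(mu)[:, None] * phi,
                    size=(n_genes, n_samples))
    counts = rng.poisson(lam)
    return ExpressionMatrix(pd.DataFrame(
        counts, index=[f"G{i}" for i in range(n_genes)],
        columns=[f"{prefix}{j}" for j in range(n_samples)]))
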