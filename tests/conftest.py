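import numpy as np
import pandas as pd
import pytest

from gbskit.synthetic import (
    SimAdmixedConfig,
    SimPanelConfig,
    simulate_admixed,
    simulate_reference_panel,
)
from gbskit.variant_filter import GenotypeMatrix


def make_matrix(doses, samples=None, ref="A", alt="G"):
    """GenotypeMatrix from a (samples x loci) dose array with default metadata."""
    doses = np.asarray(doses, dtype=np.int8)
    n_samples, n_loci = doses.shape
    samples = samples or [f"s{i + 1}" for i in range(n_samples)]
    loci = pd.DataFrame(
        {
            "chromosome": ["1"] * n_loci,
            "pos": np.arange(1, n_loci + 1) * 10,
            "ref": [ref] * n_loci,
            "alt": [alt] * n_loci,
        }
    )
    return GenotypeMatrix(samples, loci, doses)


@pytest.fixture(scope="session")
def sim_panel():
    """A K=3, Fst=0.15 Balding-Nichols panel shared across tests."""
    return simulate_reference_panel(
        SimPanelConfig(K=3, n_loci=2000, n_per_pop=20, fst=0.15, seed=11)
    )


@pytest.fixture(scope="session")
def sim_admixed(sim_panel):
    """Five admixed individuals at true Q = (0.7, 0.3, 0.0), no missingness."""
    q = np.tile([0.7, 0.3, 0.0], (5, 1))
    return simulate_admixed(
        sim_panel.panel, SimAdmixedConfig(true_Q=q, missing_rate=0.0, seed=12)
    )
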