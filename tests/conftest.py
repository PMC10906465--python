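import numpy as np
import pandas as pd
import pytest

from dysreg.io import CountMatrix, SampleTable
from dysreg.simulate import SimParams, simulate_experiment


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        ["gA", "gB", "gC"],
        ["s1", "s2"],
        np.array([[3, 4], [5, 0], [10, 20]]),
    )


@pytest.fixture
def tiny_samples() -> SampleTable:
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "genotype": ["WT", "HET"],
                "treatment": ["VEHICLE", "VEHICLE"],
            }
        )
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A modest 6-vs-6 simulated experiment with planted DE, reused across tests."""
    params = SimParams(
        n_genes=500,
        frac_de=0.2,
        set_size=80,
        set_de_enrichment=3.0,
        lfc_mean=1.0,
        baseline_log_sd=0.5,
        seed=11,
    )
    return params, *simulate_experiment(params)
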