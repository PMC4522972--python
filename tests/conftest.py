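import numpy as np
import pandas as pd
import pytest

from protsig import ExpressionMatrix, GeneSignature, SimulationConfig, simulate_cohort


@pytest.fixture
def small_matrix():
    data = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["GENE_A", "GENE_B", "GENE_C"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def small_signature():
    return GeneSignature((("GENE_A", 1), ("GENE_B", -1)), name="SIG")


@pytest.fixture
def planted_cohort():
    """Cohort with a strong planted signal, for downstream smoke checks."""
    return simulate_cohort(
        SimulationConfig(n_samples=80, n_genes=400, n_signature_genes=30, seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
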