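import numpy as np
import pytest

import clonetrack as ct


def random_genotypes(rng, n, m, missing_rate=0.1, prefix=""):
    """Unstructured random dosage matrix with a missing mask (test helper)."""
    dosage = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    missing = rng.random((n, m)) < missing_rate
    return ct.GenotypeMatrix(
        [f"{prefix}S{i}" for i in range(n)],
        [f"{prefix}L{j}" for j in range(m)],
        dosage,
        missing,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def k5_scenario():
    """Standard recovery design: 5 Beta(0.5,0.5) founders, m=2000 loci,
    240 pure + 40 F1 + 20 multi-ancestry individuals."""
    G, Q, F, cats = ct.recovery_scenario(
        k_true=5, m=2000, n_pure_per_founder=48, n_f1=40, n_multi=20, seed=11
    )
    return G, Q, F, cats


@pytest.fixture(scope="session")
def k5_full_fit(k5_scenario):
    G, _, _, _ = k5_scenario
    return ct.fit_admixture(G, 5, seed=7, n_restarts=3)
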