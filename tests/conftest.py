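import numpy as np
import pandas as pd
import pytest

from canprot import simulate


@pytest.fixture(scope="session")
def small_cohort():
    """A modest 7-dog cohort used by several suites (session-cached)."""
    cfg = simulate.SimConfig(n_proteins=150, n_gene_sets=20, seed=11)
    table, truth = simulate.simulate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort: 7 dogs, 915 proteins, 5% true effects."""
    cfg = simulate.SimConfig(seed=5)
    table, truth = simulate.simulate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture()
def tiny_peptides():
    """Two dogs, two proteins, hand-sized abundances for exact checks."""
    from tests_oracles import make_tiny_peptides

    return make_tiny_peptides()


@pytest.fixture(scope="session")
def random_rnk():
    rng = np.random.default_rng(42)
    n = 300
    genes = [f"G{i:04d}" for i in range(n)]
    scores = np.sort(rng.normal(size=n))[::-1]
    return pd.DataFrame({"gene_id": genes, "score": scores})
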