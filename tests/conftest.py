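import numpy as np
import pandas as pd
import pytest

from suscept_gxe import prs_engine, synthetic_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One study-scale cohort shared by read-only tests."""
    return synthetic_cohort.make_cohort(seed=20240101)


@pytest.fixture()
def toy_panel():
    """Tiny hand-built panel: 3 individuals x 2 SNPs."""
    markers = pd.DataFrame({
        "snp": ["rs1", "rs2"],
        "chr": ["1", "1"],
        "bp": [1000, 2000],
        "a1": ["A", "G"],
        "a2": ["C", "T"],
    })
    dosages = np.array([[2.0, 0.0], [1.0, 1.0], [0.0, 2.0]])
    return prs_engine.GenotypePanel(
        ids=np.array(["s1", "s2", "s3"], dtype=object),
        markers=markers, dosages=dosages)


def make_ge(n, seed):
    """(G, E) with G exactly min-max scaled to [0, 1]."""
    rng = np.random.default_rng(seed)
    g = rng.uniform(0, 1, n)
    G = (g - g.min()) / (g.max() - g.min())
    return G, rng.standard_normal(n)
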