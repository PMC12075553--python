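import numpy as np
import pytest

import txclass
from txclass.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small spiked cohort shared by read-only tests (300 genes, 20/30/30)."""
    spec = txclass.CohortSpec(
        n_genes=300,
        class_sizes=(20, 30, 30),
        spike_fraction=0.05,
        spike_log2fc=3.0,
        seed=7,
    )
    return txclass.simulate_counts(spec)


@pytest.fixture(scope="session")
def separable_em():
    """3-class expression matrix with 5-sd class-mean separation on 50 features."""
    rng = np.random.default_rng(0)
    n_per, d = 80, 50
    means = np.zeros((3, d))
    means[0, :15] = 5.0
    means[1, 15:30] = 5.0
    means[2, 30:45] = 5.0
    x = np.vstack([rng.normal(0.0, 1.0, (n_per, d)) + means[c] for c in range(3)])
    labels = np.repeat(["a", "b", "c"], n_per)
    return ExpressionMatrix(
        x,
        [f"s{i}" for i in range(3 * n_per)],
        [f"f{j}" for j in range(d)],
        labels,
    )
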