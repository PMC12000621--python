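import numpy as np
import pandas as pd
import pytest

from coregmap import synthetic


@pytest.fixture(scope="session")
def small_truth():
    """Planted network small enough for fast whole-pipeline tests."""
    return synthetic.generate_grn(
        n_regulators=12, n_targets=60, activators_per_target=2, inhibitors_per_target=1, seed=3
    )


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    expr, labels, batches = synthetic.simulate_expression(
        small_truth, n_samples_per_class=40, sigma=0.25, seed=4
    )
    return expr, labels, batches


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_expr():
    """Deterministic 6-gene × 8-sample frame."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{j}" for j in range(8)]
    return pd.DataFrame(rng.normal(size=(6, 8)), index=genes, columns=samples)
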