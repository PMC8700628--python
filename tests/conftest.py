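import numpy as np
import pandas as pd
import pytest

import ibdclass as ib


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic cohort (29/65/20/13 classes, 2000 genes)."""
    return ib.simulate_counts(ib.SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_expr(default_sim):
    """Filtered, TMM-normalized log2-CPM matrix of the default cohort."""
    counts, meta, truth = default_sim
    labels4 = (meta.disease + "_" + meta.status).to_numpy()
    filt = ib.filter_low_counts(counts, labels4)
    expr = ib.log_cpm(filt, ib.tmm_factors(filt))
    return expr, meta, truth


@pytest.fixture
def small_two_class():
    """12 samples x 10 genes with two separated classes (genes x samples)."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(12, 10))
    X[:6, :2] += 2.0
    expr = pd.DataFrame(
        X.T, index=[f"g{i:02d}" for i in range(10)], columns=[f"s{i:02d}" for i in range(12)]
    )
    labels = pd.Series(["A"] * 6 + ["B"] * 6, index=expr.columns)
    return expr, labels
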