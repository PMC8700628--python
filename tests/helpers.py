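"""Shared fixture builders for the test suite."""

import numpy as np
import pandas as pd


def gaussian_two_class(rng, n_a, n_b, n_genes, n_signal=0, effect=0.0):
    """Plain Gaussian expression fixture with optional planted mean shift."""
    X = rng.normal(size=(n_a + n_b, n_genes))
    X[:n_a, :n_signal] += effect
    expr = pd.DataFrame(
        X.T,
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"s{i:03d}" for i in range(n_a + n_b)],
    )
    labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=expr.columns)
    return expr, labels
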