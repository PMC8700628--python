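"""Principal component analysis of the log-expression matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PCAResult", "run_pca"]


@dataclass(frozen=True)
class PCAResult:
    """Sample scores, gene loadings and per-component variance proportions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray


def run_pca(expr: pd.DataFrame, ncomp: int = 10) -> PCAResult:
    """PCA of samples over genes by SVD of the column-centered data.

    Samples are the observations and genes the variables; genes are
    centered but not scaled (log-CPM values already share a common scale).
    ``explained`` is sigma_h^2 over the total sum of squared singular
    values. The sign of each component is fixed so that its
    largest-magnitude gene loading is positive, making output reproducible
    across linear-algebra backends.
    """
    X = expr.to_numpy(float).T
    n, p = X.shape
    if not (1 <= ncomp <= min(n - 1, p)):
        raise ValueError(f"ncomp must be in [1, {min(n - 1, p)}], got {ncomp}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    for h in range(min(ncomp, s.size)):
        j = int(np.argmax(np.abs(Vt[h])))
        if Vt[h, j] < 0:
            Vt[h] *= -1.0
            U[:, h] *= -1.0
    comp = [f"PC{h + 1}" for h in range(ncomp)]
    scores = pd.DataFrame(U[:, :ncomp] * s[:ncomp], index=expr.columns, columns=comp)
    loadings = pd.DataFrame(Vt[:ncomp].T, index=expr.index, columns=comp)
    explained = (s[:ncomp] ** 2) / total if total > 0 else np.zeros(ncomp)
    return PCAResult(scores=scores, loadings=loadings, explained=explained)
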