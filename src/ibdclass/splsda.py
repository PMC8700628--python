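"""Sparse PLS-DA: per-component gene selection and keepX tuning.

The sparse variant soft-thresholds each component's dense weight vector at
the magnitude of its (keepX+1)-th largest absolute entry, so exactly keepX
genes carry nonzero weight, then renormalizes and deflates as in the dense
fit. keepX per component is tuned by a sequential (greedy) grid search:
component 1's keepX is chosen by minimizing the mean cross-validated error
over the grid, then held fixed while component 2's grid is searched, and so
on. The tuning criterion defaults to the balanced error rate because the
inflamed-tissue classes are mildly unbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluate import _cv_errors_arrays, _repeated_folds
from .plsda import (
    PLSModel,
    _check_two_classes,
    _class_score_means,
    _fit_core,
    _model_from_fit,
    _predict_core,
)

__all__ = ["SparseModel", "TuningResult", "fit_splsda", "tune_keepx"]


@dataclass
class SparseModel(PLSModel):
    """A fitted sparse PLS-DA model.

    The sparsity lives in ``x_weights``: in component h exactly
    ``keepx[h]`` genes have nonzero weight and ``selected[h]`` lists them
    (in matrix order). ``x_loadings`` remain the dense projection loadings
    used for deflation and prediction.
    """

    keepx: tuple = ()
    selected: list = None  # type: ignore[assignment]

    def signature_genes(self) -> list[str]:
        """Union of the selected genes over all components, in matrix order."""
        sel = set().union(*map(set, self.selected))
        return [g for g in self.gene_ids if g in sel]


def _lex_order_key(gene_ids: Sequence[str]) -> np.ndarray:
    """Rank of each gene in lexicographic identifier order (tie-break key)."""
    order = np.argsort(np.asarray(gene_ids, dtype=object))
    key = np.empty(len(gene_ids), dtype=int)
    key[order] = np.arange(len(gene_ids))
    return key


def _as_keepx(keepx, ncomp: int, p: int) -> tuple[int, ...]:
    if np.isscalar(keepx):
        keepx = [int(keepx)] * ncomp
    keepx = tuple(int(v) for v in keepx)
    if len(keepx) != ncomp:
        raise ValueError(f"keepx must have one value per component ({ncomp}), got {len(keepx)}")
    for h, v in enumerate(keepx):
        if not (1 <= v <= p):
            raise ValueError(f"keepx[{h}] = {v} out of range [1, {p}]")
    return keepx


def fit_splsda(
    expr: pd.DataFrame,
    labels: Sequence,
    ncomp: int,
    keepx,
    scale: bool = True,
) -> SparseModel:
    """Fit a two-class sparse PLS-DA model.

    ``keepx`` gives the number of genes with nonzero weight per component
    (a scalar is broadcast to every component). With keepx equal to the
    number of genes the fit coincides with :func:`ibdclass.plsda.fit_plsda`.
    """
    labels = pd.Series(list(labels), index=expr.columns)
    y_idx, classes = _check_two_classes(labels)
    X = expr.to_numpy(float).T
    keepx = _as_keepx(keepx, ncomp, X.shape[1])
    fit = _fit_core(
        X, y_idx, ncomp, scale=scale, keepx=keepx, order_key=_lex_order_key(expr.index)
    )
    base = _model_from_fit(fit, expr, labels, y_idx, classes, ncomp, scale)
    gene_arr = np.asarray(base.gene_ids, dtype=object)
    selected = [list(gene_arr[fit["W"][:, h] != 0.0]) for h in range(ncomp)]
    return SparseModel(**base.__dict__, keepx=keepx, selected=selected)


@dataclass(frozen=True)
class TuningResult:
    """Error curves and chosen keepX of the sequential grid search."""

    grid: tuple
    error_curve: pd.DataFrame  # columns: component, keepx, mean, sd
    chosen: tuple
    criterion: str
    seed: int


def _splsda_fit_predict(ncomp, keepx, scale, distance):
    """Array-level fit/predict closure for the CV loops."""

    def fp(X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray) -> np.ndarray:
        order = np.arange(X_tr.shape[1])
        fit = _fit_core(X_tr, y_tr, ncomp, scale=scale, keepx=keepx, order_key=order)
        means = _class_score_means(fit["T"], y_tr)
        return _predict_core(fit, X_te, means, distance)

    return fp


def tune_keepx(
    expr: pd.DataFrame,
    labels: Sequence,
    ncomp: int,
    grid: Sequence[int] = tuple(range(1, 301)),
    folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
    scale: bool = True,
    distance: str = "max_score",
    criterion: str = "ber",
) -> TuningResult:
    """Sequential per-component keepX search by repeated stratified CV.

    For component h, every grid value is evaluated with the previously
    chosen keepX for components 1..h-1 held fixed; the value minimizing the
    mean cross-validated error (``criterion``: ``"ber"`` balanced or
    ``"oer"`` overall) is chosen, ties going to the smaller keepX. Fold
    splits are stratified by class, shared across grid values and driven
    solely by ``seed``.
    """
    if criterion not in ("ber", "oer"):
        raise ValueError(f"criterion must be 'oer' or 'ber', got {criterion!r}")
    grid = tuple(sorted(int(g) for g in set(grid)))
    if not grid:
        raise ValueError("grid must be non-empty")
    labels = pd.Series(list(labels), index=expr.columns)
    y_idx, _ = _check_two_classes(labels)
    X = expr.to_numpy(float).T
    for g in grid:
        if not (1 <= g <= X.shape[1]):
            raise ValueError(f"grid value {g} out of range [1, {X.shape[1]}]")
    folds_list = _repeated_folds(y_idx, folds, repeats, seed)
    which = 1 if criterion == "ber" else 0
    chosen: list[int] = []
    rows = []
    for h in range(1, ncomp + 1):
        means = []
        for g in grid:
            fp = _splsda_fit_predict(h, tuple(chosen) + (g,), scale, distance)
            errs = _cv_errors_arrays(fp, X, y_idx, folds_list, folds)
            vals = np.array([e[which] for e in errs])
            rows.append(
                {
                    "component": h,
                    "keepx": g,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                }
            )
            means.append(float(vals.mean()))
        chosen.append(grid[int(np.argmin(means))])  # ascending grid: tie -> smaller
    return TuningResult(
        grid=grid,
        error_curve=pd.DataFrame(rows),
        chosen=tuple(chosen),
        criterion=criterion,
        seed=int(seed),
    )
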