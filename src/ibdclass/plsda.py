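"""Two-class partial least-squares discriminant analysis (PLS-DA).

PLS-DA encodes the two class labels as a centered indicator matrix Y and
extracts latent components t_h = X w_h whose covariance with the projected
indicator is maximal; after each component the predictor matrix is deflated
by its regression on the score (regression-mode deflation). For a two-class
problem the centered indicator columns are exact negatives of each other, so
each component weight has the closed form w_h  ∝  X_h' y_c (cross-covariance
with the centered first indicator column), which this implementation exploits
instead of running the NIPALS inner loop to convergence.

The module also provides the gene-pruning statistic used to remove strong
normal-tissue discriminators: the projection of each gene's loading vector
onto the unit direction connecting the two class centroids in score space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PLSModel",
    "fit_plsda",
    "predict_plsda",
    "class_direction_scores",
]

_EPS = np.finfo(float).eps


def _standardize(X: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center (and optionally unit-variance scale, ddof=1) the columns of X."""
    mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd < _EPS, 1.0, sd)
    else:
        sd = np.ones(X.shape[1])
    return (X - mean) / sd, mean, sd


def _indicator(y_idx: np.ndarray) -> np.ndarray:
    """n x 2 class-indicator matrix from 0/1 class indices."""
    Y = np.zeros((y_idx.shape[0], 2))
    Y[np.arange(y_idx.shape[0]), y_idx] = 1.0
    return Y


def _sparsify(w: np.ndarray, keepx: int, order_key: np.ndarray) -> np.ndarray:
    """Soft-threshold w so exactly ``keepx`` entries stay nonzero.

    The threshold is the (keepx+1)-th largest |w|; ties are broken by the
    lexicographic gene order given in ``order_key`` (an argsort key). Tied
    selected entries that a plain soft-threshold would zero out are given
    half the smallest surviving magnitude so the support size is exact.
    """
    p = w.shape[0]
    if keepx >= p:
        return w
    mag = np.abs(w)
    # sort by magnitude descending, gene order ascending for ties
    order = np.lexsort((order_key, -mag))
    selected = order[:keepx]
    lam = mag[order[keepx]]
    out = np.zeros_like(w)
    shrunk = mag[selected] - lam
    pos = shrunk[shrunk > 0]
    floor = (pos.min() / 2.0) if pos.size else 1.0
    out[selected] = np.sign(w[selected]) * np.maximum(shrunk, floor * (shrunk <= 0))
    return out


def _fit_core(
    X: np.ndarray,
    y_idx: np.ndarray,
    ncomp: int,
    scale: bool = True,
    keepx: Sequence[int] | None = None,
    order_key: np.ndarray | None = None,
) -> dict:
    """Fit the latent components on raw X (samples x genes) and 0/1 labels.

    Returns the fitted arrays; used by both the dense and the sparse front
    ends and by the cross-validation loops (no pandas overhead).
    """
    n, p = X.shape
    if ncomp < 1:
        raise ValueError("ncomp must be >= 1")
    Xd, x_mean, x_scale = _standardize(X, scale)
    Y = _indicator(y_idx)
    y_mean = Y.mean(axis=0)
    Yd = Y - y_mean
    if order_key is None:
        order_key = np.arange(p)

    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    C = np.zeros((2, ncomp))
    T = np.zeros((n, ncomp))
    for h in range(ncomp):
        w = Xd.T @ Yd[:, 0]
        nrm = np.linalg.norm(w)
        if nrm < 1e-12:
            raise ValueError(f"component {h + 1} is degenerate: ncomp exceeds the data rank")
        w = w / nrm
        if keepx is not None:
            w = _sparsify(w, int(keepx[h]), order_key)
            w = w / np.linalg.norm(w)
        # deterministic sign: largest-|w| entry positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            raise ValueError(f"component {h + 1} is degenerate: ncomp exceeds the data rank")
        c = Yd.T @ t / tt
        pl = Xd.T @ t / tt
        Xd = Xd - np.outer(t, pl)
        Yd = Yd - np.outer(t, c)
        W[:, h], P[:, h], C[:, h], T[:, h] = w, pl, c, t
    return {
        "W": W,
        "P": P,
        "C": C,
        "T": T,
        "x_mean": x_mean,
        "x_scale": x_scale,
        "y_mean": y_mean,
    }


def _rotation(W: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Projection matrix R with T_new = X_centered @ R (R = W (P'W)^-1)."""
    return W @ np.linalg.inv(P.T @ W)


def _predict_core(
    fit: dict,
    X_new: np.ndarray,
    class_means: np.ndarray,
    distance: str,
    ncomp: int | None = None,
) -> np.ndarray:
    """Predicted 0/1 class indices for raw X_new (samples x genes)."""
    h = fit["W"].shape[1] if ncomp is None else int(ncomp)
    Xc = (X_new - fit["x_mean"]) / fit["x_scale"]
    R = _rotation(fit["W"][:, :h], fit["P"][:, :h])
    T_new = Xc @ R
    if distance == "max_score":
        yhat = T_new @ fit["C"][:, :h].T + fit["y_mean"]
        return np.argmax(yhat, axis=1)  # tie -> first (alphabetical) class
    if distance == "centroid":
        d = ((T_new[:, None, :] - class_means[None, :, :h]) ** 2).sum(axis=2)
        return np.argmin(d, axis=1)
    raise ValueError(f"unknown distance {distance!r}")


def _class_score_means(T: np.ndarray, y_idx: np.ndarray) -> np.ndarray:
    return np.vstack([T[y_idx == g].mean(axis=0) for g in (0, 1)])


@dataclass
class PLSModel:
    """A fitted two-class PLS-DA model.

    ``x_weights`` are the unit-norm component weights, ``x_loadings`` the
    regression (projection) loadings used for deflation and prediction,
    ``class_score_means`` the per-class centroids in score space. Labels are
    stored sorted, so class 0 is the alphabetically first one.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    class_labels: tuple[str, str]
    ncomp: int
    scale: bool
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_weights: np.ndarray
    scores: np.ndarray
    centers: np.ndarray
    scales: np.ndarray
    y_means: np.ndarray
    class_score_means: np.ndarray
    _fit: dict = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serializable flat-array bundle."""
        return {
            "gene_ids": list(self.gene_ids),
            "sample_ids": list(self.sample_ids),
            "class_labels": list(self.class_labels),
            "ncomp": self.ncomp,
            "scale": self.scale,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_weights": self.y_weights.tolist(),
            "scores": self.scores.tolist(),
            "centers": self.centers.tolist(),
            "scales": self.scales.tolist(),
            "y_means": self.y_means.tolist(),
            "class_score_means": self.class_score_means.tolist(),
        }


def _check_two_classes(labels: pd.Series) -> tuple[np.ndarray, tuple[str, str]]:
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    counts = labels.value_counts()
    small = counts.idxmin()
    if counts.min() < 2:
        raise ValueError(f"class {small!r} has fewer than 2 samples")
    y_idx = np.asarray([classes.index(v) for v in labels], dtype=int)
    return y_idx, (str(classes[0]), str(classes[1]))


def _model_from_fit(
    fit: dict,
    expr: pd.DataFrame,
    labels: pd.Series,
    y_idx: np.ndarray,
    classes: tuple[str, str],
    ncomp: int,
    scale: bool,
) -> PLSModel:
    return PLSModel(
        gene_ids=list(expr.index),
        sample_ids=list(expr.columns),
        class_labels=classes,
        ncomp=ncomp,
        scale=scale,
        x_weights=fit["W"],
        x_loadings=fit["P"],
        y_weights=fit["C"],
        scores=fit["T"],
        centers=fit["x_mean"],
        scales=fit["x_scale"],
        y_means=fit["y_mean"],
        class_score_means=_class_score_means(fit["T"], y_idx),
        _fit=fit,
    )


def fit_plsda(
    expr: pd.DataFrame,
    labels: Sequence,
    ncomp: int,
    scale: bool = True,
) -> PLSModel:
    """Fit a two-class PLS-DA model on a genes x samples expression matrix.

    Parameters
    ----------
    expr
        log-expression matrix, genes in rows, samples in columns.
    labels
        one class label per sample (exactly two distinct values, each with
        at least two samples).
    ncomp
        number of latent components; must not exceed the data rank.
    scale
        center and unit-variance scale every gene before fitting (default).
    """
    labels = pd.Series(list(labels), index=expr.columns)
    y_idx, classes = _check_two_classes(labels)
    X = expr.to_numpy(float).T
    fit = _fit_core(X, y_idx, ncomp, scale=scale)
    return _model_from_fit(fit, expr, labels, y_idx, classes, ncomp, scale)


def predict_plsda(
    model: PLSModel,
    expr_new: pd.DataFrame,
    distance: str = "max_score",
    ncomp: int | None = None,
) -> pd.Series:
    """Predict class labels for new samples.

    ``max_score`` assigns the class whose predicted indicator value is
    largest; ``centroid`` the class whose mean score vector is nearest in
    latent space. Ties go to the alphabetically first class label.
    """
    missing = [g for g in model.gene_ids if g not in expr_new.index]
    if missing:
        raise ValueError(f"expression matrix is missing model gene {missing[0]!r}")
    X_new = expr_new.loc[model.gene_ids].to_numpy(float).T
    idx = _predict_core(model._fit, X_new, model.class_score_means, distance, ncomp)
    return pd.Series(
        [model.class_labels[i] for i in idx], index=expr_new.columns, name="predicted"
    )


def class_direction_scores(model: PLSModel) -> pd.Series:
    """Per-gene pruning statistic: |loading vector . inter-centroid direction|.

    The direction d connects the two class mean score vectors (unit length);
    the score of gene g is the absolute projection of its loading vector on
    d. Genes that strongly discriminate the two classes score high.
    """
    d = model.class_score_means[0] - model.class_score_means[1]
    nrm = np.linalg.norm(d)
    if nrm < 1e-12:
        raise ValueError("class centroids coincide: the inter-class direction is degenerate")
    d = d / nrm
    scores = np.abs(model.x_loadings @ d)
    return pd.Series(scores, index=model.gene_ids, name="prune_score")
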