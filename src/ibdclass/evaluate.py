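"""Stratified repeated k-fold cross-validation and error-rate reporting.

Two error rates are reported, matching the two numbers conventionally
quoted for discriminant models on unbalanced designs:

* overall error rate (OER) — misclassified / total, pooled over the k test
  folds of a repeat, then averaged over repeats;
* balanced error rate (BER) — the mean of per-class error rates, likewise
  averaged over repeats.

Folds are stratified by class: with a 13-sample class, unstratified 5-fold
splitting can produce test folds containing no member of one class, which
leaves the per-class error undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["CVReport", "stratified_folds", "cross_validate"]


@dataclass(frozen=True)
class CVReport:
    """Fold assignments and error rates of a repeated stratified k-fold CV."""

    folds: np.ndarray  # repeats x samples fold index
    per_repeat: list  # list of (oer, ber) tuples, one per repeat
    oer: float
    ber: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "oer": self.oer,
            "ber": self.ber,
            "per_repeat": [list(t) for t in self.per_repeat],
            "seed": self.seed,
        }


def stratified_folds(labels: Sequence, k: int, seed) -> np.ndarray:
    """Assign each sample to one of ``k`` folds, stratified by class.

    Within each class the samples are permuted by the seeded generator and
    dealt round-robin into the folds, so per-class fold sizes differ by at
    most one. ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fold = np.empty(labels.shape[0], dtype=int)
    for cls in sorted(pd.unique(labels)):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls!r} has {idx.size} samples, fewer than k={k}")
        perm = rng.permutation(idx)
        fold[perm] = np.arange(perm.size) % k
    return fold


def _error_rates(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """(overall, balanced) error rates over pooled predictions."""
    wrong = y_true != y_pred
    oer = float(wrong.mean())
    per_class = [float(wrong[y_true == c].mean()) for c in np.unique(y_true)]
    return oer, float(np.mean(per_class))


def _repeated_folds(labels: Sequence, k: int, repeats: int, seed: int) -> list[np.ndarray]:
    """One stratified fold assignment per repeat, all driven by ``seed``."""
    rng = np.random.default_rng(seed)
    return [stratified_folds(labels, k, rng) for _ in range(repeats)]


def _cv_errors_arrays(
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    X: np.ndarray,
    y_idx: np.ndarray,
    folds_list: list[np.ndarray],
    k: int,
) -> list[tuple[float, float]]:
    """Per-repeat (oer, ber) for an array-level fit/predict callable.

    ``fit_predict(X_train, y_train, X_test) -> predicted class indices``;
    used by the tuning and workflow loops to avoid pandas overhead.
    """
    out = []
    for fold in folds_list:
        pred = np.empty_like(y_idx)
        for f in range(k):
            te = fold == f
            tr = ~te
            pred[te] = fit_predict(X[tr], y_idx[tr], X[te])
        out.append(_error_rates(y_idx, pred))
    return out


def cross_validate(
    fitter: Callable,
    expr: pd.DataFrame,
    labels: Sequence,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold cross-validation of a fitting procedure.

    ``fitter(expr_train, labels_train)`` must return a callable mapping a
    held-out genes x samples expression matrix to predicted labels. Any
    feature selection or tuning the fitter performs happens inside each
    training fold, so no information leaks from the test fold. Within each
    repeat the fold predictions are pooled before computing the error
    rates, then rates are averaged over repeats.
    """
    labels = pd.Series(list(labels), index=expr.columns)
    folds_list = _repeated_folds(labels.to_numpy(), k, repeats, seed)
    y_true = labels.to_numpy()
    per_repeat: list[tuple[float, float]] = []
    for r, fold in enumerate(folds_list):
        pred = np.empty(y_true.shape[0], dtype=object)
        for f in range(k):
            te = fold == f
            tr = ~te
            try:
                predict = fitter(expr.iloc[:, tr], labels.iloc[tr])
                pred[te] = np.asarray(list(predict(expr.iloc[:, te])), dtype=object)
            except Exception as exc:  # noqa: BLE001 - annotate location, re-raise
                raise RuntimeError(f"fitter failed on repeat {r}, fold {f}: {exc}") from exc
        per_repeat.append(_error_rates(y_true, pred))
    oer = float(np.mean([t[0] for t in per_repeat]))
    ber = float(np.mean([t[1] for t in per_repeat]))
    return CVReport(
        folds=np.vstack(folds_list),
        per_repeat=per_repeat,
        oer=oer,
        ber=ber,
        seed=int(seed),
    )
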