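"""Dense PLS-DA: closed-form, SVD and scikit-learn oracles, prediction
rules and the centroid-direction pruning statistic."""

import numpy as np
import pandas as pd
import pytest

from ibdclass.plsda import (
    class_direction_scores,
    fit_plsda,
    predict_plsda,
)
from helpers import gaussian_two_class


def svd_pls_oracle(X, y01, ncomp, scale=True):
    """Independent SVD-based PLS-DA: weight = top singular vector of X_h'Y_c.

    Coded apart from the package's NIPALS-style routine; regression-mode
    deflation, no sign convention (comparisons are made up to sign).
    """
    X = np.asarray(X, float)
    Xd = X - X.mean(axis=0)
    if scale:
        Xd = Xd / X.std(axis=0, ddof=1)
    Y = np.zeros((X.shape[0], 2))
    Y[np.arange(X.shape[0]), y01] = 1.0
    Yd = Y - Y.mean(axis=0)
    Ws, Ts = [], []
    for _ in range(ncomp):
        U, s, Vt = np.linalg.svd(Xd.T @ Yd, full_matrices=False)
        w = U[:, 0]
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        c = Yd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, c)
        Ws.append(w)
        Ts.append(t)
    return np.column_stack(Ws), np.column_stack(Ts)


class TestFit:
    def test_separated_clouds_zero_training_error(self, small_two_class):
        expr, labels = small_two_class
        model = fit_plsda(expr, labels, ncomp=1)
        assert (predict_plsda(model, expr) == labels).all()

    def test_first_component_matches_cross_covariance_direction(self, small_two_class):
        expr, labels = small_two_class
        model = fit_plsda(expr, labels, ncomp=1)
        X = expr.to_numpy().T
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        y = (labels == "A").to_numpy(float)
        w_closed = Xs.T @ (y - y.mean())  # brute-force first-component direction
        w_closed /= np.linalg.norm(w_closed)
        cos = abs(w_closed @ model.x_weights[:, 0])
        assert cos > 1 - 1e-8

    def test_sample_duplication_leaves_weights_unchanged(self, small_two_class):
        expr, labels = small_two_class
        dup = pd.concat([expr, expr.add_suffix("_bis", axis=1)], axis=1)
        dup_labels = pd.Series(list(labels) * 2, index=dup.columns)
        m1 = fit_plsda(expr, labels, ncomp=2)
        m2 = fit_plsda(dup, dup_labels, ncomp=2)
        np.testing.assert_allclose(m1.x_weights, m2.x_weights, atol=1e-8)

    def test_score_columns_are_orthogonal(self):
        expr, labels = gaussian_two_class(np.random.default_rng(5), 15, 10, 40, 5, 1.0)
        model = fit_plsda(expr, labels, ncomp=4)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() / np.diag(G).max() < 1e-6

    def test_matches_independent_svd_pls(self, small_two_class):
        expr, labels = small_two_class
        model = fit_plsda(expr, labels, ncomp=2)
        W, T = svd_pls_oracle(expr.to_numpy().T, (labels == "B").to_numpy(int), 2)
        for h in range(2):
            sign = np.sign(W[:, h] @ model.x_weights[:, h])
            np.testing.assert_allclose(model.x_weights[:, h], sign * W[:, h], atol=1e-6)
            np.testing.assert_allclose(model.scores[:, h], sign * T[:, h], atol=1e-6)

    def test_matches_sklearn_plsregression(self):
        from sklearn.cross_decomposition import PLSRegression

        expr, labels = gaussian_two_class(np.random.default_rng(9), 12, 14, 25, 4, 1.2)
        model = fit_plsda(expr, labels, ncomp=3)
        Y = np.zeros((26, 2))
        Y[np.arange(26), (labels == "B").to_numpy(int)] = 1.0
        sk = PLSRegression(n_components=3, scale=True).fit(expr.to_numpy().T, Y)
        for h in range(3):
            a, b = model.x_weights[:, h], sk.x_weights_[:, h]
            assert abs(a @ b) / np.linalg.norm(b) > 1 - 1e-8

    @pytest.mark.parametrize(
        "labels, err",
        [
            (["A"] * 4 + ["B"] * 4 + ["C"] * 4, "exactly two classes"),
            (["A"] * 11 + ["B"], "fewer than 2 samples"),
        ],
    )
    def test_bad_labels_rejected(self, small_two_class, labels, err):
        expr, _ = small_two_class
        with pytest.raises(ValueError, match=err):
            fit_plsda(expr, labels, ncomp=1)

    def test_ncomp_beyond_rank_rejected(self):
        # rank-1 predictors: the second component must be degenerate
        u = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        expr = pd.DataFrame(
            np.outer(np.array([1.0, -2.0, 0.5]), u),
            index=["g1", "g2", "g3"],
            columns=[f"s{i}" for i in range(6)],
        )
        labels = ["A", "A", "A", "B", "B", "B"]
        with pytest.raises(ValueError, match="degenerate"):
            fit_plsda(expr, labels, ncomp=3, scale=False)


class TestPredict:
    def test_centroid_matches_brute_force_distances(self):
        expr, labels = gaussian_two_class(np.random.default_rng(2), 10, 10, 30, 3, 1.5)
        model = fit_plsda(expr, labels, ncomp=2)
        pred = predict_plsda(model, expr, distance="centroid")
        # independent exhaustive distance computation in score space
        R = model.x_weights @ np.linalg.inv(model.x_loadings.T @ model.x_weights)
        T = ((expr.to_numpy().T - model.centers) / model.scales) @ R
        for i, s in enumerate(expr.columns):
            d = [np.linalg.norm(T[i] - model.class_score_means[g]) for g in (0, 1)]
            assert pred[s] == model.class_labels[int(np.argmin(d))]

    def test_training_sample_at_centroid_gets_that_class(self):
        expr, labels = gaussian_two_class(np.random.default_rng(4), 8, 8, 12, 2, 2.0)
        model = fit_plsda(expr, labels, ncomp=2)
        # a synthetic sample whose scores sit exactly on class B's centroid
        R = model.x_weights @ np.linalg.inv(model.x_loadings.T @ model.x_weights)
        x_std, *_ = np.linalg.lstsq(R.T, model.class_score_means[1], rcond=None)
        probe = pd.DataFrame(
            (x_std * model.scales + model.centers).reshape(-1, 1),
            index=model.gene_ids,
            columns=["probe"],
        )
        assert predict_plsda(model, probe, distance="centroid")["probe"] == "B"

    def test_exact_tie_goes_to_alphabetically_first_label(self):
        from ibdclass.plsda import _predict_core

        fit = {
            "W": np.array([[1.0]]),
            "P": np.array([[1.0]]),
            "C": np.array([[1.0], [1.0]]),  # both classes score identically
            "x_mean": np.zeros(1),
            "x_scale": np.ones(1),
            "y_mean": np.array([0.5, 0.5]),
        }
        means = np.array([[1.0], [-1.0]])  # probe at 0: equidistant centroids
        X_new = np.zeros((1, 1))
        assert _predict_core(fit, X_new, means, "max_score")[0] == 0
        assert _predict_core(fit, X_new, means, "centroid")[0] == 0

    def test_missing_gene_named_in_error(self, small_two_class):
        expr, labels = small_two_class
        model = fit_plsda(expr, labels, ncomp=1)
        with pytest.raises(ValueError, match="g00"):
            predict_plsda(model, expr.drop(index="g00"))


class TestDirectionScores:
    def test_planted_single_discriminator_scores_highest(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr, labels = gaussian_two_class(rng, 12, 12, 30, n_signal=1, effect=3.0)
            model = fit_plsda(expr, labels, ncomp=2)
            scores = class_direction_scores(model)
            hits += scores.idxmax() == "g000"
        assert hits == 20

    def test_single_component_reduces_to_absolute_loading(self, small_two_class):
        expr, labels = small_two_class
        model = fit_plsda(expr, labels, ncomp=1)
        scores = class_direction_scores(model)
        np.testing.assert_allclose(scores, np.abs(model.x_loadings[:, 0]), atol=1e-12)

    def test_gene_permutation_permutes_scores(self, small_two_class):
        expr, labels = small_two_class
        perm = list(expr.index[::-1])
        s1 = class_direction_scores(fit_plsda(expr, labels, ncomp=2))
        s2 = class_direction_scores(fit_plsda(expr.loc[perm], labels, ncomp=2))
        pd.testing.assert_series_equal(s1.sort_index(), s2.sort_index(), atol=1e-10, rtol=0)

    def test_invariant_to_label_swap(self, small_two_class):
        expr, labels = small_two_class
        swapped = labels.map({"A": "B", "B": "A"})
        s1 = class_direction_scores(fit_plsda(expr, labels, ncomp=2))
        s2 = class_direction_scores(fit_plsda(expr, swapped, ncomp=2))
        pd.testing.assert_series_equal(s1, s2, atol=1e-10, rtol=0)
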