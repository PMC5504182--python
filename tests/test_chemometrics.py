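"""Tests of PCA screening and OPLS-DA: oracle equivalence with plain PLS,
orthogonality of the filtered scores, Q² behavior and permutation validity."""

import numpy as np
import pytest
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from nmrmetab.chemometrics import (
    OPLSDA,
    _q2_arrays,
    _permutation_arrays,
    cross_validated_q2,
    encode_classes,
    fit_opls_da,
    fit_pca,
    flag_outliers,
    loading_pseudospectrum,
    permutation_test,
)

from conftest import make_fm


def _two_group_data(rng, n_a=10, n_b=10, p=8, effect=0.0):
    X = rng.normal(size=(n_a + n_b, p))
    X[:n_a, 0] += effect
    labels = ["a"] * n_a + ["b"] * n_b
    return X, labels


class TestPca:
    def test_rank_one_data_has_unit_first_variance_fraction(self, rng):
        t = rng.normal(size=20)
        X = np.outer(t, [1.0, 2.0])  # exactly on a line
        res = fit_pca(X, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_are_orthonormal(self, rng):
        X = rng.normal(size=(30, 6))
        res = fit_pca(X, n_components=4)
        gram = res.loadings @ res.loadings.T
        assert np.allclose(gram, np.eye(4), atol=1e-8)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(15, 5))
        res = fit_pca(X, n_components=5)
        rec = res.scores @ res.loadings + res.mean
        assert np.allclose(rec, X, atol=1e-6)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError, match="rank"):
            fit_pca(rng.normal(size=(4, 10)), n_components=5)


class TestOutlierFlagging:
    def test_far_point_is_the_only_flag(self, rng):
        X = rng.normal(size=(50, 3))
        X[7] = 10.0  # ~10 sd from the cloud
        res = fit_pca(X, n_components=2)
        flagged = flag_outliers(res, alpha=0.01)
        assert flagged == [7]

    def test_brute_force_t2_agrees(self, rng):
        X = rng.normal(size=(40, 5))
        res = fit_pca(X, n_components=2)
        t2 = res.hotelling_t2()
        # oracle: componentwise score^2 / variance sums
        manual = np.array(
            [
                sum(res.scores[i, k] ** 2 / res.explained_variance[k] for k in range(2))
                for i in range(40)
            ]
        )
        assert np.allclose(t2, manual, atol=1e-10)
        n, k = 40, 2
        f_crit = stats.f.ppf(0.95, k, n - k)
        expected = k * (n - 1) * (n + 1) / (n * (n - k)) * f_crit
        assert res.t2_critical(0.05) == pytest.approx(expected)

    def test_alpha_near_one_flags_nothing_extreme(self, rng):
        X = rng.normal(size=(30, 4))
        res = fit_pca(X, n_components=2)
        # alpha is the tail probability: tiny alpha -> huge critical value -> no flags
        assert flag_outliers(res, alpha=1e-12) == []

    def test_false_positive_rate_calibrated(self, rng):
        X = rng.normal(size=(500, 5))
        res = fit_pca(X, n_components=2)
        frac = len(flag_outliers(res, alpha=0.05)) / 500
        assert 0.02 <= frac <= 0.09

    def test_invalid_alpha_rejected(self, rng):
        res = fit_pca(rng.normal(size=(20, 3)), n_components=2)
        with pytest.raises(ValueError, match="alpha"):
            res.t2_critical(alpha=1.5)


class TestClassEncoding:
    def test_centered_two_level_coding(self):
        y, pos, ref = encode_classes(["a", "a", "b", "b", "b"])
        assert pos == "b" and ref == "a"
        assert y.mean() == pytest.approx(0.0)
        assert len(np.unique(y)) == 2

    def test_three_classes_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            encode_classes(["a", "b", "c"])


class TestOplsDa:
    def test_single_informative_feature(self):
        X = np.array(
            [[1.0, 7.0, 0.1], [1.0, 7.0, 0.1], [1.0, 7.0, 0.1],
             [3.0, 7.0, 0.1], [3.0, 7.0, 0.1], [3.0, 7.0, 0.1]]
        )
        res = OPLSDA(X, ["a"] * 3 + ["b"] * 3, n_orthogonal=0).fit()
        assert abs(res.corr[0]) == pytest.approx(1.0, abs=1e-9)
        assert res.r2y == pytest.approx(1.0, abs=1e-9)
        assert res.corr[1] == 0.0 and res.cov[1] == 0.0  # constant feature

    @pytest.mark.parametrize("trial", range(10))
    def test_zero_orthogonal_components_is_plain_pls(self, trial):
        # oracle: scikit-learn's NIPALS PLS on the centered data
        rng = np.random.default_rng(100 + trial)
        X, labels = _two_group_data(rng, 8, 7, 6, effect=1.0)
        res = OPLSDA(X, labels, n_orthogonal=0).fit()
        y, _, _ = encode_classes(labels)
        Xc = X - X.mean(axis=0)
        pls = PLSRegression(n_components=1, scale=False).fit(Xc, y)
        w_sk = pls.x_weights_[:, 0]
        t_sk = pls.x_scores_[:, 0]
        sign = np.sign(w_sk @ res.weights)
        assert np.allclose(res.weights, sign * w_sk, atol=1e-9)
        assert np.allclose(res.scores_pred, sign * t_sk, atol=1e-9)

    def test_orthogonal_filter_recovers_clean_loading(self, rng):
        # plant a y-orthogonal component on top of clean two-group data
        X, labels = _two_group_data(rng, 12, 12, 10, effect=2.0)
        y, _, _ = encode_classes(labels)
        Xc = X - X.mean(axis=0)
        noise_dir = rng.normal(size=10)
        w_clean = Xc.T @ y
        w_clean /= np.linalg.norm(w_clean)
        noise_dir -= (noise_dir @ w_clean) * w_clean  # orthogonal to the PLS weight
        t_noise = rng.normal(size=24) * 5
        t_noise -= t_noise @ y / (y @ y) * y  # uncorrelated with y
        X_dirty = Xc + np.outer(t_noise, noise_dir)

        clean = OPLSDA(Xc, labels, n_orthogonal=0).fit()
        filtered = OPLSDA(X_dirty, labels, n_orthogonal=1).fit()
        sign = np.sign(clean.weights @ filtered.weights)
        assert np.allclose(filtered.weights, sign * clean.weights, atol=1e-6)

    def test_predictive_score_orthogonal_to_filtered_scores(self, rng):
        X, labels = _two_group_data(rng, 15, 10, 12, effect=1.5)
        res = OPLSDA(X, labels, n_orthogonal=3).fit()
        for t_o in res.ortho_scores:
            denom = np.linalg.norm(res.scores_pred) * np.linalg.norm(t_o)
            assert abs(res.scores_pred @ t_o) / denom < 1e-6

    def test_weight_vector_is_unit_norm(self, rng):
        X, labels = _two_group_data(rng, 8, 8, 5, effect=1.0)
        res = OPLSDA(X, labels, n_orthogonal=2).fit()
        assert np.linalg.norm(res.weights) == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= res.r2y <= 1.0

    def test_positive_class_scores_positive(self, rng):
        X, labels = _two_group_data(rng, 10, 10, 6, effect=2.0)
        res = OPLSDA(X, labels, n_orthogonal=1, positive_class="a").fit()
        mask = np.array(labels) == "a"
        assert res.scores_pred[mask].mean() > 0

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.raises(ValueError, match="two classes"):
            OPLSDA(X, ["a"] * 6).fit()

    def test_zero_variance_matrix_rejected(self):
        X = np.ones((6, 4))
        with pytest.raises(ValueError, match="zero-variance"):
            OPLSDA(X, ["a", "a", "a", "b", "b", "b"]).fit()


class TestPseudospectrum:
    def test_heights_match_brute_force_covariance(self, rng):
        X, labels = _two_group_data(rng, 9, 9, 7, effect=1.0)
        res = OPLSDA(X, labels, n_orthogonal=1).fit()
        table = loading_pseudospectrum(res)
        Xc = X - X.mean(axis=0)
        n = X.shape[0]
        manual = np.array(
            [
                sum(res.scores_pred[i] * Xc[i, j] for i in range(n)) / (n - 1)
                for j in range(X.shape[1])
            ]
        )
        assert np.allclose(table["covariance"], manual, atol=1e-12)
        assert ((table["r2"] >= 0) & (table["r2"] <= 1)).all()

    def test_perfectly_correlated_feature_has_color_one(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]])
        res = OPLSDA(X, ["a", "a", "b", "b"], n_orthogonal=0).fit()
        table = loading_pseudospectrum(res)
        assert table["r2"][0] == pytest.approx(1.0, abs=1e-9)
        assert table["r2"][1] == 0.0  # zero-variance feature


class TestQ2:
    def test_dominant_noiseless_feature_predicts_well(self, rng):
        n = 40
        labels = ["a"] * 20 + ["b"] * 20
        y, _, _ = encode_classes(labels)
        X = np.column_stack([y * 10, rng.normal(size=(n, 4)) * 0.01])
        q2 = _q2_arrays(X, y, 1, 7, seed=0)
        assert q2 >= 0.95

    def test_permuted_labels_give_low_q2(self, rng):
        n = 30
        labels = ["a"] * 15 + ["b"] * 15
        y, _, _ = encode_classes(labels)
        q2s = []
        for i in range(100):
            X = np.column_stack([y * 5, rng.normal(size=(n, 5))])
            yp = rng.permutation(y)
            q2s.append(_q2_arrays(X, yp, 1, 5, seed=i))
        assert np.median(q2s) < 0.1

    def test_q2_never_exceeds_one(self, rng):
        X, labels = _two_group_data(rng, 8, 8, 6, effect=3.0)
        y, _, _ = encode_classes(labels)
        assert _q2_arrays(X, y, 1, 4, seed=3) <= 1.0

    def test_q2_below_r2_on_informative_data(self, rng):
        X, labels = _two_group_data(rng, 12, 12, 8, effect=2.0)
        fm = make_fm(X, labels, normalized=True)
        fmp = fm.with_values(fm.values - fm.values.mean(), pareto=True)
        res = fit_opls_da(fmp, n_orthogonal=1)
        q2 = cross_validated_q2(fmp, n_orthogonal=1, folds=7, seed=0)
        assert q2 <= res.r2y + 1e-9

    def test_deterministic_given_seed(self, rng):
        X, labels = _two_group_data(rng, 10, 10, 6, effect=1.0)
        y, _, _ = encode_classes(labels)
        assert _q2_arrays(X, y, 1, 5, seed=42) == _q2_arrays(X, y, 1, 5, seed=42)


class TestPermutationTest:
    def test_plus_one_lower_bound(self, rng):
        X, labels = _two_group_data(rng, 8, 8, 5, effect=5.0)
        fm = make_fm(X, labels, normalized=True)
        fmp = fm.with_values(fm.values - fm.values.mean(), pareto=True)
        p = permutation_test(fmp, n_permutations=50, seed=0, folds=4)
        assert p >= 1 / 51

    def test_strong_separation_reaches_the_floor(self, rng):
        # effect 5 sd, n=20/group: no permuted Q2 should beat the observed
        X, labels = _two_group_data(rng, 20, 20, 6, effect=5.0)
        y, _, _ = encode_classes(labels)
        p, _ = _permutation_arrays(X, y, 1, 200, seed=1, folds=7)
        assert p == pytest.approx(1 / 201)

    def test_invariant_to_class_relabeling(self, rng):
        X, labels = _two_group_data(rng, 9, 11, 6, effect=1.0)
        y, _, _ = encode_classes(labels)
        flipped = [{"a": "b", "b": "a"}[l] for l in labels]
        y2, _, _ = encode_classes(flipped)
        p1, _ = _permutation_arrays(X, y, 1, 100, seed=5, folds=5)
        p2, _ = _permutation_arrays(X, y2, 1, 100, seed=5, folds=5)
        assert p1 == p2

    def test_degenerate_labels_rejected(self, rng):
        X = rng.normal(size=(8, 4))
        with pytest.raises(ValueError, match="degenerate|two classes"):
            _permutation_arrays(X, np.zeros(8), 1, 10, seed=0, folds=3)
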