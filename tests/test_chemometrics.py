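import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from ftirage.chemometrics import (
    CVSpec,
    DataMatrix,
    PLSModel,
    flag_outliers,
    nipals_pls1,
    pca_fit,
    pearson_r,
    pls_fit,
    q_residuals,
    score_discrimination,
    select_n_factors,
)
from ftirage.errors import (
    DegenerateDataError,
    GroupError,
    RankError,
    ShapeError,
)


def data_matrix(X):
    X = np.asarray(X, float)
    meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(X.shape[0])]})
    return DataMatrix(X, meta, np.arange(X.shape[1], dtype=float))


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(0)
    return data_matrix(rng.normal(size=(20, 50)))


class TestPCA:
    def test_rank_one_data_explained_by_pc1(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=15)
        direction = rng.normal(size=8)
        X = 3.0 + np.outer(t, direction)
        model = pca_fit(data_matrix(X), 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(RankError):
            pca_fit(data_matrix(X), 2)

    def test_full_reconstruction_identity(self, random_matrix):
        model = pca_fit(random_matrix, min(random_matrix.X.shape[0] - 1, 19))
        Xc = random_matrix.X - model.column_means
        recon = model.scores @ model.loadings.T
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_loadings_orthonormal_variance_sorted(self, random_matrix):
        model = pca_fit(random_matrix, 7)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(7), atol=1e-8)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_row_permutation_equivariance(self, random_matrix):
        model = pca_fit(random_matrix, 3)
        perm = np.random.default_rng(3).permutation(random_matrix.X.shape[0])
        permuted = data_matrix(random_matrix.X[perm])
        model_p = pca_fit(permuted, 3)
        # loadings may flip sign; compare projections of the same rows
        for k in range(3):
            s = np.sign(model.loadings[:, k] @ model_p.loadings[:, k])
            np.testing.assert_allclose(
                model.scores[perm, k] * s, model_p.scores[:, k], atol=1e-8
            )


class TestQResiduals:
    def test_in_span_rows_have_zero_q(self, random_matrix):
        model = pca_fit(random_matrix, 4)
        X = np.vstack(
            [
                model.column_means,
                model.column_means + 5.0 * model.loadings[:, 0],
                model.column_means - 2.0 * model.loadings[:, 2],
            ]
        )
        q = q_residuals(model, data_matrix(X))
        np.testing.assert_allclose(q, 0.0, atol=1e-10)

    def test_orthogonal_component_norm_squared(self, random_matrix):
        model = pca_fit(random_matrix, 4)
        rng = np.random.default_rng(4)
        v = rng.normal(size=model.loadings.shape[0])
        v -= model.loadings @ (model.loadings.T @ v)
        v *= 3.0 / np.linalg.norm(v)
        X = np.vstack([model.column_means + v] * 3)
        q = q_residuals(model, data_matrix(X))
        np.testing.assert_allclose(q, 9.0, atol=1e-8)

    def test_invariant_to_in_span_shifts(self, random_matrix):
        model = pca_fit(random_matrix, 4)
        q0 = q_residuals(model, random_matrix)
        shift = model.loadings @ np.array([1.0, -2.0, 0.5, 3.0])
        shifted = data_matrix(random_matrix.X + shift)
        np.testing.assert_allclose(q_residuals(model, shifted), q0, atol=1e-8)

    def test_column_mismatch_rejected(self, random_matrix):
        model = pca_fit(random_matrix, 2)
        with pytest.raises(ShapeError):
            q_residuals(model, data_matrix(np.ones((3, 5))))


class TestFlagOutliers:
    def test_mad_rule_flags_the_spike(self):
        flags = flag_outliers(np.array([1.0, 1.0, 1.0, 1.0, 100.0]))
        assert flags.tolist() == [False, False, False, False, True]

    def test_identical_values_never_flagged(self):
        assert not flag_outliers(np.full(10, 2.5)).any()

    def test_quantile_rule_counts(self):
        q = np.arange(100.0)
        assert flag_outliers(q, rule="quantile", k=0.95).sum() == 5


class TestPLS:
    def test_noiseless_rank3_recovered_with_three_factors(self):
        rng = np.random.default_rng(5)
        basis = rng.normal(size=(3, 50))
        T = rng.normal(size=(20, 3))
        X = T @ basis
        y = X @ rng.normal(size=50)
        model = pls_fit(data_matrix(X), y, max_factors=3, cv=None)
        assert model.max_factors == 3
        assert pearson_r(y, model.predict(X)) > 0.999

    def test_kernel_matches_nipals_oracle(self, random_matrix):
        rng = np.random.default_rng(6)
        y = rng.normal(size=20)
        model = pls_fit(random_matrix, y, max_factors=5, cv=None)
        y_nipals, _ = nipals_pls1(random_matrix.X, y, 5)
        np.testing.assert_allclose(model.predict(random_matrix.X), y_nipals, atol=1e-8)

    def test_kernel_matches_sklearn(self, random_matrix):
        rng = np.random.default_rng(7)
        y = rng.normal(size=20)
        model = pls_fit(random_matrix, y, max_factors=4, cv=None)
        sk = PLSRegression(n_components=4, scale=False).fit(random_matrix.X, y)
        np.testing.assert_allclose(
            model.predict(random_matrix.X),
            sk.predict(random_matrix.X).ravel(),
            atol=1e-8,
        )

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=30)
        model = pls_fit(data_matrix(X), y, max_factors=6, cv=None)
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(30), X]), y, rcond=None
        )
        ols_pred = beta[0] + X @ beta[1:]
        np.testing.assert_allclose(model.predict(X), ols_pred, atol=1e-6)

    def test_scores_mutually_orthogonal(self, random_matrix):
        y = np.random.default_rng(9).normal(size=20)
        model = pls_fit(random_matrix, y, max_factors=5, cv=None)
        gram = model.T.T @ model.T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-6 * np.linalg.norm(model.T)

    def test_constant_x_degenerate(self):
        X = np.ones((10, 4))
        with pytest.raises(DegenerateDataError):
            pls_fit(data_matrix(X), np.arange(10.0), cv=None)

    def test_constant_y_degenerate(self, random_matrix):
        with pytest.raises(DegenerateDataError):
            pls_fit(random_matrix, np.ones(20), cv=None)

    def test_prediction_shift_with_constant_y_offset(self, random_matrix):
        rng = np.random.default_rng(10)
        y = rng.normal(size=20)
        m1 = pls_fit(random_matrix, y, max_factors=3, cv=None)
        m2 = pls_fit(random_matrix, y + 100.0, max_factors=3, cv=None)
        np.testing.assert_allclose(
            m2.predict(random_matrix.X), m1.predict(random_matrix.X) + 100.0,
            atol=1e-8,
        )

    def test_grouped_cv_holds_out_whole_groups(self, random_matrix):
        rng = np.random.default_rng(11)
        y = rng.normal(size=20)
        groups = np.repeat(np.arange(10), 2)
        model = pls_fit(
            random_matrix, y, max_factors=2, cv=CVSpec(n_folds=5, seed=0),
            groups=groups,
        )
        assert model.y_cv.shape == (20, 2)
        assert not np.any(np.isnan(model.y_cv[:, 0]))


class TestFactorSelection:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            # brute-force evaluation of the 2% parsimony band: the band is
            # [2.9, 2.958]; 3.0 misses it, so three factors are needed
            ((5.0, 3.0, 2.9, 2.95), 3),
            ((9.0, 5.0, 3.0, 1.0), 4),
            ((2.0, 2.0, 2.0), 1),
        ],
    )
    def test_parsimony_rule(self, curve, expected):
        model = PLSModel(
            x_mean=np.zeros(2), y_mean=0.0,
            W=np.zeros((2, len(curve))), P=np.zeros((2, len(curve))),
            q=np.zeros(len(curve)), R=np.zeros((2, len(curve))),
            T=np.zeros((3, len(curve))), cv_rmse=np.array(curve),
        )
        assert select_n_factors(model) == expected
        # independent brute-force scan of the stated rule
        band = 1.02 * min(curve)
        brute = min(i + 1 for i, v in enumerate(curve) if v <= band)
        assert select_n_factors(model) == brute


class TestDiscrimination:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, -1.0, -2.0])
        labels = np.array(["old", "old", "old", "young", "young"])
        res = score_discrimination(scores, labels, "old")
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_eight_of_ten_vs_six_of_eight(self):
        scores = np.concatenate([np.r_[np.ones(8), -np.ones(2)],
                                 np.r_[-np.ones(6), np.ones(2)]])
        labels = np.array(["old"] * 10 + ["young"] * 8)
        res = score_discrimination(scores, labels, "old")
        assert res.sensitivity == pytest.approx(80.0)
        assert res.specificity == pytest.approx(75.0)
        assert (res.tp, res.fn, res.tn, res.fp) == (8, 2, 6, 2)

    def test_sign_invariance_with_auto_orientation(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=18)
        labels = np.array(["old"] * 9 + ["young"] * 9)
        a = score_discrimination(scores, labels, "old")
        b = score_discrimination(-scores, labels, "old")
        assert (a.tp, a.fn, a.tn, a.fp) == (b.tp, b.fn, b.tn, b.fp)
        assert a.flipped != b.flipped

    def test_empty_group_rejected(self):
        with pytest.raises(GroupError):
            score_discrimination(np.ones(3), ["old"] * 3, "young")


class TestPearson:
    def test_affine_and_anticorrelated(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(a, 2 * a + 1) == pytest.approx(1.0)
        assert pearson_r(a, -a) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])
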