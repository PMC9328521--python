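import numpy as np
import pytest

from tcam import (
    MTransform,
    TCAM,
    center_mdf,
    choose_q_by_variance,
    fit,
    loadings_matrix,
    make_m_transform,
    mean_sample,
    ranking_vector,
    scores,
    transform,
    truncate_model,
)
from conftest import random_mdf_tensor


def pca_identity_m():
    return MTransform(np.array([[1.0]]), kind="custom")


class TestCentering:
    def test_mean_of_identical_slices(self):
        s = np.arange(12.0).reshape(1, 4, 3)
        a = np.repeat(s, 2, axis=0)
        assert np.array_equal(mean_sample(a), s)

    def test_opposite_slices_cancel(self, rng):
        s = rng.standard_normal((1, 4, 3))
        a = np.concatenate([s, -s], axis=0)
        assert np.allclose(mean_sample(a), 0.0)

    def test_matches_loop_oracle(self, rng):
        a = rng.standard_normal((10, 4, 3))
        expected = sum(a[i] for i in range(10)) / 10
        assert np.allclose(mean_sample(a)[0], expected, atol=1e-14)

    def test_center_is_idempotent_and_mdf(self, rng):
        a = rng.standard_normal((6, 4, 3))
        c, a_bar = center_mdf(a)
        assert np.linalg.norm(mean_sample(c)) < 1e-12
        c2, _ = center_mdf(c)
        assert np.allclose(c2, c, atol=1e-14)

    def test_single_subject_centers_to_zero(self, rng):
        a = rng.standard_normal((1, 4, 3))
        c, _ = center_mdf(a)
        assert np.allclose(c, 0.0)


class TestRankingVector:
    def test_sort_example(self):
        s_hat = np.array([[3.0, 2.0], [1.0, 0.5]])  # faces: (3,1), (2,0.5)
        r = ranking_vector(s_hat)
        assert r.pairs() == [(0, 0), (0, 1), (1, 0), (1, 1)]
        assert np.array_equal(r.sigma, [3.0, 2.0, 1.0, 0.5])

    def test_tie_break_contract(self):
        r = ranking_vector(np.ones((2, 2)))
        assert r.pairs() == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_sigma_is_sorted_multiset(self, rng):
        s_hat = rng.uniform(0, 5, size=(4, 3))
        r = ranking_vector(s_hat)
        assert np.array_equal(r.sigma, np.sort(s_hat.ravel())[::-1])
        assert len(set(r.pairs())) == 12

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ranking_vector(np.array([[1.0, -0.1]]))


class TestFit:
    def test_explained_variance_arithmetic(self, rng, dct4):
        # plant known hat-domain singular values via a diagonal tensor
        from tcam import mode3_inverse

        sig = np.array([3.0, 2.0, 1.0, 0.5])
        hat = np.zeros((2, 2, 4))
        hat[0, 0, :2] = sig[:2]
        hat[1, 1, 2:] = sig[2:]
        a = mode3_inverse(hat, dct4)
        a = np.concatenate([a, -a], axis=0)  # MDF by symmetry, m=4
        model = fit(a, dct4)
        top4 = model.explained_variance[:4]
        expected = np.array([9, 4, 1, 0.25])
        # centering and stacking rescale uniformly, so fractions match
        expected = expected / expected.sum() * top4.sum()
        assert np.allclose(top4, expected, atol=1e-12)
        assert np.isclose(model.explained_variance.sum(), 1.0, atol=1e-12)

    def test_single_component_tensor(self, rng):
        from tcam import mode3_inverse

        mt = make_m_transform(4, "haar_random", seed=0)
        u = rng.standard_normal((5, 1))
        u -= u.mean()  # centered -> the tensor is already MDF
        v = rng.standard_normal((7, 1))
        hat = np.zeros((5, 7, 4))
        hat[:, :, 2] = u @ v.T  # a single nonzero hat-domain component
        model = fit(mode3_inverse(hat, mt), mt)
        assert model.explained_variance[0] > 1 - 1e-12
        assert np.all(model.explained_variance[1:] < 1e-12)

    def test_degenerate_variance_raises(self, dct4, rng):
        slice_ = rng.standard_normal((1, 3, 4))
        a = np.repeat(slice_, 4, axis=0)
        with pytest.raises(ValueError, match="degenerate"):
            fit(a, dct4)

    def test_too_few_subjects(self, dct4, rng):
        with pytest.raises(ValueError):
            fit(rng.standard_normal((1, 3, 4)), dct4)

    def test_determinism(self, rng, dct4):
        a = rng.standard_normal((5, 7, 4))
        m1, m2 = fit(a, dct4), fit(a, dct4)
        assert np.array_equal(m1.training_scores_, m2.training_scores_)
        assert np.array_equal(m1.v, m2.v)
        assert np.array_equal(m1.explained_variance, m2.explained_variance)


class TestScores:
    def test_copies_of_mean_give_zero(self, dct4, rng):
        a = rng.standard_normal((4, 5, 4))
        model = fit(a, dct4)
        copies = np.repeat(mean_sample(a), 3, axis=0)
        assert np.max(np.abs(scores(model, copies))) < 1e-10

    def test_eq2_path_matches_u_sigma(self, rng, dct4):
        a = rng.standard_normal((5, 7, 4))
        model = fit(a, dct4)
        z = scores(model, a)
        assert np.max(np.abs(z - model.training_scores_)) < 1e-10

    def test_gram_matrix_preserved_at_full_rank(self, rng, dct4):
        a = rng.standard_normal((5, 7, 4))
        model = fit(a, dct4)
        z = scores(model, a)
        c = a - a.mean(axis=0, keepdims=True)
        unfolded = c.reshape(5, -1)
        assert np.max(np.abs(z @ z.T - unfolded @ unfolded.T)) < 1e-8

    def test_column_variance_proportional_to_sigma_squared(self, rng, dct4):
        a = rng.standard_normal((6, 8, 4))
        model = fit(a, dct4)
        z = scores(model, a)
        col_ss = np.sum(z**2, axis=0)
        assert np.allclose(col_ss, model.ranking.sigma**2, rtol=1e-8)
        assert np.all(np.diff(col_ss) <= 1e-8)

    def test_shape_mismatch(self, rng, dct4):
        model = fit(rng.standard_normal((5, 7, 4)), dct4)
        with pytest.raises(ValueError):
            scores(model, rng.standard_normal((5, 6, 4)))


class TestTransform:
    def test_mean_maps_to_zero(self, rng, dct4):
        a = rng.standard_normal((5, 7, 4))
        model = fit(a, dct4)
        assert np.max(np.abs(transform(model, mean_sample(a)))) < 1e-12

    def test_training_slice_reproduces_score_row(self, rng, dct4):
        a = rng.standard_normal((5, 7, 4))
        model = fit(a, dct4)
        z = scores(model, a)
        for i in range(5):
            zi = transform(model, a[i])
            assert np.max(np.abs(zi - z[i])) < 1e-10

    def test_linearity_about_the_mean(self, rng, dct4):
        a = rng.standard_normal((5, 7, 4))
        model = fit(a, dct4)
        d = rng.standard_normal((1, 7, 4))
        a_bar = mean_sample(a)
        z1 = transform(model, a_bar + d)
        z2 = transform(model, a_bar + 2 * d)
        assert np.max(np.abs(z2 - 2 * z1)) < 1e-10


class TestLoadings:
    def test_rows_unit_norm(self, rng, dct4):
        model = fit(rng.standard_normal((5, 7, 4)), dct4)
        l = loadings_matrix(model)
        assert l.shape == (model.q, 7)
        assert np.allclose(np.linalg.norm(l, axis=1), 1.0, atol=1e-10)

    def test_same_face_rows_orthogonal(self, rng, dct4):
        model = fit(rng.standard_normal((5, 7, 4)), dct4)
        l = loadings_matrix(model)
        face = model.ranking.face
        for h in range(len(face)):
            for h2 in range(h + 1, len(face)):
                if face[h] == face[h2]:
                    assert abs(l[h] @ l[h2]) < 1e-10


class TestPcaDegeneration:
    def test_scores_loadings_variance_match_pca(self, rng):
        a = rng.standard_normal((8, 5, 1))
        model = fit(a, pca_identity_m())
        z = scores(model, a)
        l = loadings_matrix(model)

        x = a[:, :, 0] - a[:, :, 0].mean(axis=0)
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        z_pca = u * s
        ev_pca = s**2 / np.sum(s**2)

        sign = np.sign(np.sum(z * z_pca, axis=0))
        assert np.max(np.abs(z - z_pca * sign)) < 1e-10
        assert np.max(np.abs(l - vt * sign[:, None])) < 1e-10
        assert np.allclose(model.explained_variance, ev_pca, atol=1e-12)


class TestTruncationAndQ:
    def test_nesting(self, rng, dct4):
        a = rng.standard_normal((5, 7, 4))
        model = fit(a, dct4)
        small = truncate_model(model, 2)
        z_full = scores(model, a)
        z_small = scores(small, a)
        assert np.array_equal(z_small, z_full[:, :2])
        assert np.array_equal(loadings_matrix(small),
                              loadings_matrix(model)[:2])

    def test_full_q_is_identity(self, rng, dct4):
        model = fit(rng.standard_normal((5, 7, 4)), dct4)
        assert truncate_model(model, model.n_components).q == model.n_components

    def test_q_out_of_range(self, rng, dct4):
        model = fit(rng.standard_normal((5, 7, 4)), dct4)
        with pytest.raises(ValueError):
            truncate_model(model, 0)
        with pytest.raises(ValueError):
            truncate_model(model, model.n_components + 1)

    def test_choose_q_by_variance(self, rng, dct4):
        model = fit(rng.standard_normal((5, 7, 4)), dct4)
        model.explained_variance = np.array([0.7, 0.2, 0.1] + [0.0] * 17)
        assert choose_q_by_variance(model, 0.85) == 2
        assert choose_q_by_variance(model, 0.7) == 1
        assert choose_q_by_variance(model, 1.0) == 3
        with pytest.raises(ValueError):
            choose_q_by_variance(model, 0.0)
        with pytest.raises(ValueError):
            choose_q_by_variance(model, 1.5)


class TestModelPersistence:
    def test_save_load_round_trip(self, rng, dct4, tmp_path):
        a = rng.standard_normal((5, 7, 4))
        model = fit(a, dct4, feature_labels=[f"f{j}" for j in range(7)],
                    timepoint_labels=list("abcd"))
        model.save(tmp_path / "model.npz")
        back = type(model).load(tmp_path / "model.npz")
        assert np.array_equal(scores(back, a), scores(model, a))
        assert back.feature_labels == model.feature_labels


class TestVarianceAndDistortionOptimality:
    """The fitted map beats random pseudo ⋆_M-orthogonal rank-q competitors
    on captured variance and configuration distortion."""

    @staticmethod
    def competitor_scores(a_mdf, mt, q, rng):
        from tcam import mode3_product

        m, p, n = a_mdf.shape
        k = min(m, p)
        w_hat = np.empty((p, k, n))
        for i in range(n):
            w_hat[:, :, i] = np.linalg.qr(rng.standard_normal((p, k)))[0]
        a_hat = mode3_product(a_mdf, mt)
        z_hat = np.einsum("ipn,pkn->ikn", a_hat, w_hat)
        cells = rng.choice(k * n, size=q, replace=False)
        return z_hat[:, cells // n, cells % n]

    def test_tcam_maximizes_variance_and_minimizes_distortion(self, rng):
        mt = make_m_transform(3, "dct2")
        a = random_mdf_tensor(rng, 6, 8, 3)
        model = fit(a, mt)
        unfolded = a.reshape(6, -1)
        gram = unfolded @ unfolded.T
        for q in (1, 2, 5):
            z = scores(truncate_model(model, q), a)
            var_tcam = np.trace(z.T @ z)
            dist_tcam = np.linalg.norm(gram - z @ z.T, ord="nuc")
            for _ in range(50):
                zc = self.competitor_scores(a, mt, q, rng)
                assert var_tcam >= np.trace(zc.T @ zc) - 1e-9
                assert dist_tcam <= np.linalg.norm(gram - zc @ zc.T, ord="nuc") + 1e-9

    def test_zero_distortion_at_full_rank(self, rng):
        mt = make_m_transform(3, "dct2")
        a = random_mdf_tensor(rng, 5, 6, 3)
        model = fit(a, mt)
        z = scores(model, a)
        unfolded = a.reshape(5, -1)
        assert np.linalg.norm(unfolded @ unfolded.T - z @ z.T, ord="nuc") < 1e-8


class TestSklearnStyleWrapper:
    def test_fit_transform_matches_functions(self, rng, dct4):
        a = rng.standard_normal((5, 7, 4))
        est = TCAM(m_transform=dct4, q=3)
        z = est.fit_transform(a)
        assert z.shape == (5, 3)
        assert np.array_equal(z, scores(truncate_model(fit(a, dct4), 3), a))
        assert est.explained_variance_ratio_.shape == (3,)
        z_new = est.transform(a[0])
        assert np.max(np.abs(z_new[0] - z[0])) < 1e-10
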