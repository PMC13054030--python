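import numpy as np
import pytest

from sheddetect.o2pls import O2PLS, cross_validate, default_grid, preprocess, inverse_preprocess


def _match_up_to_sign(A, B, atol):
    """Columns of A equal columns of B up to sign."""
    assert A.shape == B.shape
    for j in range(A.shape[1]):
        d = min(np.abs(A[:, j] - B[:, j]).max(), np.abs(A[:, j] + B[:, j]).max())
        assert d < atol, f"column {j} deviates by {d}"


def _planted(rng, N=20, p=30, q=25, noise=0.02):
    w = rng.normal(size=p); w /= np.linalg.norm(w)
    c = rng.normal(size=q); c /= np.linalg.norm(c)
    wx = rng.normal(size=p); wx -= w * (w @ wx); wx /= np.linalg.norm(wx)
    t = rng.normal(size=N) * 3
    t_orth = rng.normal(size=N) * 1.5
    X = np.outer(t, w) + np.outer(t_orth, wx) + noise * rng.normal(size=(N, p))
    Y = np.outer(t, c) + noise * rng.normal(size=(N, q))
    return X, Y, w, c, wx


class TestPreprocess:
    def test_centering_idempotent(self, rng):
        X = rng.normal(size=(10, 5))
        Xc, _ = preprocess(X)
        Xcc, _ = preprocess(Xc)
        np.testing.assert_allclose(Xc, Xcc, atol=1e-12)

    def test_roundtrip(self, rng):
        X = rng.normal(size=(12, 6)) * 4 + 3
        Xp, rec = preprocess(X, scale="unit_variance")
        np.testing.assert_allclose(inverse_preprocess(Xp, rec), X, atol=1e-12)

    def test_constant_column_with_scaling_errors(self, rng):
        X = rng.normal(size=(8, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="GENE_B"):
            preprocess(X, scale="unit_variance", feature_names=["GENE_A", "GENE_B", "GENE_C"])


class TestFit:
    def test_joint_loadings_equal_cross_svd(self, rng):
        X = rng.normal(size=(20, 15))
        Y = rng.normal(size=(20, 10))
        for n in (1, 2, 3):
            model = O2PLS(n_joint=n, center=False).fit(X, Y)
            U, _, Vt = np.linalg.svd(X.T @ Y)
            _match_up_to_sign(model.W_, U[:, :n], 1e-8)
            _match_up_to_sign(model.C_, Vt[:n].T, 1e-8)

    def test_rank_one_self_integration(self, rng):
        t = rng.normal(size=12)
        w = rng.normal(size=8)
        X = np.outer(t, w)
        model = O2PLS(n_joint=1, center=False).fit(X, X.copy())
        r = np.corrcoef(model.T_[:, 0], model.U_[:, 0])[0, 1]
        assert abs(r) > 1 - 1e-10
        assert np.linalg.norm(model.E_) < 1e-10
        assert np.linalg.norm(model.F_) < 1e-10

    def test_planted_joint_loading_recovered(self):
        rng = np.random.default_rng(5)
        X, Y, w, c, _ = _planted(rng)
        model = O2PLS(n_joint=1, n_orth_x=1).fit(X, Y)
        assert abs(model.W_[:, 0] @ w) > 0.95
        assert abs(model.C_[:, 0] @ c) > 0.95

    def test_reconstruction_and_energy_partition(self, rng):
        for _ in range(10):
            N, p, q = 15, 12, 9
            X = rng.normal(size=(N, p))
            Y = rng.normal(size=(N, q))
            model = O2PLS(n_joint=2, n_orth_x=1, n_orth_y=2).fit(X, Y)
            for block, M in (("X", X), ("Y", Y)):
                Mc = M - M.mean(axis=0)
                joint = model.joint_part(block)
                orth = model.orthogonal_part(block)
                resid = model.residual(block)
                np.testing.assert_allclose(joint + orth + resid, Mc, atol=1e-10)
                total = np.linalg.norm(Mc) ** 2
                parts = sum(np.linalg.norm(m) ** 2 for m in (joint, orth, resid))
                assert abs(total - parts) / total < 1e-8

    def test_systematic_is_input_minus_residual(self, rng):
        X = rng.normal(size=(14, 10))
        Y = rng.normal(size=(14, 8))
        model = O2PLS(n_joint=2, n_orth_x=1, n_orth_y=1).fit(X, Y)
        np.testing.assert_allclose(
            model.systematic_part("X"), (X - X.mean(0)) - model.E_, atol=1e-10
        )

    def test_without_orthogonal_systematic_equals_joint(self, rng):
        X = rng.normal(size=(10, 6))
        Y = rng.normal(size=(10, 5))
        model = O2PLS(n_joint=2).fit(X, Y)
        np.testing.assert_allclose(model.systematic_part("X"), model.joint_part("X"), atol=1e-12)

    def test_noiseless_planted_systematic_equals_input(self):
        rng = np.random.default_rng(9)
        X, Y, *_ = _planted(rng, noise=0.0)
        model = O2PLS(n_joint=1, n_orth_x=1).fit(X, Y)
        np.testing.assert_allclose(model.systematic_part("X"), X - X.mean(0), atol=1e-8)

    def test_orthogonal_component_never_raises_own_residual(self, rng):
        X = rng.normal(size=(16, 12))
        Y = rng.normal(size=(16, 9))
        prev = None
        for nx in (0, 1, 2):
            model = O2PLS(n_joint=2, n_orth_x=nx).fit(X, Y)
            resid = np.linalg.norm(model.E_) ** 2
            if prev is not None:
                assert resid <= prev + 1e-10
            prev = resid

    def test_orthogonal_components_capped_by_joint_rank(self, rng):
        # sequential extraction exhausts span((I-WW')X'XW) after n steps
        X = rng.normal(size=(16, 12))
        Y = rng.normal(size=(16, 9))
        with pytest.raises(ValueError, match="only 1 attainable"):
            O2PLS(n_joint=1, n_orth_x=2).fit(X, Y)

    def test_sample_permutation_equivariance(self, rng):
        X = rng.normal(size=(12, 8))
        Y = rng.normal(size=(12, 6))
        perm = rng.permutation(12)
        a = O2PLS(n_joint=2, n_orth_x=1, n_orth_y=1).fit(X, Y)
        b = O2PLS(n_joint=2, n_orth_x=1, n_orth_y=1).fit(X[perm], Y[perm])
        np.testing.assert_allclose(a.T_[perm], b.T_, atol=1e-8)
        np.testing.assert_allclose(a.T_yosc_[perm], b.T_yosc_, atol=1e-8)
        np.testing.assert_allclose(a.U_xosc_[perm], b.U_xosc_, atol=1e-8)

    def test_sign_convention_fixed(self, rng):
        X = rng.normal(size=(11, 7))
        Y = rng.normal(size=(11, 5))
        model = O2PLS(n_joint=2, n_orth_x=1, n_orth_y=1).fit(X, Y)
        for L in (model.W_, model.C_, model.P_yosc_, model.P_xosc_):
            for j in range(L.shape[1]):
                assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_loading_orthonormality_and_score_near_orthogonality(self, rng):
        X = rng.normal(size=(15, 10))
        Y = rng.normal(size=(15, 8))
        model = O2PLS(n_joint=2, n_orth_x=2, n_orth_y=1).fit(X, Y)
        np.testing.assert_allclose(model.W_.T @ model.W_, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(model.C_.T @ model.C_, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(model.P_yosc_.T @ model.P_yosc_, np.eye(2), atol=1e-10)
        # joint and orthogonal loadings of a block are mutually orthogonal
        np.testing.assert_allclose(model.P_yosc_.T @ model.W_, 0, atol=1e-10)
        np.testing.assert_allclose(model.P_xosc_.T @ model.C_, 0, atol=1e-10)

    def test_infeasible_components_error(self, rng):
        X = rng.normal(size=(6, 5))
        Y = rng.normal(size=(6, 4))
        with pytest.raises(ValueError, match="N >"):
            O2PLS(n_joint=3, n_orth_x=3).fit(X, Y)
        with pytest.raises(ValueError, match="min\\(p, q"):
            O2PLS(n_joint=5).fit(X, Y)

    def test_rank_deficiency_reports_attainable(self, rng):
        t = rng.normal(size=10)
        X = np.outer(t, rng.normal(size=6))
        Y = np.outer(t, rng.normal(size=5))
        with pytest.raises(ValueError, match="at most"):
            O2PLS(n_joint=3, center=False).fit(X, Y)

    def test_save_load_roundtrip(self, rng, tmp_path):
        X = rng.normal(size=(10, 7))
        Y = rng.normal(size=(10, 6))
        model = O2PLS(n_joint=2, n_orth_x=1).fit(X, Y)
        path = tmp_path / "model.npz"
        model.save(path)
        back = O2PLS.load(path)
        np.testing.assert_array_equal(model.W_, back.W_)
        np.testing.assert_array_equal(model.E_, back.E_)
        np.testing.assert_allclose(
            model.predict(X, block="Y"), back.predict(X, block="Y"), atol=1e-12
        )


class TestCrossValidation:
    def test_noiseless_rank_one_selects_parsimonious_joint(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=20)
        X = np.outer(t, rng.normal(size=10))
        Y = np.outer(t, rng.normal(size=8))
        X += 1e-6 * rng.normal(size=X.shape)  # break exact rank deficiency
        Y += 1e-6 * rng.normal(size=Y.shape)
        sel = cross_validate(X, Y, grid=[(1, 0, 0), (2, 0, 0)], seed=0)
        assert sel.n_joint == 1

    def test_independent_noise_selects_single_component(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 12))
        Y = rng.normal(size=(30, 10))
        sel = cross_validate(X, Y, grid=[(n, 0, 0) for n in (1, 2, 3)], seed=1)
        assert sel.n_joint == 1
        errs = sel.cv_error.sort_values("n_joint")["error"].to_numpy()
        assert errs[0] <= errs[1] <= errs[2]

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(20, 8))
        Y = rng.normal(size=(20, 6))
        a = cross_validate(X, Y, grid=default_grid(2, 1), seed=7)
        b = cross_validate(X, Y, grid=default_grid(2, 1), seed=7)
        assert (a.n_joint, a.n_orth_x, a.n_orth_y) == (b.n_joint, b.n_orth_x, b.n_orth_y)
        np.testing.assert_array_equal(a.cv_error["error"], b.cv_error["error"])

    def test_small_folds_rejected(self, rng):
        X = rng.normal(size=(8, 5))
        Y = rng.normal(size=(8, 4))
        with pytest.raises(ValueError, match="at least 2"):
            cross_validate(X, Y, grid=[(1, 0, 0)], k_folds=5)

    def test_empty_grid_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        Y = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="empty"):
            cross_validate(X, Y, grid=[])
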