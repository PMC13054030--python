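import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sheddetect.diffexpr import (
    bh_adjust,
    call_differential,
    estimate_common_dispersion,
    exact_test_pvalues_for_total,
    moderated_t,
    nb_exact_test,
    tmm_factors,
)
from sheddetect.io import ExpressionMatrix, SampleDesign


def _design(n_ctrl, n_kd, prefix=("c", "k")):
    ids = [f"{prefix[0]}{i}" for i in range(n_ctrl)] + [f"{prefix[1]}{i}" for i in range(n_kd)]
    return ids, SampleDesign(pd.DataFrame({
        "sample_id": ids,
        "condition": ["control"] * n_ctrl + ["knockdown"] * n_kd,
    }))


def _counts(matrix, ids=None):
    matrix = np.asarray(matrix, float)
    ids = ids or [f"s{i}" for i in range(matrix.shape[0])]
    return ExpressionMatrix(matrix, ids, [f"g{j}" for j in range(matrix.shape[1])], "counts")


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


class TestTMM:
    def test_global_scaling_absorbed_by_library_size(self, rng):
        base = rng.poisson(100, size=(1, 50))
        em = _counts(np.vstack([base, 2 * base, 5 * base]))
        np.testing.assert_allclose(tmm_factors(em).to_numpy(), 1.0, atol=1e-12)

    def test_identical_samples_unit_factors(self):
        em = _counts([[10, 20, 30], [10, 20, 30]])
        np.testing.assert_allclose(tmm_factors(em).to_numpy(), [1, 1], atol=1e-12)

    def test_four_gene_hand_computed_factor(self):
        # one asymmetric gene; weighted trimmed mean of M-values worked out
        # by explicit enumeration of M, A and precision weights
        em = _counts([[100, 200, 300, 400], [100, 200, 300, 4000]], ids=["A", "B"])
        f = tmm_factors(em, reference="A")
        np.testing.assert_allclose(f["A"], 1.9176502472788537, rtol=1e-9)
        np.testing.assert_allclose(f["B"], 0.5214715255918019, rtol=1e-9)
        np.testing.assert_allclose(np.exp(np.mean(np.log(f))), 1.0, atol=1e-12)

    def test_all_zero_sample_errors(self):
        em = _counts([[0, 0, 0], [1, 2, 3]])
        with pytest.raises(ValueError, match="zero library"):
            tmm_factors(em)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------


class TestDispersion:
    def test_poisson_counts_give_near_zero(self):
        rng = np.random.default_rng(7)
        ids, design = _design(6, 6)
        mu = rng.uniform(50, 500, size=2000)
        em = _counts(rng.poisson(mu, size=(12, 2000)), ids)
        d = estimate_common_dispersion(em, design)
        assert d.common_dispersion < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(8)
        ids, design = _design(6, 6)
        phi = 0.2
        mu = rng.uniform(50, 500, size=2000)
        lam = rng.gamma(1 / phi, phi, size=(12, 2000)) * mu
        em = _counts(rng.poisson(lam), ids)
        d = estimate_common_dispersion(em, design)
        assert 0.15 <= d.common_dispersion <= 0.25

    def test_constant_counts_give_zero(self):
        ids, design = _design(3, 3)
        em = _counts(np.full((6, 50), 20.0), ids)
        assert estimate_common_dispersion(em, design).common_dispersion == 0.0


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------


def brute_force_exact_p(total, n1, n2, dispersion):
    """Independent enumeration oracle using scipy NB/binomial pmfs."""
    ks = np.arange(total + 1)
    if dispersion == 0:
        w = stats.binom.pmf(ks, total, n1 / (n1 + n2))
    else:
        r1, r2 = n1 / dispersion, n2 / dispersion
        w = stats.nbinom.pmf(ks, r1, 0.5) * stats.nbinom.pmf(total - ks, r2, 0.5)
        w = w / w.sum()
    out = np.empty(total + 1)
    for k in ks:
        out[k] = w[w <= w[k] * (1 + 1e-12)].sum()
    return np.minimum(out, 1.0)


class TestExactTest:
    @pytest.mark.parametrize("dispersion", [0.0, 0.1])
    @pytest.mark.parametrize("total", [10, 20, 30])
    def test_matches_enumeration_oracle(self, total, dispersion):
        got = exact_test_pvalues_for_total(total, 6, 6, dispersion)
        want = brute_force_exact_p(total, 6, 6, dispersion)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_poisson_limit_binomial_sum_of_extreme_splits(self):
        # total 20 split 10/10 between equal groups: every split enumerated
        p = exact_test_pvalues_for_total(20, 5, 5, 0.0)
        w = stats.binom.pmf(np.arange(21), 20, 0.5)
        expected_at_3 = w[w <= w[3] * (1 + 1e-12)].sum()
        np.testing.assert_allclose(p[3], expected_at_3, atol=1e-12)
        assert p[10] == pytest.approx(1.0)

    def test_identical_groups_p_one(self):
        ids, design = _design(3, 3)
        em = _counts(np.tile([[7, 30, 100]], (6, 1)), ids)
        res = nb_exact_test(em, design, dispersion=0.1)
        np.testing.assert_allclose(res["pvalue"], 1.0)
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)

    def test_zero_count_feature_untestable(self):
        ids, design = _design(2, 2)
        em = _counts([[0, 5], [0, 6], [0, 7], [0, 8]], ids)
        res = nb_exact_test(em, design, dispersion=0.0)
        assert bool(res.loc[res["feature_id"] == "g0", "untestable"].iloc[0])
        assert res.loc[res["feature_id"] == "g0", "pvalue"].iloc[0] == 1.0

    def test_power_monotone_in_effect_size(self):
        # effect planted in a quarter of the genes so normalization cannot
        # absorb it; median p over the planted subset falls as |log2FC| grows
        rng = np.random.default_rng(21)
        ids, design = _design(6, 6)
        med_p = []
        for lfc in (0.5, 1.0, 1.5):
            mu = np.full(400, 200.0)
            kd_mu = mu.copy()
            kd_mu[:100] *= 2.0**lfc
            counts = np.vstack([
                rng.poisson(mu, size=(6, 400)),
                rng.poisson(kd_mu, size=(6, 400)),
            ])
            res = nb_exact_test(_counts(counts, ids), design, dispersion=0.05)
            med_p.append(np.median(res["pvalue"][:100]))
        assert med_p[0] > med_p[1] > med_p[2]


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def _log_em(matrix, ids):
    return ExpressionMatrix(matrix, ids, [f"p{j}" for j in range(matrix.shape[1])],
                            "log_intensities")


class TestModeratedT:
    def test_zero_prior_df_equals_student_t(self, rng):
        ids, design = _design(5, 5)
        X = rng.normal(0, 1, size=(10, 60))
        res = moderated_t(_log_em(X, ids), design, prior_df=0.0)
        ref = stats.ttest_ind(X[5:], X[:5], equal_var=True)
        np.testing.assert_allclose(res["pvalue"], ref.pvalue, atol=1e-10)
        np.testing.assert_allclose(res["log2fc"], X[5:].mean(0) - X[:5].mean(0), atol=1e-12)

    def test_infinite_prior_pools_variance(self, rng):
        ids, design = _design(4, 4)
        X = rng.normal(0, 1, size=(8, 50))
        res = moderated_t(_log_em(X, ids), design, prior_df=np.inf)
        order_t = np.argsort(np.abs(res["tstat"].to_numpy()))
        order_d = np.argsort(np.abs(res["log2fc"].to_numpy()))
        np.testing.assert_array_equal(order_t, order_d)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(42)
        ids, design = _design(5, 5)
        X = rng.normal(0, 1, size=(10, 500))
        res = moderated_t(_log_em(X, ids), design)
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_missing_values_reduce_df_and_flag_untestable(self, rng):
        ids, design = _design(3, 3)
        X = rng.normal(0, 1, size=(6, 3))
        X[0:2, 0] = np.nan          # 1 control obs left -> untestable
        X[0, 1] = np.nan            # 2 control obs left -> still testable
        res = moderated_t(_log_em(X, ids), design)
        assert bool(res["untestable"][0])
        assert not bool(res["untestable"][1])

    def test_zero_variance_feature_floored_not_fatal(self):
        ids, design = _design(3, 3)
        X = np.ones((6, 2))
        X[:, 1] = [0, 0.1, -0.2, 1.4, 1.2, 1.6]
        res = moderated_t(_log_em(X, ids), design)
        assert np.isfinite(res["pvalue"]).all()


# ---------------------------------------------------------------------------
# BH and calling
# ---------------------------------------------------------------------------


def bh_oracle(p):
    """Definitional step-up: q_i = min over j with p_(j) >= p_(i) of p_(j)*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q_sorted, 1.0)
    return out


class TestBH:
    def test_textbook_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms(use_true_random=False))
    def test_permutation_equivariant(self, p, rnd):
        p = np.asarray(p)
        perm = np.asarray(rnd.sample(range(len(p)), len(p)))
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[0])


class TestCallDifferential:
    def _frame(self, log2fc, fdr):
        return pd.DataFrame({"feature_id": ["f"], "log2fc": [log2fc], "fdr": [fdr]})

    def test_fc_boundary_is_strict(self):
        res = call_differential(self._frame(np.log2(1.2), 0.001), fc_threshold=1.2)
        assert not res["significant"].iloc[0]

    def test_fdr_boundary_is_strict(self):
        res = call_differential(self._frame(1.0, 0.05), fc_threshold=1.5)
        assert not res["significant"].iloc[0]

    def test_downregulation_called(self):
        res = call_differential(self._frame(-1.0, 0.001), fc_threshold=1.5)
        assert res["significant"].iloc[0]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_differential(self._frame(1, 0.01), fc_threshold=0.9)
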