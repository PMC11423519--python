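import numpy as np
import pytest
from scipy import stats

from mimicbench.da_tests import (
    ancom_w_test,
    ks_test,
    linear_model_test,
    moderated_t_test,
    t_test,
    wilcoxon_test,
)


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        m = np.array([[1.0] * 10])
        labels = np.array([0] * 5 + [1] * 5)
        assert wilcoxon_test(m, labels).p[0] == 1.0

    def test_exact_complete_separation(self):
        """10 vs 10 fully separated distinct values: exact p = 2 / C(20,10)."""
        m = np.arange(20, dtype=float)[None, :]
        labels = np.array([0] * 10 + [1] * 10)
        res = wilcoxon_test(m, labels)
        assert res.p[0] == pytest.approx(2 / 184_756, rel=1e-9)

    def test_single_stratum_equals_naive(self):
        rng = np.random.default_rng(0)
        m = rng.random((5, 30))
        labels = (np.arange(30) % 2).astype(int)
        naive = wilcoxon_test(m, labels)
        blocked = wilcoxon_test(m, labels, block=np.zeros(30, dtype=int))
        assert np.allclose(blocked.p, naive.p)

    def test_blocked_raises_p_on_confounder_feature(self):
        # feature driven entirely by the stratum, stratum correlated with label
        rng = np.random.default_rng(1)
        stratum = np.array([0] * 30 + [1] * 30)
        labels = np.concatenate([rng.permutation([0] * 24 + [1] * 6),
                                 rng.permutation([0] * 6 + [1] * 24)])
        m = (stratum * 2.0 + rng.normal(0, 0.5, 60))[None, :]
        p_naive = wilcoxon_test(m, labels).p[0]
        p_blocked = wilcoxon_test(m, labels, block=stratum).p[0]
        assert p_blocked > p_naive

    def test_empty_stratum_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        m = rng.random((2, 20))
        labels = np.array([0, 1] * 8 + [0, 0, 0, 0])
        block = np.array([0] * 16 + [1] * 4)  # stratum 1 has no group-1 samples
        with pytest.warns(UserWarning, match="dropped"):
            res = wilcoxon_test(m, labels, block=block)
        assert np.all((res.p >= 0) & (res.p <= 1))


class TestTTest:
    def test_equal_values_p_one(self):
        m = np.array([[3.0] * 8])
        labels = np.array([0] * 4 + [1] * 4)
        assert t_test(m, labels).p[0] == 1.0

    def test_zero_within_variance_contract(self):
        m = np.array([[0.0, 0, 0, 0, 1, 1, 1, 1]])
        labels = np.array([0] * 4 + [1] * 4)
        res = t_test(m, labels)
        assert res.p[0] == 1.0
        assert res.flags["degenerate_variance"][0]

    def test_welch_hand_computation(self):
        """{1..5} vs {3..7}: t = -2/sqrt(2.5/5 + 2.5/5) = -2, df = 8, p = 0.0805
        (cross-checked against R's t.test)."""
        m = np.array([[1, 2, 3, 4, 5, 3, 4, 5, 6, 7]], dtype=float)
        labels = np.array([1] * 5 + [0] * 5)  # group1 - group0 = -2
        res = t_test(m, labels)
        assert res.statistic[0] == pytest.approx(-2.0, abs=1e-9)
        assert res.p[0] == pytest.approx(0.08051624, abs=1e-6)


class TestKS:
    def test_identical_samples(self):
        m = np.array([[1.0, 2, 3, 1, 2, 3]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = ks_test(m, labels)
        assert res.statistic[0] == 0.0
        assert res.p[0] == 1.0

    def test_full_separation_d_one(self):
        m = np.array([[1, 2, 3, 10, 20, 30]], dtype=float)
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert ks_test(m, labels).statistic[0] == 1.0

    def test_interleaved_d_third(self):
        m = np.array([[1, 2, 3, 1.5, 2.5, 3.5]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert ks_test(m, labels).statistic[0] == pytest.approx(1 / 3)


class TestLinearModel:
    def test_naive_equals_pooled_t(self):
        """OLS F-test on a binary predictor is the pooled t-test (F = t^2)."""
        rng = np.random.default_rng(3)
        m = rng.normal(size=(20, 40))
        labels = (np.arange(40) < 20).astype(int)
        res = linear_model_test(m, labels)
        t_pooled = stats.ttest_ind(m[:, labels == 1], m[:, labels == 0], axis=1, equal_var=True)
        assert np.allclose(res.p, t_pooled.pvalue, atol=1e-12)
        assert np.allclose(res.statistic, t_pooled.statistic**2, atol=1e-9)

    def test_single_level_covariate_reduces_to_naive(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(5, 30))
        labels = (np.arange(30) % 2).astype(int)
        naive = linear_model_test(m, labels)
        rand = linear_model_test(m, labels, covariate=np.ones(30), covariate_role="random")
        assert np.allclose(rand.p, naive.p, atol=1e-6)

    def test_frisch_waugh_fixed_adjustment(self):
        """With label orthogonal to the covariate, the fixed-adjusted label p
        matches the naive p computed on covariate-residualized data."""
        rng = np.random.default_rng(5)
        n = 40
        labels = np.tile([0, 1], n // 2).astype(float)
        cov = np.repeat([0, 1], n // 2).astype(float)  # orthogonal to labels
        m = 3.0 * cov + rng.normal(size=(8, n))
        fixed = linear_model_test(m, labels, covariate=cov, covariate_role="fixed")
        resid = m - np.outer(m @ (cov - cov.mean()) / ((cov - cov.mean()) ** 2).sum(),
                             cov - cov.mean())
        naive_resid = linear_model_test(resid, labels)
        # same t up to the one-df difference in the residual variance estimate
        assert np.allclose(np.abs(fixed.statistic),
                           np.sqrt(naive_resid.statistic) * np.sqrt(37 / 38), rtol=1e-6)

    def test_mixed_model_adjusts_confounded_feature(self):
        rng = np.random.default_rng(6)
        conf = np.array([0] * 30 + [1] * 30)
        labels = np.concatenate([rng.permutation([0] * 24 + [1] * 6),
                                 rng.permutation([0] * 6 + [1] * 24)])
        m = (conf * 3.0 + rng.normal(0, 1, 60))[None, :]
        p_naive = linear_model_test(m, labels).p[0]
        p_mixed = linear_model_test(m, labels, covariate=conf, covariate_role="random").p[0]
        assert p_mixed > p_naive


class TestModeratedT:
    def test_null_pvalues_uniform(self):
        """On Gaussian nulls the moderated p-values are ~Uniform(0, 1)."""
        rng = np.random.default_rng(7)
        m = rng.normal(size=(1000, 20))
        labels = (np.arange(20) % 2).astype(int)
        res = moderated_t_test(m, labels)
        assert stats.kstest(res.p, "uniform").pvalue > 0.01

    def test_detects_strong_shift(self):
        rng = np.random.default_rng(8)
        m = rng.normal(size=(50, 20))
        labels = (np.arange(20) % 2).astype(int)
        m[0, labels == 1] += 5.0
        res = moderated_t_test(m, labels)
        assert res.p[0] < 1e-4
        assert res.p[0] == res.p.min()

    def test_equal_variances_pool(self):
        """When residual variances are (nearly) identical, d0 -> inf and the
        statistic uses the pooled variance."""
        rng = np.random.default_rng(9)
        base = rng.normal(size=(200, 30))
        # force all features to the same residual scale
        labels = (np.arange(30) % 2).astype(int)
        resid_sd = base.std(axis=1, keepdims=True)
        m = base / resid_sd
        res = moderated_t_test(m, labels)
        assert np.isinf(res.flags["d0"]) or res.flags["d0"] > 50


class TestAncomW:
    def test_null_scores_near_one(self):
        rng = np.random.default_rng(10)
        m = np.abs(rng.normal(10, 1, size=(20, 30)))
        labels = (np.arange(30) % 2).astype(int)
        res = ancom_w_test(m, labels)
        assert not res.is_pvalue
        assert np.median(res.p) > 0.5

    def test_single_scaled_feature_discovered(self):
        rng = np.random.default_rng(11)
        m = np.abs(rng.normal(10, 1, size=(20, 40)))
        labels = (np.arange(40) % 2).astype(int)
        m[0, labels == 1] *= 50
        res = ancom_w_test(m, labels)
        assert res.statistic[0] >= 0.7 * (m.shape[0] - 1)
        assert res.p[0] < 0.05

    def test_score_strictly_decreasing_in_w(self):
        from mimicbench.da_tests import ancom_w_test as _  # noqa: F401
        # reconstruct the mapping over the full W range for m = 50
        m = 50
        tau = 0.7 * (m - 1)
        w = np.arange(m)
        score = np.where(
            w >= tau,
            0.05 * (1.0 - (w - tau + 0.5) / (m - tau)),
            1.0 - 0.95 * w / tau,
        )
        assert np.all(np.diff(score) < 0)
        assert score[w >= tau].max() < 0.05
        assert score[w < tau].min() >= 0.05

    def test_too_few_features(self):
        with pytest.raises(ValueError):
            ancom_w_test(np.ones((2, 10)), (np.arange(10) % 2).astype(int))


class TestPermutationInvariance:
    @pytest.mark.parametrize("runner", [
        lambda m, lab: wilcoxon_test(m, lab).p,
        lambda m, lab: t_test(m, lab).p,
        lambda m, lab: linear_model_test(m, lab).p,
        lambda m, lab: moderated_t_test(m, lab).p,
    ], ids=["wilcoxon", "ttest", "lm", "modt"])
    def test_sample_permutation_leaves_p_unchanged(self, runner):
        rng = np.random.default_rng(12)
        m = rng.normal(size=(10, 30))
        labels = (np.arange(30) % 2).astype(int)
        perm = rng.permutation(30)
        assert np.allclose(runner(m, labels), runner(m[:, perm], labels[perm]), atol=1e-9)
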