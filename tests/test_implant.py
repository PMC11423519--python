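import numpy as np
import pytest

from mimicbench.containers import CountMatrix
from mimicbench.implant import (
    implant_abundance,
    implant_compositional,
    implant_prevalence,
    implant_signal,
    select_da_features,
    split_groups,
)


class TestSplitGroups:
    @pytest.mark.parametrize("n,expect", [(100, {50}), (101, {50, 51})])
    def test_balanced_partition(self, n, expect):
        cm = CountMatrix(np.ones((2, n), dtype=int), ["a", "b"], [f"s{i}" for i in range(n)])
        labels = split_groups(cm, seed=0)
        assert {int((labels == 0).sum()), int((labels == 1).sum())} <= expect | {50, 51}
        assert abs((labels == 0).sum() - (labels == 1).sum()) <= 1

    def test_deterministic(self, baseline_cm):
        assert np.array_equal(split_groups(baseline_cm, 7), split_groups(baseline_cm, 7))

    def test_too_few_samples(self):
        cm = CountMatrix(np.ones((1, 3), dtype=int), ["a"], ["s0", "s1", "s2"])
        with pytest.raises(ValueError):
            split_groups(cm, 0)


class TestSelectFeatures:
    def test_fraction_count(self):
        cm = CountMatrix(
            np.ones((300, 10), dtype=int), [f"f{i}" for i in range(300)], [f"s{i}" for i in range(10)]
        )
        assert len(select_da_features(cm, 0.1, seed=0)) == 30

    def test_fraction_zero_empty(self, baseline_cm):
        assert select_da_features(baseline_cm, 0.0, seed=0) == []

    def test_low_mode_excludes_prevalent(self):
        # feature "dense" non-zero in 60% of samples: its 75th percentile > 0
        counts = np.zeros((10, 20), dtype=int)
        counts[0, :12] = 5
        ids = ["dense"] + [f"rare{i}" for i in range(9)]
        for i in range(1, 10):
            counts[i, i] = 1
        cm = CountMatrix(counts, ids, [f"s{j}" for j in range(20)])
        for seed in range(10):
            assert "dense" not in select_da_features(cm, 0.3, mode="low", seed=seed)

    def test_pool_exhaustion_errors(self, small_cm):
        with pytest.raises(ValueError, match="pool"):
            select_da_features(small_cm, 1.0, seed=0, exclude=small_cm.feature_ids[:2])


class TestPrevalenceShift:
    def _cm(self):
        # one feature: 10 non-zeros in group 0 (donor), 5 zeros in group 1
        counts = np.zeros((1, 20), dtype=int)
        counts[0, :10] = 7  # donor group samples, all non-zero
        counts[0, 10:15] = 3  # target group non-zero
        labels = np.array([0] * 10 + [1] * 10)
        cm = CountMatrix(counts, ["f"], [f"s{i}" for i in range(20)])
        return cm, labels

    def test_shift_zero_unchanged(self):
        cm, labels = self._cm()
        out = implant_prevalence(cm, labels, ["f"], 0.0, {"f": 1}, seed=0)
        assert np.array_equal(out.counts, cm.counts)

    def test_exact_swap_count_and_zero_conservation(self):
        cm, labels = self._cm()
        out = implant_prevalence(cm, labels, ["f"], 0.2, {"f": 1}, seed=0)
        # round(0.2 * 10 donors) = 2 swaps into the 5 target zeros
        assert (out.counts[0, labels == 1] > 0).sum() == 5 + 2
        assert (out.counts[0, labels == 0] > 0).sum() == 10 - 2
        assert (out.counts == 0).sum() == (cm.counts == 0).sum()

    def test_no_zeros_available_no_error(self):
        counts = np.ones((1, 10), dtype=int) * 4  # target group has no zeros
        cm = CountMatrix(counts, ["f"], [f"s{i}" for i in range(10)])
        labels = np.array([0] * 5 + [1] * 5)
        out = implant_prevalence(cm, labels, ["f"], 0.5, {"f": 1}, seed=0)
        assert np.array_equal(out.counts, cm.counts)


class TestAbundanceScaling:
    def test_scale_one_identity(self, small_cm):
        labels = np.array([0, 1] * 3)
        out = implant_abundance(small_cm, labels, ["fA"], 1.0, {"fA": 1})
        assert out is small_cm

    def test_integer_scaling(self):
        counts = np.array([[7, 7, 0, 7]])
        cm = CountMatrix(counts, ["f"], list("abcd"))
        labels = np.array([1, 1, 1, 0])
        out = implant_abundance(cm, labels, ["f"], 2.0, {"f": 1})
        assert out.counts.tolist() == [[14, 14, 0, 7]]

    def test_round_half_up_with_floor(self):
        counts = np.array([[1, 2, 0]])
        cm = CountMatrix(counts, ["f"], list("abc"))
        labels = np.array([1, 1, 1])
        out = implant_abundance(cm, labels, ["f"], 1.25, {"f": 1})
        # 1*1.25 -> 1.25 -> round-half-up 1 (floor 1 keeps prevalence); 2*1.25 -> 2.5 -> 3
        assert out.counts.tolist() == [[1, 3, 0]]

    def test_zero_pattern_conserved(self, baseline_cm):
        ds = implant_signal(baseline_cm, seed=4, scale=20.0, shift=0.0)
        assert np.array_equal(ds.cm.counts == 0, baseline_cm.counts == 0)


class TestImplantSignal:
    def test_null_faithfulness(self, baseline_cm):
        ds = implant_signal(baseline_cm, seed=9, scale=1.0, shift=0.0)
        assert np.array_equal(ds.cm.counts, baseline_cm.counts)

    def test_determinism(self, baseline_cm):
        a = implant_signal(baseline_cm, seed=5, scale=2.0, shift=0.2)
        b = implant_signal(baseline_cm, seed=5, scale=2.0, shift=0.2)
        assert np.array_equal(a.cm.counts, b.cm.counts)
        assert a.truth.features == b.truth.features
        assert np.array_equal(a.labels, b.labels)

    def test_balanced_alternation(self, baseline_cm):
        ds = implant_signal(baseline_cm, seed=5, scale=2.0, shift=0.2, balanced=True)
        dirs = list(ds.truth.direction.values())
        assert abs(dirs.count(0) - dirs.count(1)) <= 1

    def test_strong_effect_all_retained(self, baseline_cm):
        ds = implant_signal(baseline_cm, seed=5, scale=20.0, shift=0.3)
        assert ds.truth.rejected == []
        assert all(abs(g) >= 1e-3 for f, g in ds.truth.gfc.items() if f in ds.truth.feature_set)

    def test_gfc_monotone_in_effect_size(self, baseline_cm):
        """Mean |gFC| over implanted features grows with scale and shift."""
        by_scale = [
            np.mean(np.abs(list(implant_signal(baseline_cm, 5, scale=s, shift=0.0).truth.gfc.values())))
            for s in (1.0, 2.0, 5.0, 20.0)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(by_scale, by_scale[1:]))
        by_shift = [
            np.mean(np.abs(list(implant_signal(baseline_cm, 5, scale=1.0, shift=s).truth.gfc.values())))
            for s in (0.0, 0.1, 0.2, 0.3)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(by_shift, by_shift[1:]))


class TestCompositional:
    def test_totals_preserved_under_pure_scaling(self, baseline_cm):
        ds = implant_compositional(baseline_cm, seed=3, scale=10.0, shift=0.0)
        assert np.array_equal(ds.cm.counts.sum(axis=0), baseline_cm.counts.sum(axis=0))

    def test_null_is_identity(self, baseline_cm):
        ds = implant_compositional(baseline_cm, seed=3, scale=1.0, shift=0.0)
        assert np.array_equal(ds.cm.counts, baseline_cm.counts)

    def test_background_depleted_in_implanted_group(self, baseline_cm):
        ds = implant_compositional(baseline_cm, seed=3, scale=10.0, shift=0.0)
        rel = ds.cm.relative_abundance()
        bg = [i for i, f in enumerate(ds.cm.feature_ids)
              if f not in ds.truth.feature_set and f not in set(ds.truth.rejected)]
        bg_mean_target = rel[np.ix_(bg, np.flatnonzero(ds.labels == 1))].mean()
        bg_mean_other = rel[np.ix_(bg, np.flatnonzero(ds.labels == 0))].mean()
        assert bg_mean_target < bg_mean_other
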