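import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from avipbk import meta


class TestAggregateStudyMeans:
    def test_hand_arithmetic_example(self):
        agg = meta.aggregate_study_means([10, 12, 14])
        assert agg.mean == pytest.approx(12.0)
        assert agg.sem == pytest.approx(2.0 / math.sqrt(3), rel=1e-12)
        assert agg.n_studies == 3

    def test_single_study_sem_undefined(self):
        agg = meta.aggregate_study_means([7.5])
        assert agg.mean == 7.5 and agg.sem is None and agg.n_studies == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            meta.aggregate_study_means([])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
                    min_size=2, max_size=30))
    def test_matches_brute_force_oracle(self, values):
        agg = meta.aggregate_study_means(values)
        # independent oracle: direct definition sums
        n = len(values)
        mean = sum(values) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
        scale = max(1.0, max(abs(v) for v in values))
        assert abs(agg.mean - mean) <= 1e-12 * scale
        assert abs(agg.sem - sd / math.sqrt(n)) <= 1e-10 * max(1.0, sd)

    def test_simulated_study_set_recovers_truth(self):
        rng = np.random.default_rng(42)
        values = rng.normal(27.1, 2.7, size=10)
        agg = meta.aggregate_study_means(values)
        assert abs(agg.mean - 27.1) < 3 * 2.7 / math.sqrt(10)


class TestEffectSizes:
    @pytest.mark.parametrize("test,ref,expected", [
        (27.1, 45.4, 40.3),   # hematocrit, hen vs mallard
        (9.2, 15.4, 40.2),    # hemoglobin
        (1.19, 1.67, 28.7),   # albumin, laying vs immature
    ])
    def test_percent_lower_reproduces_printed(self, test, ref, expected):
        assert meta.matches_printed(meta.percent_difference(test, ref),
                                    str(expected))

    def test_percent_difference_identity_and_errors(self):
        assert meta.percent_difference(3.3, 3.3) == 0.0
        with pytest.raises(ValueError):
            meta.percent_difference(1.0, 0.0)

    def test_percent_increase_total_protein(self):
        assert meta.matches_printed(meta.percent_increase(6.30, 4.40), "43.2")

    @pytest.mark.parametrize("test,ref,expected", [
        (2.42, 0.046, "52.6"),   # ovary relative weight
        (2.80, 0.046, "60.9"),   # oviduct relative weight
    ])
    def test_fold_change_reproduces_printed(self, test, ref, expected):
        assert meta.matches_printed(meta.fold_change(test, ref), expected)

    def test_fold_change_identity(self):
        assert meta.fold_change(1.7, 1.7) == 1.0

    @pytest.mark.parametrize("a,b,expected", [
        (6.30, 4.40, 1.90),    # laying vs quiescent mallard total protein
        (57.3, 31.1, 26.2),    # total minus intracellular water
        (5.0, 5.0, 0.0),
    ])
    def test_absolute_delta(self, a, b, expected):
        assert meta.absolute_delta(a, b) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(test=st.floats(min_value=0.01, max_value=100),
           ref=st.floats(min_value=0.01, max_value=100))
    def test_percent_and_fold_consistency(self, test, ref):
        if test < ref:
            lower = meta.percent_difference(test, ref)
            assert lower == pytest.approx(
                100.0 * (1.0 - meta.fold_change(test, ref)), rel=1e-9)


class TestTTests:
    def test_identical_samples_t_zero_p_one(self):
        res = meta.unpaired_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_closed_form_hand_computation(self):
        res = meta.unpaired_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), rel=1e-12)
        assert res.df == 4

    def test_zero_variance_unequal_means_underflow_safe(self):
        res = meta.unpaired_t([1.0, 1.0], [2.0, 2.0])
        assert res.p > 0.0 and res.p < 1e-100

    def test_type_one_error_calibration(self):
        # 5,000 null simulations at alpha = 0.05
        rng = np.random.default_rng(7)
        a = rng.standard_normal((5000, 10))
        b = rng.standard_normal((5000, 10))
        res = stats.ttest_ind(a, b, axis=1)
        spot = meta.unpaired_t(a[0], b[0])
        assert spot.p == pytest.approx(res.pvalue[0], rel=1e-9)
        rate = float(np.mean(res.pvalue < 0.05))
        assert 0.04 <= rate <= 0.06

    def test_paired_zero_differences(self):
        res = meta.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_paired_hand_arithmetic(self):
        res = meta.paired_t([1, 2, 3], [2, 4, 5])
        assert res.t == pytest.approx(-5.0, rel=1e-9)
        assert res.df == 2

    def test_paired_and_unpaired_agree_on_independent_data(self):
        rng = np.random.default_rng(11)
        a, b = rng.standard_normal(200), rng.standard_normal(200)
        up, pp = meta.unpaired_t(a, b), meta.paired_t(a, b)
        assert up.t == pytest.approx(pp.t, abs=0.2)  # Monte-Carlo-level agreement

    def test_welch_flag(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 5, 25)
        res = meta.unpaired_t(a, b, equal_variance=False)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.p == pytest.approx(float(ref.pvalue), rel=1e-12)


class TestAnovaDunnett:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = meta.anova_dunnett(g, [list(g), list(g)])
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert all(p == pytest.approx(1.0, abs=0.01) for p in res.adjusted_p)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            meta.anova_dunnett([1.0, 2.0], [])

    def test_two_groups_reduce_to_unpaired_t(self):
        rng = np.random.default_rng(5)
        a, b = list(rng.normal(0, 1, 12)), list(rng.normal(0.8, 1, 12))
        res = meta.anova_dunnett(a, [b], seed=17)
        t = meta.unpaired_t(a, b)
        assert res.adjusted_p[0] == pytest.approx(t.p, abs=0.01)

    def test_adjusted_p_dominates_unadjusted(self):
        rng = np.random.default_rng(9)
        control = list(rng.normal(0, 1, 8))
        treats = [list(rng.normal(d, 1, 8)) for d in (0.0, 0.5, 1.5)]
        res = meta.anova_dunnett(control, treats, seed=21)
        for adj, unadj in zip(res.adjusted_p, res.unadjusted_p):
            assert adj >= unadj
        assert all(0.0 <= p <= 1.0 for p in res.adjusted_p)

    def test_against_scipy_dunnett_oracle(self):
        # independent route: scipy's multivariate-t implementation
        rng = np.random.default_rng(13)
        control = rng.normal(0, 1, 10)
        treats = [rng.normal(0.7, 1, 10), rng.normal(1.4, 1, 10)]
        ours = meta.anova_dunnett(list(control), [list(t) for t in treats],
                                  seed=3, n_draws=200_000)
        ref = stats.dunnett(*treats, control=control,
                            random_state=np.random.default_rng(1))
        for p_ours, p_ref in zip(ours.adjusted_p, ref.pvalue):
            assert p_ours == pytest.approx(float(p_ref), abs=0.01)

    def test_familywise_error_calibration(self):
        # 5,000 null replicates, 3 treatments vs control, alpha = 0.05.
        # The package rejects when min adjusted p < alpha, i.e. when the
        # observed max |t| exceeds the 95th percentile of its Monte-Carlo
        # null; replicates are evaluated vectorized against that null.
        n, reps = 10, 5000
        df = 4 * n - 4
        crit = float(np.quantile(
            meta.dunnett_null_sample(n, [n, n, n], df, n_draws=50_000, seed=101),
            0.95))
        rng = np.random.default_rng(29)
        data = rng.standard_normal((reps, 4, n))
        means = data.mean(axis=2)
        ss = ((data - data.mean(axis=2, keepdims=True)) ** 2).sum(axis=(1, 2))
        se = np.sqrt(ss / df * (2.0 / n))
        tmax = np.abs(means[:, 1:] - means[:, [0]]).max(axis=1) / se
        rate = float(np.mean(tmax > crit))
        assert 0.035 <= rate <= 0.065
        # spot check: the package's decision on one replicate matches
        one = meta.anova_dunnett(list(data[0, 0]), [list(g) for g in data[0, 1:]],
                                 seed=101)
        assert (min(one.adjusted_p) < 0.05) == bool(tmax[0] > crit)


class TestMatchesPrinted:
    @pytest.mark.parametrize("computed,printed,ok", [
        (40.2597, "40.2", True),   # truncated print
        (40.3084, "40.3", True),
        (40.2597, "40.1", False),
        (6.3804, "6.38", True),
        (6.3804, "6.40", False),
        (37.6152, "37.6", True),
    ])
    def test_one_ulp_rule(self, computed, printed, ok):
        assert meta.matches_printed(computed, printed) is ok
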