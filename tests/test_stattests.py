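"""Normality screening and predicted-vs-measured comparison tests."""

import itertools
import math

import numpy as np
import pytest

from smdqsar.stattests import (
    CODE_FAILED_F,
    CODE_N_RULE,
    CODE_NON_NORMAL,
    anderson_darling,
    compare_predictions,
    equal_variance_f,
    ks_two_sample,
    mann_whitney,
    paired_t,
)


def exact_mw_p(a, b):
    """Brute-force two-sided Mann-Whitney p by enumerating rank assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1 = len(a)
    pooled = np.concatenate([a, b])
    observed = sum((x > y) for x in a for y in b)
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        u = sum((x > y) for x in pooled[mask] for y in pooled[~mask])
        total += 1
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


def brute_force_ks_d(a, b):
    """Sup-difference of the two empirical CDFs over all data points."""
    pts = np.concatenate([a, b])
    return max(abs(np.mean(a <= t) - np.mean(b <= t)) for t in pts)


class TestAndersonDarling:
    def test_normal_samples_pass_in_most_seeds(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            _, normal = anderson_darling(rng.standard_normal(1000))
            hits += normal
        assert hits >= 90

    def test_two_point_distribution_rejected(self):
        rng = np.random.default_rng(1)
        sample = rng.choice([0.0, 1.0], size=200) + 1e-9 * rng.standard_normal(200)
        _, normal = anderson_darling(sample)
        assert not normal

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            anderson_darling([1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            anderson_darling([1.0, 2.0])


class TestEqualVarianceF:
    def test_identical_samples_boundary(self, rng):
        a = rng.standard_normal(20)
        F, p = equal_variance_f(a, a.copy())
        assert F == pytest.approx(1.0)
        assert p == pytest.approx(0.5)

    def test_variance_ratio_four_rejected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 2.0, 50)
        b = rng.normal(0, 1.0, 50)
        F, p = equal_variance_f(a, b)
        assert F > 1
        assert p < 0.05

    def test_orientation_symmetric(self, rng):
        a, b = rng.standard_normal(15), 2.0 * rng.standard_normal(15)
        assert equal_variance_f(a, b) == equal_variance_f(b, a)


class TestPairedT:
    def test_identical_samples(self, rng):
        a = rng.standard_normal(12)
        t, p = paired_t(a, a.copy())
        assert t == 0.0 and p == 1.0

    def test_three_sigma_shift_detected(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(20)
        b = a + 3.0 + 0.5 * rng.standard_normal(20)
        _, p = paired_t(b, a)
        assert p < 0.05

    def test_shift_monotonicity(self, rng):
        """A growing constant shift never increases the paired-t p-value."""
        a = rng.standard_normal(15)
        noise = 0.3 * rng.standard_normal(15)
        ps = [paired_t(a + d + noise, a)[1] for d in (0.5, 1.0, 2.0, 4.0)]
        assert all(q <= p + 1e-12 for p, q in zip(ps, ps[1:]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0])


class TestKolmogorovSmirnov:
    def test_self_comparison(self, rng):
        a = rng.standard_normal(30)
        D, p = ks_two_sample(a, a.copy())
        assert D == 0.0 and p == pytest.approx(1.0)

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(5)
        D, p = ks_two_sample(rng.normal(0, 1, 50), rng.normal(2, 1, 50))
        assert p < 0.05

    def test_statistic_matches_brute_force_sup(self, rng):
        for _ in range(20):
            a = rng.standard_normal(rng.integers(5, 25))
            b = rng.standard_normal(rng.integers(5, 25))
            D, _ = ks_two_sample(a, b)
            assert D == pytest.approx(brute_force_ks_d(a, b), abs=1e-12)


class TestMannWhitney:
    def test_identical_samples_p_near_one(self, rng):
        a = rng.standard_normal(12)
        _, p = mann_whitney(a, a.copy())  # full ties: midrank path
        assert p > 0.9

    def test_matches_exhaustive_enumeration_small_n(self, rng):
        for _ in range(10):
            a = rng.standard_normal(rng.integers(4, 9))
            b = rng.standard_normal(rng.integers(4, 9))
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(exact_mw_p(a, b), abs=1e-12)

    def test_disjoint_support_minimal_p(self):
        a = np.arange(10, dtype=float)
        b = np.arange(10, dtype=float) + 100.0
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(2.0 / math.comb(20, 10), rel=1e-9)


class TestTypeIError:
    @pytest.mark.parametrize("test_name", ["F", "t", "KS", "MW"])
    def test_nominal_level_under_null(self, test_name):
        """Each test rejects ~5% of the time when samples share a distribution."""
        rng = np.random.default_rng({"F": 11, "t": 22, "KS": 33, "MW": 44}[test_name])
        n, reps, alpha = 20, 1000, 0.05
        rejections = 0
        for _ in range(reps):
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            if test_name == "F":
                _, p = equal_variance_f(a, b)
                rejections += p < alpha / 2  # oriented ratio: halve the tail
            elif test_name == "t":
                rejections += paired_t(a, b)[1] < alpha
            elif test_name == "KS":
                rejections += ks_two_sample(a, b)[1] < alpha
            else:
                rejections += mann_whitney(a, b)[1] < alpha
        assert 0.03 <= rejections / reps <= 0.07


class TestComparePredictions:
    def test_identical_samples_never_reject(self, rng):
        a = rng.standard_normal(15)
        report = compare_predictions(a, a + 1e-9 * rng.standard_normal(15))
        for name, out in report.outcomes.items():
            if out.applicable:
                assert not out.reject, name

    def test_large_bias_rejected_by_t_and_mw(self):
        rng = np.random.default_rng(6)
        measured = rng.standard_normal(20)
        predicted = measured + 2.5 + 0.3 * rng.standard_normal(20)
        report = compare_predictions(predicted, measured)
        assert report.outcomes["t"].applicable and report.outcomes["t"].reject
        assert report.outcomes["MW"].applicable and report.outcomes["MW"].reject

    def test_non_normal_sample_gates_parametric_path(self):
        rng = np.random.default_rng(7)
        measured = rng.standard_normal(40)
        predicted = rng.choice([0.0, 5.0], size=40) + 1e-6 * rng.standard_normal(40)
        report = compare_predictions(predicted, measured)
        assert not report.outcomes["F"].applicable
        assert report.outcomes["F"].code == CODE_NON_NORMAL
        assert report.outcomes["t"].code == CODE_NON_NORMAL
        # the distribution-free path still runs
        assert report.outcomes["KS"].applicable
        assert report.outcomes["MW"].applicable

    def test_unequal_variance_gates_t(self):
        rng = np.random.default_rng(8)
        measured = rng.normal(0, 1, 30)
        predicted = measured * 4.0  # same mean, inflated variance
        report = compare_predictions(predicted, measured)
        assert report.outcomes["F"].reject
        assert report.outcomes["t"].code == CODE_FAILED_F

    def test_sample_size_rules(self, rng):
        a = rng.standard_normal(8)
        b = a + 0.1 * rng.standard_normal(8)
        report = compare_predictions(a, b)
        assert report.outcomes["KS"].code == CODE_N_RULE  # needs n > 10
        assert report.outcomes["MW"].applicable            # n > 7 suffices
        small = compare_predictions(a[:6], b[:6])
        assert small.outcomes["MW"].code == CODE_N_RULE

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError):
            compare_predictions([1.0, 2.0], [1.0, 2.0])
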