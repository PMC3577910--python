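"""Variance components, bootstrap intervals, permutation tests."""

import numpy as np
import pandas as pd
import pytest

from amidrift.stats import (
    among_line_variance,
    bonferroni,
    bootstrap_ci,
    change_in_mean,
    classify_interval,
    log_transform,
    permutation_welch_test,
    variance_components_from_table,
)


class TestLogTransform:
    def test_values(self):
        out = log_transform(np.array([1.0, np.e, 1345.0]))
        assert out[0] == 0.0
        assert out[1] == pytest.approx(1.0)
        assert out[2] == pytest.approx(7.2042, abs=1e-4)

    def test_round_trip(self, rng):
        x = rng.lognormal(5, 1, size=50)
        np.testing.assert_allclose(np.exp(log_transform(x)), x, rtol=1e-12)

    def test_dataframe_cnpc_column(self):
        df = pd.DataFrame({"CNPC": [1.0, np.e], "Gene": ["a", "b"]})
        out = log_transform(df)
        assert out["CNPC"].tolist() == pytest.approx([0.0, 1.0])
        assert df["CNPC"].iloc[0] == 1.0  # input untouched

    def test_nonpositive_names_offender(self):
        df = pd.DataFrame({"CNPC": [2.0, -1.0]}, index=["r0", "r1"])
        with pytest.raises(ValueError, match="r1"):
            log_transform(df)


class TestAmongLineVariance:
    def test_constant_data(self):
        vc = among_line_variance(np.full((3, 4), 7.0))
        assert vc.sigma_sq_line == 0.0 and vc.sigma_sq_resid == 0.0

    def test_hand_computed_between_lines(self):
        """Lines {1,1} and {3,3}: MSW = 0, MSB = 4, sigma_sq_line = 2."""
        vc = among_line_variance(np.array([[1.0, 1.0], [3.0, 3.0]]))
        assert vc.sigma_sq_resid == 0.0
        assert vc.sigma_sq_line == pytest.approx(2.0)

    def test_negative_estimate_truncated(self):
        """Lines {0,10} and {5,5}: MSB = 0, MSW = 25, raw estimate < 0 -> 0."""
        vc = among_line_variance(np.array([[0.0, 10.0], [5.0, 5.0]]))
        assert vc.sigma_sq_resid == pytest.approx(25.0)
        assert vc.sigma_sq_line == 0.0

    def test_too_small_design(self):
        with pytest.raises(ValueError):
            among_line_variance(np.ones((1, 3)))
        with pytest.raises(ValueError):
            among_line_variance(np.ones((3, 1)))

    def test_unbalanced_table_rejected(self):
        df = pd.DataFrame(
            {"Cell.line": ["L1", "L1", "L2"], "CNPC": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="unbalanced"):
            variance_components_from_table(df)

    def test_table_matches_array_path(self, rng):
        y = rng.normal(size=(4, 3))
        df = pd.DataFrame(
            {
                "Cell.line": np.repeat([f"L{i}" for i in range(4)], 3),
                "CNPC": y.ravel(),
            }
        )
        assert variance_components_from_table(df) == among_line_variance(y)

    def test_recovers_simulated_components(self, rng):
        """MoM estimates converge on the generating variances for a big design."""
        k, m = 200, 50
        line = rng.normal(0, np.sqrt(4.0), size=(k, 1))
        y = line + rng.normal(0, np.sqrt(1.0), size=(k, m))
        vc = among_line_variance(y)
        # 3 sigma of the estimator's sampling sd (~0.44 for this design)
        assert vc.sigma_sq_line == pytest.approx(4.0, abs=1.3)
        assert vc.sigma_sq_resid == pytest.approx(1.0, rel=0.05)


class TestBootstrapCI:
    def test_constant_data_degenerate_interval(self, rng):
        est = bootstrap_ci(np.full(10, 3.5), np.mean, rng=rng)
        assert est.lo == est.hi == est.point == 3.5

    def test_coverage_of_gaussian_mean(self, rng):
        """Percentile interval covers the true mean near-nominally (quick check).

        The percentile method undercovers slightly at n = 30 (~93% true
        coverage for a Gaussian mean); this sanity check uses a coarse band,
        the precision run lives in the acceptance suite.
        """
        meta, n = 600, 30
        covered = 0
        for _ in range(meta):
            x = rng.normal(0, 1, size=n)
            est = bootstrap_ci(x, np.mean, n_boot=400, rng=rng)
            covered += est.lo <= 0.0 <= est.hi
        assert abs(covered / meta - 0.95) < 0.05

    def test_classification_rule(self):
        from amidrift.stats import IntervalEstimate

        assert classify_interval(IntervalEstimate(2, 1, 3)) == "increase"
        assert classify_interval(IntervalEstimate(-2, -3, -1)) == "decrease"
        assert classify_interval(IntervalEstimate(0.5, -0.1, 1.2)) == "no change"

    def test_seed_reproducible(self):
        x = np.arange(20.0)
        a = bootstrap_ci(x, np.median, rng=np.random.default_rng(3))
        b = bootstrap_ci(x, np.median, rng=np.random.default_rng(3))
        assert a == b


class TestPermutationWelch:
    def test_identical_groups_p_is_one(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert permutation_welch_test(x, x.copy(), n_perm=200, rng=rng) == 1.0

    def test_extreme_separation_minimum_p(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(100, 1, 50)
        n_perm = 999
        p = permutation_welch_test(a, b, n_perm=n_perm, rng=rng)
        assert p == pytest.approx(1 / (n_perm + 1))

    def test_type_i_error_rate(self, rng):
        """Null rejection rate at alpha = 0.05 stays near nominal (200 meta-reps)."""
        meta, n = 200, 30
        rejections = 0
        for _ in range(meta):
            a = rng.normal(0, 1, n)
            b = rng.normal(0, 1, n)
            rejections += permutation_welch_test(a, b, n_perm=400, rng=rng) < 0.05
        assert abs(rejections / meta - 0.05) < 0.03

    def test_seed_reproducible(self):
        a, b = np.arange(10.0), np.arange(10.0) + 0.5
        p1 = permutation_welch_test(a, b, n_perm=500, rng=np.random.default_rng(9))
        p2 = permutation_welch_test(a, b, n_perm=500, rng=np.random.default_rng(9))
        assert p1 == p2

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_welch_test(np.array([]), np.array([1.0]), rng=rng)


class TestBonferroni:
    def test_single_p_unchanged(self):
        out = bonferroni([0.03])
        assert out["p_adjusted"].iloc[0] == pytest.approx(0.03)
        assert bool(out["significant"].iloc[0])

    def test_multiplies_by_family_size(self):
        out = bonferroni([0.03, 0.2, 0.5, 0.9, 0.002])
        assert out["p_adjusted"].iloc[0] == pytest.approx(0.15)
        assert not bool(out["significant"].iloc[0])  # 0.03 * 5 = 0.15
        assert bool(out["significant"].iloc[4])  # 0.002 * 5 = 0.01

    def test_caps_at_one(self):
        out = bonferroni([0.5] * 5)
        assert (out["p_adjusted"] == 1.0).all()

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.2])


class TestChangeInMean:
    def test_no_change(self, rng):
        x = np.array([10.0, 12.0, 9.0, 11.0, 10.5, 13.0])
        est = change_in_mean(x, x.copy(), rng=rng)
        assert est.point == 0.0
        assert classify_interval(est) == "no change"

    def test_uniform_shift_detected(self, rng):
        x = np.array([10.0, 12.0, 9.0, 11.0, 10.5, 13.0])
        est = change_in_mean(x, x + 10.0, rng=rng)
        assert est.point == pytest.approx(10.0)
        assert classify_interval(est) == "increase"

    def test_unpaired_rejected(self, rng):
        with pytest.raises(ValueError):
            change_in_mean(np.ones(5), np.ones(6), rng=rng)
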