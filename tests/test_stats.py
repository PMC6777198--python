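"""Descriptives, t-tests and ICC against closed-form and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from aortadose.stats import (
    describe,
    icc_consistency_average,
    percent_difference,
    two_sample_ttest,
)


class TestDescribe:
    def test_small_sample(self):
        s = describe([1, 2, 3])
        assert (s.mean, s.sd, s.median, s.minimum, s.maximum) == (2.0, 1.0, 2.0, 1.0, 3.0)

    def test_constant_dose_column(self):
        s = describe([120.0] * 20, variable="dose")
        assert s.mean == 120.0 and s.sd == 0.0
        assert (s.minimum, s.maximum) == (120.0, 120.0)

    def test_sampling_error_of_sd(self):
        rng = np.random.default_rng(1)
        s = describe(rng.standard_normal(10_000))
        assert s.sd == pytest.approx(1.0, abs=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            describe([])


class TestPercentDifference:
    @pytest.mark.parametrize(
        "ref, other, expected",
        [(120.0, 101.8, -15.166666), (282.2, 191.2, -32.246), (5.0, 5.0, 0.0)],
    )
    def test_values(self, ref, other, expected):
        assert percent_difference(ref, other) == pytest.approx(expected, abs=1e-3)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 5.0)

    @given(
        a=st.floats(1.0, 1e4),
        b=st.floats(1.0, 1e4),
    )
    def test_reciprocal_identity(self, a, b):
        d1 = percent_difference(a, b)
        d2 = percent_difference(b, a)
        assert (1 + d1 / 100) * (1 + d2 / 100) == pytest.approx(1.0, rel=1e-9)


class TestTTest:
    def test_identical_paired_samples(self):
        r = two_sample_ttest([1, 2, 3, 4], [1, 2, 3, 4], variant="paired")
        assert r.t == 0.0 and r.p == 1.0 and not r.significant

    def test_pooled_hand_computed_example(self):
        # means 2.5 vs 3.5, pooled sd = 1.291 → |t| = 1.095, df = 6
        r = two_sample_ttest([1, 2, 3, 4], [2, 3, 4, 5], variant="student_pooled")
        assert abs(r.t) == pytest.approx(1.095, abs=5e-4)
        assert r.df == 6

    def test_welch_matches_pooled_for_balanced_equal_variance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 50), rng.normal(0.4, 1, 50)
        p = two_sample_ttest(x, y, variant="student_pooled")
        w = two_sample_ttest(x, y, variant="welch")
        assert w.t == pytest.approx(p.t, rel=1e-3)
        assert w.p == pytest.approx(p.p, rel=1e-3)

    def test_degenerate_zero_variance(self):
        r = two_sample_ttest([5.0, 5.0], [5.0, 5.0])
        assert r.t == 0.0 and r.p == 1.0
        r2 = two_sample_ttest([5.0, 5.0], [6.0, 6.0])
        assert r2.p == 0.0 and np.isinf(r2.t)

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1, 2, 3], [1, 2], variant="paired")

    def test_null_p_values_uniform(self):
        """Under the null the pooled-t p-value is Uniform(0,1) (KS check)."""
        from scipy import stats as sps

        rng = np.random.default_rng(8)
        pvals = [
            two_sample_ttest(rng.normal(size=20), rng.normal(size=20)).p
            for _ in range(2000)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.001

    def test_type_one_error_at_study_alpha(self):
        """False-positive rate at α = 0.025 over 10,000 null trials, n = 20/20."""
        rng = np.random.default_rng(12)
        hits = sum(
            two_sample_ttest(rng.normal(size=20), rng.normal(size=20)).significant
            for _ in range(10_000)
        )
        assert hits / 10_000 == pytest.approx(0.025, abs=0.005)


def _icc_bruteforce(m: np.ndarray) -> float:
    """Two-way ANOVA mean squares by explicit loops: the independent oracle."""
    n, k = m.shape
    grand = sum(m[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(m[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(m[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((m[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_rows = ss_rows / (n - 1)
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / ms_rows


class TestIcc:
    def test_identical_columns_give_one(self):
        m = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 3))
        assert icc_consistency_average(m).value == pytest.approx(1.0)

    @settings(max_examples=40)
    @given(
        m=arrays(
            float,
            st.tuples(st.integers(3, 12), st.integers(2, 4)),
            elements=st.floats(-10, 10, allow_nan=False, width=32),
        )
    )
    def test_matches_bruteforce_anova_oracle(self, m):
        row_var = np.var(m.mean(axis=1))
        if row_var < 1e-8:
            return  # degenerate case covered separately
        assert icc_consistency_average(m).value == pytest.approx(
            _icc_bruteforce(m), abs=1e-10
        )

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(19)
        m = rng.normal(size=(200, 2))
        assert abs(icc_consistency_average(m).value) < 0.15

    def test_invariant_under_per_rater_shift(self):
        """Consistency ICC ignores constant rater offsets — exactly the
        structure of the second reader's systematically higher grades."""
        rng = np.random.default_rng(23)
        m = rng.normal(size=(30, 3))
        shifted = m + np.array([0.0, 1.1, -0.45])
        assert icc_consistency_average(shifted).value == pytest.approx(
            icc_consistency_average(m).value, abs=1e-12
        )

    def test_zero_between_subject_variance_reported_undefined(self):
        m = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        r = icc_consistency_average(m)
        assert r.value is None
        assert "between-subject" in r.undefined_reason

    def test_agrees_with_pingouin_icc3k(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(31)
        m = rng.normal(size=(25, 3)) + rng.normal(size=(25, 1))  # real subject effect
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(25), 3),
                "rater": np.tile(np.arange(3), 25),
                "score": m.ravel(),
            }
        )
        table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        icc3k = table.loc[table["Type"] == "ICC(C,k)", "ICC"].iloc[0]
        assert icc_consistency_average(m).value == pytest.approx(icc3k, abs=1e-9)

    def test_bad_matrices_rejected(self):
        with pytest.raises(ValueError):
            icc_consistency_average(np.ones((1, 3)))
        with pytest.raises(ValueError):
            icc_consistency_average(np.array([[1.0, np.nan], [2.0, 3.0]]))
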