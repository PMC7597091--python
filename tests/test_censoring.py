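import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from kwgphc.censoring import (
    CensoringScheme,
    classify_and_truncate,
    effective_removals,
    generate_gphc_sample,
    generate_progressive_type2,
)
from kwgphc.datasets import shasta_censored, shasta_scheme
from kwgphc.distributions import kw_cdf


@st.composite
def random_schemes(draw):
    m = draw(st.integers(2, 8))
    extra = draw(st.lists(st.integers(0, 3), min_size=m, max_size=m))
    n = m + sum(extra)
    k = draw(st.integers(1, m))
    T = draw(st.floats(0.05, 0.95))
    return CensoringScheme(n=n, m=m, k=k, T=T, R=tuple(extra))


class TestScheme:
    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            CensoringScheme(n=10, m=5, k=3, T=0.5, R=(1, 1, 1, 1, 2))  # sum+m != n
        with pytest.raises(ValueError):
            CensoringScheme(n=10, m=5, k=6, T=0.5, R=(1, 1, 1, 1, 1))  # k > m
        with pytest.raises(ValueError):
            CensoringScheme(n=10, m=5, k=3, T=-0.1, R=(1, 1, 1, 1, 1))

    def test_named_patterns(self):
        s1 = CensoringScheme.pattern("I", n=40, m=30, k=20, T=0.9)
        s2 = CensoringScheme.pattern("II", n=40, m=30, k=20, T=0.9)
        s3 = CensoringScheme.pattern("III", n=40, m=30, k=20, T=0.9)
        assert s1.R[0] == 10 and sum(s1.R[1:]) == 0
        assert s2.R[-1] == 10 and sum(s2.R[:-1]) == 0
        assert s3.R[0] == 5 and s3.R[-1] == 5 and sum(s3.R) == 10

    def test_from_config_accepts_pattern_or_vector(self):
        cfg = {"n": 42, "m": 21, "k": 19, "T": 0.75, "R": [1] * 21}
        named = {"n": 40, "m": 30, "k": 20, "T": 0.9, "R": "scheme_II"}
        assert CensoringScheme.from_config(cfg).R == (1,) * 21
        assert CensoringScheme.from_config(named).R[-1] == 10


class TestEffectiveRemovals:
    def test_case1_pooled_count(self):
        scheme = shasta_scheme("I")  # n=42, k=19, R_1..18 = 1
        Reff, rstar = effective_removals(scheme, "I", 19)
        assert Reff[-1] == 42 - 19 - 18 == 5
        assert rstar == 0 and Reff.sum() + 19 == 42

    def test_case2_terminal(self):
        scheme = shasta_scheme("II")
        Reff, rstar = effective_removals(scheme, "II", 14)
        assert rstar == 42 - 14 - 14 == 14
        Reff18, rstar18 = effective_removals(scheme, "II", 18)
        assert rstar18 == 6

    def test_complete_sample_all_zero(self):
        scheme = CensoringScheme(n=5, m=5, k=5, T=0.9, R=(0,) * 5)
        Reff, rstar = effective_removals(scheme, "III", 5)
        assert rstar == 0 and not Reff.any()


class TestClassification:
    """The three published illustration settings on the censored subsample."""

    def test_case1(self):
        sample = classify_and_truncate(shasta_censored(), shasta_scheme("I"))
        assert sample.case == "I" and sample.D == 19
        assert sample.Reff[-1] == 5 and sample.is_balanced

    def test_case1_planned_convention(self):
        sample = classify_and_truncate(
            shasta_censored(), shasta_scheme("I"), case_i_terminal="planned"
        )
        assert sample.case == "I" and tuple(sample.Reff) == (1,) * 19
        assert not sample.is_balanced  # four units deliberately unaccounted

    def test_case2_observes_all_failures_below_threshold(self):
        # x_18 = 0.744881 < 0.75 < x_19 = 0.767135, so J = 18
        sample = classify_and_truncate(shasta_censored(), shasta_scheme("II"))
        assert sample.case == "II" and sample.D == 18
        assert sample.Rstar_next == 6 and sample.is_balanced

    def test_case3(self):
        sample = classify_and_truncate(shasta_censored(), shasta_scheme("III"))
        assert sample.case == "III" and sample.D == 21 and sample.Rstar_next == 0

    def test_tie_with_threshold_counts_as_observed(self):
        x = np.array([0.1, 0.3, 0.5, 0.7])
        scheme = CensoringScheme(n=6, m=4, k=1, T=0.5, R=(1, 1, 0, 0))
        sample = classify_and_truncate(x, scheme)
        assert sample.case == "II" and sample.D == 3

    @given(scheme=random_schemes(), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_accounting_identity_fuzzed(self, scheme, seed):
        sample = generate_gphc_sample(scheme, (3.0, 2.0), rng=seed)
        assert sample.D + sample.Reff.sum() + sample.Rstar_next == scheme.n
        assert np.all(np.diff(sample.x) > 0)


class TestGenerator:
    def test_deterministic_under_seed(self):
        scheme = CensoringScheme.pattern("III", n=20, m=10, k=5, T=0.9)
        a = generate_progressive_type2(scheme, (3.0, 2.0), rng=11)
        b = generate_progressive_type2(scheme, (3.0, 2.0), rng=11)
        assert np.array_equal(a, b)

    def test_no_removals_reproduces_iid_order_statistics(self, rng):
        """With R = 0 the full sample is just n iid Kumaraswamy draws; pool
        many replicates and K-S test them against the cdf."""
        n = 5
        scheme = CensoringScheme(n=n, m=n, k=n, T=0.9, R=(0,) * n)
        pooled = np.concatenate(
            [generate_progressive_type2(scheme, (3.0, 2.0), rng=rng) for _ in range(400)]
        )
        p = stats.kstest(pooled, lambda v: kw_cdf(v, 3.0, 2.0)).pvalue
        assert p > 0.01

    def test_single_failure_is_minimum_of_n(self, rng):
        """m=1, R1 = n-1: the lone observed failure is the sample minimum,
        with cdf 1 - (1-F)**n."""
        n = 8
        scheme = CensoringScheme(n=n, m=1, k=1, T=0.9, R=(n - 1,))
        draws = np.array(
            [generate_progressive_type2(scheme, (3.0, 2.0), rng=rng)[0] for _ in range(3000)]
        )
        min_cdf = lambda v: 1.0 - (1.0 - kw_cdf(v, 3.0, 2.0)) ** n
        assert stats.kstest(draws, min_cdf).pvalue > 0.01

    def test_type2_reduction_matches_first_order_statistics(self, rng):
        """R = (0,...,0,n-m) is conventional Type-II censoring: the first m
        order statistics of n iid draws.  Compare the marginal law of X_1
        against the iid minimum by K-S."""
        n, m = 10, 4
        scheme = CensoringScheme(n=n, m=m, k=m, T=0.99, R=(0,) * (m - 1) + (n - m,))
        firsts = np.array(
            [generate_progressive_type2(scheme, (3.0, 2.0), rng=rng)[0] for _ in range(2000)]
        )
        min_cdf = lambda v: 1.0 - (1.0 - kw_cdf(v, 3.0, 2.0)) ** n
        assert stats.kstest(firsts, min_cdf).pvalue > 0.01

    def test_case_probabilities_respond_to_threshold(self, rng):
        """T near 1 forces Case III; tiny T with k fixed forces Case I."""
        kwargs = dict(n=20, m=10, k=5)
        late = CensoringScheme.pattern("II", T=0.999, **kwargs)
        early = CensoringScheme.pattern("II", T=0.01, **kwargs)
        cases_late = [generate_gphc_sample(late, (3.0, 2.0), rng=rng).case for _ in range(100)]
        cases_early = [generate_gphc_sample(early, (3.0, 2.0), rng=rng).case for _ in range(100)]
        assert cases_late.count("III") >= 95
        assert cases_early.count("I") >= 95
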