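"""The Y statistic, its moments, the four tail bounds, and the quartet test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from svdscore import (
    METHODS,
    SitePatternCounts,
    covariance_spectrum,
    mean_Y,
    pvalue_bhc,
    pvalue_chebyshev,
    pvalue_logconcave,
    pvalue_markov,
    rejection_threshold,
    sample_Y_chisq,
    sample_Y_multinomial,
    test_quartet as run_quartet_test,
    threshold_table,
    var_Y,
    verify_lemma32_optima,
)
from svdscore.hypotest import variance_functional


class TestCovarianceSpectrum:
    def test_two_category_fair_coin(self):
        """Sigma((1/2,1/2)) = [[1/4,-1/4],[-1/4,1/4]] has eigenvalues 1/2, 0."""
        spec = covariance_spectrum(np.array([0.5, 0.5]))
        np.testing.assert_allclose(spec.eigenvalues, [0.5, 0.0], atol=1e-14)

    def test_point_mass_has_zero_spectrum(self):
        p = np.zeros(256)
        p[0] = 1.0
        spec = covariance_spectrum(p)
        np.testing.assert_allclose(spec.eigenvalues, 0.0, atol=1e-12)

    def test_trace_identity_on_random_simplex_points(self, rng):
        for k in (4, 32, 256):
            p = rng.dirichlet(np.ones(k))
            spec = covariance_spectrum(p)
            assert spec.trace == pytest.approx(1 - np.sum(p**2), abs=1e-12)
            assert spec.eigenvalues.sum() == pytest.approx(spec.trace, abs=1e-10)


class TestMoments:
    def test_reference_mean_and_sd(self, reference_distribution):
        """Theoretical mean and s.d. of Y at n = 25,000 on the reference quartet."""
        n = 25_000
        assert mean_Y(reference_distribution, n) == pytest.approx(24145.84, abs=0.005)
        assert np.sqrt(var_Y(reference_distribution, n)) == pytest.approx(
            6183.84, abs=0.005
        )

    def test_point_mass_moments_vanish(self):
        p = np.zeros(256)
        p[7] = 1.0
        assert mean_Y(p, 1000) == 0.0
        assert var_Y(p, 1000) == 0.0

    def test_fair_coin_moments(self):
        p = np.array([0.5, 0.5])
        assert mean_Y(p, 10) == pytest.approx(5.0)
        assert var_Y(p, 10) == pytest.approx(100 / 2)  # the simplex-wide maximum

    def test_simplex_wide_bounds(self, rng):
        """E[Y] <= n and Var[Y] <= n^2/2 across random simplex points."""
        for k in (2, 3, 8, 64, 256):
            pts = rng.dirichlet(np.ones(k), size=20_000)
            means = np.sum(pts * (1 - pts), axis=1)
            assert means.max() <= 1.0 + 1e-12
            assert variance_functional(pts).max() <= 0.5 + 1e-9


class TestSamplers:
    def test_multinomial_single_draw_algebra(self, rng):
        p = np.array([0.2, 0.3, 0.5])
        ys = sample_Y_multinomial(p, 1, 200, rng)
        # a draw of category j gives (1-p_j)^2 + sum_{i!=j} p_i^2
        expected = {
            round((1 - p[j]) ** 2 + np.sum(p**2) - p[j] ** 2, 12) for j in range(3)
        }
        assert {round(v, 12) for v in ys.values} <= expected

    def test_point_mass_samples_are_zero(self, rng):
        p = np.zeros(16)
        p[3] = 1.0
        assert np.all(sample_Y_chisq(p, 100, 50, rng).values == 0)
        assert np.all(sample_Y_multinomial(p, 100, 50, rng).values == 0)

    def test_both_samplers_match_theory_and_each_other(self, reference_distribution, rng):
        """Means within 4 standard errors of n tr Sigma (Y is right-skewed,
        so a seeded test needs slack beyond 3 SE); the two samplers agree
        in distribution (the chi-square form approximates Y well)."""
        n, reps = 25_000, 4000
        mu = mean_Y(reference_distribution, n)
        sd = np.sqrt(var_Y(reference_distribution, n))
        se = 4 * sd / np.sqrt(reps)
        ym = sample_Y_multinomial(reference_distribution, n, reps, rng)
        yc = sample_Y_chisq(reference_distribution, n, reps, rng)
        assert ym.values.mean() == pytest.approx(mu, abs=se)
        assert yc.values.mean() == pytest.approx(mu, abs=se)
        from scipy.stats import ks_2samp

        assert ks_2samp(ym.values, yc.values).statistic < 0.05


class TestPValueBounds:
    @pytest.mark.parametrize(
        "coeff, expected", [(10, 0.1), (20, 0.05), (100, 0.01), (1000, 0.001)]
    )
    def test_markov_table_row(self, coeff, expected):
        assert pvalue_markov(coeff * 5000, 5000) == pytest.approx(expected)

    def test_markov_trivial_cases(self):
        assert pvalue_markov(5000, 5000) == 1.0
        assert pvalue_markov(0.0, 5000) == 1.0

    def test_chebyshev_inversion_identity(self):
        """beta = n (1 + sqrt((1/a - 1)/2)) maps back to exactly a."""
        n = 7000
        for a in (0.2, 0.05, 0.01):
            beta = n * (1 + np.sqrt((1 / a - 1) / 2))
            assert pvalue_chebyshev(beta, n) == pytest.approx(a, rel=1e-12)
        assert pvalue_chebyshev(n, n) == 1.0
        assert pvalue_chebyshev(1e12 * n, n) < 1e-15

    @pytest.mark.parametrize(
        "coeff, expected", [(2.36, 0.10), (2.73, 0.05), (3.68, 0.01), (5.21, 0.001)]
    )
    def test_logconcave_inverts_printed_thresholds(self, coeff, expected):
        rho, bound = pvalue_logconcave(coeff * 10_000, 10_000)
        assert bound == rho
        assert rho == pytest.approx(expected, rel=2e-2)

    def test_logconcave_trivial_below_mean(self):
        assert pvalue_logconcave(9_999, 10_000) == (1.0, 1.0)

    def test_bhc_examples(self):
        assert pvalue_bhc(360.88 * 10_000, 10_000) == pytest.approx(0.05, rel=2e-3)
        assert pvalue_bhc(0.0, 10_000) == 1.0
        # k = 1 inversion: beta = 2 n ln(2/alpha) gives exactly alpha
        a = 0.03
        assert pvalue_bhc(2 * 500 * np.log(2 / a), 500, k=1) == pytest.approx(a)

    @given(st.floats(min_value=1.001, max_value=500.0))
    def test_bounds_non_increasing_in_beta(self, coeff):
        n = 10_000
        lo, hi = coeff * n, coeff * n * 1.3
        assert pvalue_markov(hi, n) <= pvalue_markov(lo, n)
        assert pvalue_chebyshev(hi, n) <= pvalue_chebyshev(lo, n)
        assert pvalue_logconcave(hi, n)[1] <= pvalue_logconcave(lo, n)[1]
        assert pvalue_bhc(hi, n) <= pvalue_bhc(lo, n)

    def test_empirical_tail_never_exceeds_any_bound(self, reference_distribution, rng):
        """Monte Carlo exceedance probabilities of Y sit below all four bounds."""
        n, reps = 2_000, 4000
        ys = sample_Y_multinomial(reference_distribution, n, reps, rng).values
        for coeff in (1.5, 2.0, 3.0, 5.0, 10.0):
            beta = coeff * n
            emp = np.mean(ys >= beta)
            assert emp <= pvalue_markov(beta, n)
            assert emp <= pvalue_chebyshev(beta, n)
            assert emp <= pvalue_logconcave(beta, n)[1]
            assert emp <= pvalue_bhc(beta, n)


class TestThresholds:
    def test_printed_coefficients(self):
        table = threshold_table()
        expected = {
            "markov": (10.0, 20.0, 100.0, 1000.0),
            "chebyshev": (3.24, 4.16, 8.07, 23.36),
            "logconcave": (2.36, 2.73, 3.68, 5.21),
            "bhc": (359.50, 360.88, 364.10, 368.70),
        }
        for method, vals in expected.items():
            for alpha, val in zip((0.10, 0.05, 0.01, 0.001), vals):
                assert table.loc[method, alpha] == pytest.approx(val, abs=0.01)

    def test_cantelli_variant_differs_from_table(self):
        assert rejection_threshold("chebyshev", 0.05) == pytest.approx(4.16, abs=0.01)
        assert rejection_threshold(
            "chebyshev", 0.05, chebyshev_variant="cantelli"
        ) == pytest.approx(1 + np.sqrt(9.5), abs=1e-12)

    def test_thresholds_decrease_in_alpha_and_order_across_methods(self):
        for method in METHODS:
            vals = [rejection_threshold(method, a) for a in (0.1, 0.05, 0.01, 0.001)]
            assert vals == sorted(vals)
        for a in (0.1, 0.05, 0.01, 0.001):
            lc = rejection_threshold("logconcave", a)
            ch = rejection_threshold("chebyshev", a)
            mk = rejection_threshold("markov", a)
            bhc = rejection_threshold("bhc", a)
            assert lc <= ch <= mk or lc <= ch <= bhc
            assert lc < bhc and ch < bhc

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            rejection_threshold("markov", 0.0)
        with pytest.raises(ValueError):
            rejection_threshold("nope", 0.05)


class TestQuartetTest:
    def test_zero_statistic_never_rejects(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[0] = 100  # rank-1 flattening: score 0 at any r >= 1
        res = run_quartet_test(SitePatternCounts(counts), "ab|cd", r=4, alpha=0.5)
        assert res.statistic == pytest.approx(0.0, abs=1e-20)
        assert not any(res.reject.values())

    def test_concordant_split_rarely_rejected(self, reference_distribution, rng):
        """Type-I control: sampling from a rank-4 ab|cd model, the
        conservative test essentially never rejects the true split."""
        rejections = 0
        for _ in range(40):
            counts = SitePatternCounts(
                rng.multinomial(20_000, reference_distribution.probs)
            )
            res = run_quartet_test(counts, "ab|cd", r=4, alpha=0.05)
            rejections += any(res.reject.values())
        assert rejections == 0

    def test_discordant_split_rejected_at_large_n(self, reference_distribution, rng):
        """At 100,000 sites the log-concave test rejects ac|bd in >= 95%
        of replicates (the expected squared score, 8.75e-5 n^2, is ~3.2x
        the 2.73n threshold there)."""
        rejected = 0
        reps = 40
        for _ in range(reps):
            counts = SitePatternCounts(
                rng.multinomial(100_000, reference_distribution.probs)
            )
            res = run_quartet_test(counts, "ac|bd", r=4, alpha=0.05, methods=("logconcave",))
            rejected += res.reject["logconcave"]
        assert rejected >= 0.95 * reps

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            run_quartet_test(SitePatternCounts(np.zeros(256, dtype=np.int64)), "ab|cd")


class TestVarianceBoundOptima:
    def test_report(self, rng):
        rep = verify_lemma32_optima(rng, n_random=30_000)
        assert rep["max_over_random_points"] <= 0.5 + 1e-9
        assert rep["value_at_two_halves"] == pytest.approx(0.5, abs=1e-15)
        assert rep["uniform_family_max"] == pytest.approx(0.5)
        assert rep["uniform_family_argmax_k"] == 2
        assert rep["interior_family_max"] == pytest.approx(0.43608, abs=5e-6)
        assert rep["interior_family_argmax_k"] == pytest.approx(
            rep["interior_family_argmax_closed_form"], abs=1e-6
        )
        assert rep["k4_m2_value"] == pytest.approx(3 / 8, abs=1e-15)
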