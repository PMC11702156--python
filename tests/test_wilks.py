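"""Distribution theory: Gamma(1/2,1) law, critical bound, coincidence solvers.

Frozen expected values were computed with a 40-digit sympy evaluation of the
closed forms (erf/erfc identities and term-by-term evaluation of the bound).
"""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eaic.wilks import (
    ALPHA0,
    alpha_bic_equiv,
    alpha_maic,
    alpha_ric,
    asymptotic_fwer,
    bic_fwer_approx,
    c_eaic,
    critical_bound,
    family_max_cdf,
    half_chi2_cdf,
    half_chi2_sf,
    mc_null_bound_check,
)


class TestHalfChi2:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (0.0, 0.0),
            (1.0, 1.0 - 0.1572992071),  # AIC's per-test asymptotic level
            (2.0, 0.9544997361),
        ],
    )
    def test_cdf_values(self, x, expected):
        assert half_chi2_cdf(x) == pytest.approx(expected, abs=1e-9)

    def test_matches_chi2_with_one_df(self):
        from scipy.stats import chi2

        for x in (0.1, 0.7, 3.0, 9.0):
            assert half_chi2_cdf(x) == pytest.approx(chi2.cdf(2 * x, df=1), abs=1e-12)

    def test_tail_precise_at_large_x(self):
        # erfc route keeps relative precision where 1 - cdf underflows.
        x = 15.0
        assert half_chi2_sf(x) > 0
        assert half_chi2_sf(x) == pytest.approx(1.0 - half_chi2_cdf(x), rel=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            half_chi2_cdf(-0.1)
        with pytest.raises(ValueError):
            half_chi2_sf(-1.0)


class TestCriticalBound:
    def test_alpha0_closed_form(self):
        assert ALPHA0 == pytest.approx(0.4311790581359798, abs=1e-12)
        b = critical_bound(100, ALPHA0)
        assert b.x == pytest.approx(3.8415803730841408, abs=1e-10)
        assert b.x == pytest.approx(math.log(100) - 0.5 * math.log(math.log(100)), abs=1e-10)

    def test_level_005_at_p_100(self):
        assert critical_bound(100, 0.05).x == pytest.approx(6.2394106792016, abs=1e-9)

    def test_alpha0_cancellation_across_q(self):
        for q in (10, 100, 10_000, 1_000_000):
            simple = math.log(q) - 0.5 * math.log(math.log(q))
            assert abs(critical_bound(q, 0.431180).x - simple) < 1e-4

    def test_monotone_in_q_and_alpha(self):
        qs = [3, 10, 100, 10_000, 1_000_000]
        xs = [critical_bound(q, 0.05).x for q in qs]
        assert all(a < b for a, b in zip(xs, xs[1:]))
        alphas = [0.01, 0.05, 0.2, 0.5, 0.9]
        xs = [critical_bound(1000, a).x for a in alphas]
        assert all(a > b for a, b in zip(xs, xs[1:]))

    def test_small_alpha_approximation(self):
        # Replacing -2 log(-log(1-alpha)) by -2 log(alpha) errs by at most
        # alpha + alpha**2, vanishing as alpha -> 0.
        p = 100
        prev = math.inf
        for alpha in (0.05, 0.02, 0.01, 1e-3, 1e-5):
            approx = (
                2 * math.log(p) - math.log(math.log(p)) - 2 * math.log(alpha) - math.log(math.pi)
            )
            diff = abs(2 * critical_bound(p, alpha).x - approx)
            assert diff <= alpha + alpha**2
            assert diff < prev
            prev = diff

    def test_domain(self):
        with pytest.raises(ValueError):
            critical_bound(1, 0.05)
        with pytest.raises(ValueError):
            critical_bound(100, 0.0)
        with pytest.raises(ValueError):
            critical_bound(100, 1.0)
        with pytest.warns(UserWarning, match="q=2"):
            critical_bound(2, 0.05)


class TestFamilyMax:
    def test_single_and_empty(self):
        assert family_max_cdf(1.3, 1) == pytest.approx(half_chi2_cdf(1.3), abs=1e-14)
        assert family_max_cdf(0.7, 0) == 1.0

    def test_large_q_log_space(self):
        x = critical_bound(10_000, 0.05).x
        assert family_max_cdf(x, 10_000) == pytest.approx(0.9550189623, abs=1e-8)

    def test_fwer_complement(self):
        assert asymptotic_fwer(1, 1.0) == pytest.approx(0.1572992071, abs=1e-9)
        assert asymptotic_fwer(100, math.inf) == 0.0
        assert asymptotic_fwer(0, 1.0) == 0.0

    def test_limit_approaches_alpha_from_below(self):
        vals = [
            asymptotic_fwer(q, critical_bound(q, 0.05).x) for q in (100, 10_000, 1_000_000)
        ]
        assert vals == pytest.approx([0.04033177544, 0.04498103775, 0.04674918018], abs=1e-8)
        assert all(a < b < 0.05 for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("alpha", [0.05, 0.1, 0.43118])
    def test_convergence_tolerances(self, alpha):
        assert abs(asymptotic_fwer(10**6, critical_bound(10**6, alpha).x) - alpha) < 0.01
        assert abs(asymptotic_fwer(10**3, critical_bound(10**3, alpha).x) - alpha) < 0.02


class TestCoincidenceLevels:
    def test_alpha_ric_values(self):
        assert alpha_ric(100) == pytest.approx(0.231186639856, abs=1e-9)
        # Exact solutions at larger p (the large-p approximation 1/sqrt(pi log p)
        # differs: 0.186 and 0.152).
        assert alpha_ric(10**4) == pytest.approx(0.169646157955, abs=1e-9)
        assert alpha_ric(10**6) == pytest.approx(0.140830842271, abs=1e-9)
        with pytest.raises(ValueError):
            alpha_ric(2)

    def test_alpha_ric_defining_identity(self):
        for p in (10, 100, 10_000):
            assert 2 * critical_bound(p, alpha_ric(p)).x == pytest.approx(
                2 * math.log(p), abs=1e-10
            )

    def test_alpha_maic_values(self):
        assert alpha_maic(100, 0.5) == pytest.approx(0.0472083723988, abs=1e-9)
        assert alpha_maic(10**4, 0.5) == pytest.approx(0.0336169689308, abs=1e-9)
        assert alpha_maic(10**6, 0.5) == pytest.approx(0.0275339454607, abs=1e-9)

    def test_c_eaic_inverse(self):
        assert c_eaic(100, 0.0472) == pytest.approx(0.5, abs=1e-3)
        for p in (10, 100, 10_000):
            for alpha in (0.01, 0.05, 0.2, 0.5):
                assert alpha_maic(p, c_eaic(p, alpha)) == pytest.approx(alpha, abs=1e-12)

    def test_c_eaic_vanishes_with_alpha(self):
        cs = [c_eaic(100, a) for a in (0.2, 0.05, 0.01, 1e-4)]
        assert all(a > b > 0 for a, b in zip(cs, cs[1:]))

    def test_alpha_bic_equiv(self):
        alpha = alpha_bic_equiv(452914, 1692)
        assert alpha == pytest.approx(0.405630856815, abs=1e-9)
        assert critical_bound(1692, alpha).x == pytest.approx(
            math.log(452914) / 2, abs=1e-10
        )

    def test_alpha_bic_equiv_hits_alpha0(self):
        # When log(n)/2 equals log p - 0.5 log log p the level collapses to alpha0.
        p = 500
        n = math.exp(2 * math.log(p) - math.log(math.log(p)))
        assert alpha_bic_equiv(round(n), p) == pytest.approx(ALPHA0, abs=1e-5)

    def test_alpha_bic_equiv_out_of_range(self):
        # Tiny n with huge p pushes the solution to alpha = 1 exactly.
        with pytest.raises(ValueError):
            alpha_bic_equiv(2, 10**6)


class TestBicFwer:
    def test_formula_value(self):
        assert bic_fwer_approx(10**4, 100) == pytest.approx(0.2311866399, abs=1e-8)
        assert bic_fwer_approx(10**4, 0) == 0.0

    def test_matches_exact_within_ten_percent(self):
        for n in (10**3, 10**4, 10**5):
            exact = asymptotic_fwer(100, math.log(n) / 2)
            assert bic_fwer_approx(n, 100) == pytest.approx(exact, rel=0.10)

    def test_limits(self):
        # p growing faster than sqrt(n log n) drives the FWER to 1; p growing
        # slower drives it to 0.
        growing = [bic_fwer_approx(n, int(n**1.5)) for n in (10**3, 10**5, 10**7)]
        assert growing[-1] > 0.999
        shrinking = [bic_fwer_approx(n, int(n**0.3)) for n in (10**3, 10**5, 10**7)]
        assert all(a > b for a, b in zip(shrinking, shrinking[1:]))
        assert shrinking[-1] < 0.01


class TestMonteCarloOracle:
    @pytest.mark.parametrize("q, alpha", [(1000, 0.05), (100, 0.2), (3, 0.05)])
    def test_within_three_binomial_se(self, q, alpha):
        reps = 10_000
        est = mc_null_bound_check(q, alpha, reps=reps, seed=77)
        target = asymptotic_fwer(q, critical_bound(q, alpha).x)
        se = math.sqrt(target * (1 - target) / reps)
        assert abs(est - target) <= 3 * se

    def test_reproducible(self):
        a = mc_null_bound_check(200, 0.1, reps=500, seed=5)
        b = mc_null_bound_check(200, 0.1, reps=500, seed=5)
        assert a == b
        with pytest.raises(ValueError):
            mc_null_bound_check(10, 0.05, reps=50, seed=1)


@given(
    q=st.integers(min_value=2000, max_value=10**6),
    alpha=st.floats(min_value=1e-3, max_value=0.5),
)
def test_fwer_at_matched_bound_tracks_alpha(q, alpha):
    """In the large-q regime the FWER at the matched bound stays near alpha,
    and the complement identity with the family-max CDF holds exactly."""
    x = critical_bound(q, alpha).x
    fwer = asymptotic_fwer(q, x)
    assert fwer == pytest.approx(1.0 - family_max_cdf(x, q), abs=1e-12)
    assert abs(fwer - alpha) <= 0.02
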