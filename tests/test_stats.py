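"""Oracle checks for the four disproportionality statistics.

Each statistic is compared against an independent evaluation route:
hand-written closed forms for ROR/PRR/chi-square, numerical integration
of the exact posteriors for BCPNN and MGPS, and parameter recovery from
data simulated at known prior truth for the MGPS fit.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize, special, stats

import pvsignal as pv
from pvsignal.stats import mgps_loglik, posterior_mixture, ebgm_simplified


def T(a, b, c, d):
    return pv.ContingencyTable("X", "PT", a, b, c, d)


# ---------------------------------------------------------------------------
# ROR


def test_ror_symmetric_table_is_one():
    ror, lo, hi = pv.ror_with_ci(T(5, 5, 5, 5))
    assert ror == pytest.approx(1.0, abs=1e-12)
    assert lo < 1.0 < hi


def test_ror_closed_form_oracle():
    a, b, c, d = 20, 80, 100, 9800
    ror, lo, hi = pv.ror_with_ci(T(a, b, c, d))
    # independent evaluation of the cross-product ratio and ln-scale CI
    expect = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    assert ror == pytest.approx(expect, abs=1e-10)
    assert ror == pytest.approx(24.5, abs=1e-10)
    assert lo == pytest.approx(expect * math.exp(-z * se), abs=1e-10)
    assert hi == pytest.approx(expect * math.exp(z * se), abs=1e-10)
    assert (round(lo, 2), round(hi, 2)) == (14.45, 41.55)


def test_ror_zero_cell_haldane_correction():
    ror, _, _ = pv.ror_with_ci(T(0, 10, 5, 100))
    assert ror == pytest.approx((0.5 * 100.5) / (10.5 * 5.5), abs=1e-12)


def test_nonzero_table_not_corrected():
    ror, _, _ = pv.ror_with_ci(T(1, 1, 1, 1))
    assert ror == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# PRR


def test_prr_closed_form_and_yates_chi2_oracle():
    a, b, c, d = 20, 80, 100, 9800
    prr, chi2 = pv.prr_with_chi2(T(a, b, c, d))
    assert prr == pytest.approx((a / (a + b)) / (c / (c + d)), abs=1e-10)
    assert prr == pytest.approx(19.8, abs=1e-10)
    # Yates chi-square by the textbook formula
    n = a + b + c + d
    expect = (
        n * (abs(a * d - b * c) - n / 2) ** 2
        / ((a + b) * (c + d) * (a + c) * (b + d))
    )
    assert chi2 == pytest.approx(expect, abs=1e-8)
    assert chi2 == pytest.approx(285.3, abs=0.05)


def test_prr_symmetric_table():
    prr, chi2 = pv.prr_with_chi2(T(5, 5, 5, 5))
    assert prr == pytest.approx(1.0)
    assert chi2 == pytest.approx(0.0, abs=1e-12)


def test_prr_swapped_margin_identity():
    t = T(7, 13, 29, 51)
    prr, _ = pv.prr_with_chi2(t)
    prr_s, _ = pv.prr_with_chi2(t.swapped())
    assert prr_s == pytest.approx(1.0 / prr)


@settings(deadline=None, max_examples=100)
@given(a=st.integers(1, 100), b=st.integers(1, 100),
       c=st.integers(1, 100), d=st.integers(1, 100))
def test_ror_farther_from_one_than_prr(a, b, c, d):
    ror, _, _ = pv.ror_with_ci(T(a, b, c, d))
    prr, _ = pv.prr_with_chi2(T(a, b, c, d))
    assert (ror >= prr >= 1.0) or (ror <= prr <= 1.0) or (
        math.isclose(ror, prr)
    )


# ---------------------------------------------------------------------------
# BCPNN


def test_ic_point_zero_at_exact_independence():
    # expected a = (a+b)(a+c)/N = 10*100/1000 = 1 = a
    assert pv.ic_point(T(1, 9, 99, 891)) == pytest.approx(0.0, abs=1e-12)


def test_ic_point_example_table():
    assert pv.ic_point(T(20, 80, 100, 9800)) == pytest.approx(
        math.log2(16.0 + 2.0 / 3.0), abs=1e-10
    )


def test_bcpnn_posterior_mean_matches_numerical_integration():
    """E(IC) equals log2 of the ratio of posterior Beta means.

    The three margins have Beta posteriors; their means are evaluated by
    quadrature rather than in closed form.
    """
    t = T(20, 80, 100, 9800)
    n = t.n_total
    ic, ic025 = pv.bcpnn_ic(t)

    def beta_mean(x, u, v):
        f = lambda p: p * stats.beta.pdf(p, u, v)
        return integrate.quad(f, 0, 1, limit=200)[0]

    p = pv.BcpnnPrior()
    m11 = beta_mean(None, t.a + p.gamma11, 0 + (n - t.a) + _gamma(t) - p.gamma11)
    m1 = beta_mean(None, (t.a + t.b) + p.alpha1, (n - t.a - t.b) + p.alpha - p.alpha1)
    m2 = beta_mean(None, (t.a + t.c) + p.beta1, (n - t.a - t.c) + p.beta - p.beta1)
    assert ic == pytest.approx(math.log2(m11 / (m1 * m2)), abs=1e-8)
    assert ic025 < ic


def _gamma(t):
    p = pv.BcpnnPrior()
    n = t.n_total
    return p.gamma11 * (n + p.alpha) * (n + p.beta) / (
        (t.a + t.b + p.alpha1) * (t.a + t.c + p.beta1)
    )


def test_ic_increasing_in_a_with_margins_fixed():
    n, row, col = 10_000, 50, 60
    ics = []
    for a in range(1, 40):
        b, c = row - a, col - a
        ics.append(pv.bcpnn_ic(T(a, b, c, n - a - b - c))[0])
    assert all(x < y for x, y in zip(ics, ics[1:]))


# ---------------------------------------------------------------------------
# MGPS


def test_mgps_loglik_matches_scipy_nbinom_mixture():
    rng = np.random.default_rng(2)
    a = rng.integers(0, 30, size=200)
    e = rng.lognormal(0.5, 1.0, size=200)
    prior = pv.MgpsPrior(0.7, 1.3, 3.0, 0.8, 0.4)
    # independent evaluation: scipy's negative-binomial pmf, summed directly
    p1 = prior.beta1 / (prior.beta1 + e)
    p2 = prior.beta2 / (prior.beta2 + e)
    brute = np.log(
        prior.p_mix * stats.nbinom.pmf(a, prior.alpha1, p1)
        + (1 - prior.p_mix) * stats.nbinom.pmf(a, prior.alpha2, p2)
    ).sum()
    assert mgps_loglik(prior, a, e) == pytest.approx(brute, abs=1e-8)


def test_mgps_prior_parameter_recovery():
    """Fit recovers a known two-gamma mixture within 25% on 5,000 pairs."""
    truth = pv.MgpsPrior(alpha1=1.0, beta1=2.0, alpha2=4.0, beta2=0.5, p_mix=0.7)
    rng = np.random.default_rng(5)
    n = 5_000
    comp1 = rng.random(n) < truth.p_mix
    lam = np.where(
        comp1,
        rng.gamma(truth.alpha1, 1 / truth.beta1, n),
        rng.gamma(truth.alpha2, 1 / truth.beta2, n),
    )
    e = rng.lognormal(1.0, 1.0, n)
    a = rng.poisson(lam * e)
    fit = pv.fit_mgps_prior((a, e), seed=0)
    for name in ("alpha1", "beta1", "alpha2", "beta2", "p_mix"):
        t, f = getattr(truth, name), getattr(fit, name)
        assert abs(f - t) / t < 0.25, name


def test_mixture_likelihood_at_least_single_gamma():
    rng = np.random.default_rng(9)
    e = rng.lognormal(0.0, 1.0, 1000)
    lam = rng.gamma(2.0, 1.0 / 1.5, 1000)  # one gamma component only
    a = rng.poisson(lam * e)

    def single_nll(theta):
        al, be = np.exp(theta)
        return -mgps_loglik(pv.MgpsPrior(al, be, al, be, 1.0 - 1e-12), a, e)

    res = optimize.minimize(single_nll, [0.0, 0.0], method="Nelder-Mead")
    mix = pv.fit_mgps_prior((a, e), seed=0)
    assert mgps_loglik(mix, a, e) >= -res.fun - 1e-6


def test_ebgm_between_one_and_raw_ratio(canonical_prior):
    t = T(20, 80, 100, 9800)  # a/E = 16.67
    ebgm, ebgm05 = pv.ebgm_with_lb(t, canonical_prior)
    assert 1.0 < ebgm <= t.a / t.expected
    assert ebgm05 < ebgm


def test_ebgm_approaches_raw_ratio_at_large_counts(canonical_prior):
    # a/E fixed at 16.67 while a grows: shrinkage vanishes
    ratios = []
    for a in (100, 1_000, 10_000, 100_000):
        n = a * 500
        t = T(a, 4 * a, 5 * a, n - 10 * a)
        ebgm, _ = pv.ebgm_with_lb(t, canonical_prior)
        ratios.append(ebgm / (t.a / t.expected))
    assert all(x < y for x, y in zip(ratios, ratios[1:]))
    assert ratios[-1] > 0.999


def test_ebgm_posterior_matches_numerical_integration(canonical_prior):
    """Closed-form E[ln lambda] and the 5th percentile vs quadrature, 20 tables."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = int(rng.integers(0, 60))
        b = int(rng.integers(1, 500))
        c = int(rng.integers(1, 2_000))
        d = int(rng.integers(5_000, 200_000))
        t = T(a, b, c, d)
        ebgm, ebgm05 = pv.ebgm_with_lb(t, canonical_prior)
        q1, (s1, r1), (s2, r2) = posterior_mixture(t, canonical_prior)

        def dens(lam):
            return q1 * stats.gamma.pdf(lam, s1, scale=1 / r1) + (
                1 - q1
            ) * stats.gamma.pdf(lam, s2, scale=1 / r2)

        hi = max(ebgm * 30, 50.0)
        m = integrate.quad(lambda l: np.log(l) * dens(l), 0, hi, limit=400)[0]
        assert ebgm == pytest.approx(np.exp(m), abs=1e-6 * max(1.0, ebgm))
        mass = integrate.quad(dens, 0, ebgm05, limit=400)[0]
        assert mass == pytest.approx(0.05, abs=1e-6)


def test_ebgm_no_data_limit_near_prior_geometric_mean(canonical_prior):
    t = T(0, 3, 5, 2_000_000)  # E ~ 0: posterior ~ prior
    ebgm, _ = pv.ebgm_with_lb(t, canonical_prior)
    p = canonical_prior
    prior_gm = np.exp(
        p.p_mix * (special.digamma(p.alpha1) - np.log(p.beta1))
        + (1 - p.p_mix) * (special.digamma(p.alpha2) - np.log(p.beta2))
    )
    assert ebgm == pytest.approx(prior_gm, rel=0.02)


def test_shrinkage_stronger_at_smaller_counts(canonical_prior):
    # equal a/E = 10; the smaller table shrinks more
    small = T(5, 95, 50, 99_850)  # E = 0.5
    big = T(500, 9_500, 5_000, 9_985_000)  # E = 50
    eb_small, _ = pv.ebgm_with_lb(small, canonical_prior)
    eb_big, _ = pv.ebgm_with_lb(big, canonical_prior)
    assert abs(np.log(eb_small)) < abs(np.log(eb_big))


def test_ebgm_simplified_is_raw_ratio():
    t = T(20, 80, 100, 9800)
    point, lb = ebgm_simplified(t)
    assert point == pytest.approx(t.a / t.expected)
    assert 0 < lb < point


# ---------------------------------------------------------------------------
# thresholds


def test_minimum_count_rule_blocks_small_a():
    flags = pv.apply_thresholds(a=2, ror_lo=50.0, prr=100.0, chi2=500.0,
                                ic025=-1.0, ebgm05=0.1)
    assert not flags["ror_flag"] and not flags["prr_flag"]


def test_ic025_boundary_is_strict():
    flags = pv.apply_thresholds(a=10, ror_lo=2.0, prr=3.0, chi2=10.0,
                                ic025=0.0, ebgm05=3.0)
    assert not flags["bcpnn_flag"]
    assert flags["ror_flag"] and flags["prr_flag"] and flags["mgps_flag"]


def test_example_table_flags_all_four(canonical_prior):
    result = pv.compute_signal(T(20, 80, 100, 9800), canonical_prior)
    assert result.methods_flagged == {"ROR", "PRR", "BCPNN", "MGPS"}
    assert result.consensus_any and result.consensus_all


def test_prr_and_ebgm_coincide_at_large_counts():
    """At paper-scale counts (a in the hundreds, b << d) shrinkage is
    negligible and PRR ~ EBGM within 5%."""
    rng = np.random.default_rng(21)
    n_exposed, n_bg = 2_425, 18_000_000
    tables = []
    for i in range(200):  # null background pairs for the prior fit
        c = int(rng.integers(1_000, 200_000))
        a = int(rng.poisson(n_exposed * c / n_bg))
        tables.append(T(a, n_exposed - a, c, n_bg - c))
    signal = T(350, n_exposed - 350, 155_000, n_bg - 155_000)
    tables.append(signal)
    prior = pv.fit_mgps_prior(tables, seed=0)
    prr, _ = pv.prr_with_chi2(signal)
    ebgm, _ = pv.ebgm_with_lb(signal, prior)
    assert abs(prr - ebgm) / prr < 0.05
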