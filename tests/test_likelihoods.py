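"""Phylogeny and range likelihoods against closed forms and oracles."""

import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.optimize import minimize

import bdchrono as bc
from bdchrono._bdprob import PiecewiseBD
from bdchrono.likelihoods import SkylineRates
from bdchrono.treesim import PhyloData


@pytest.fixture(scope="module")
def phylo():
    return PhyloData(n=6, branching_ages=[9.0, 6.5, 4.0, 2.2, 0.7],
                     origin_age=12.0, rho=1.0)


def test_yule_limit_closed_form(phylo):
    """With mu = 0 and rho = 1 the likelihood is the Yule product
    e^(-lam t0) prod lam e^(-lam t_i)."""
    lam = 0.23
    expected = -lam * phylo.origin_age + sum(
        np.log(lam) - lam * t for t in phylo.branching_ages
    )
    assert bc.phylo_loglik(phylo, lam, 0.0) == pytest.approx(expected, abs=1e-10)


def test_origin_requires_t0_and_crown_requires_two_tips():
    p = PhyloData(n=3, branching_ages=[4.0, 1.0], origin_age=None)
    with pytest.raises(ValueError):
        bc.phylo_loglik(p, 0.3, 0.1, condition="origin")
    assert np.isfinite(bc.phylo_loglik(p, 0.3, 0.1, condition="crown"))
    single = PhyloData(n=1, branching_ages=[], origin_age=5.0)
    with pytest.raises(ValueError):
        bc.phylo_loglik(single, 0.3, 0.1, condition="crown")


def test_rate_domain_errors(phylo):
    with pytest.raises(ValueError):
        bc.phylo_loglik(phylo, 0.1, 0.2)          # lam <= mu
    with pytest.raises(ValueError):
        bc.phylo_loglik(phylo, -0.1, 0.0)
    # the constraint can be lifted for samplers over the full quadrant
    assert np.isfinite(bc.phylo_loglik(phylo, 0.1, 0.2, check_rates=False))


def test_crown_conditioning_value(phylo):
    """Crown form: both crown lineages conditioned on survival."""
    lam, mu = 0.3, 0.1
    k = PiecewiseBD([0.0], [lam], [mu])
    t1 = phylo.crown_age
    p0, lp1 = k.p0_logp1(np.array([t1]))
    expected = 2 * (lp1[0] - np.log1p(-p0[0]))
    rest = phylo.branching_ages[1:]
    p0r, lp1r = k.p0_logp1(rest)
    expected += np.sum(np.log(lam) + lp1r)
    assert bc.phylo_loglik(phylo, lam, mu, condition="crown") == pytest.approx(
        expected, abs=1e-12
    )


def test_branching_time_density_normalises():
    """For n = 3 the ordered branching-time density integrates to
    u(t0)^2 / 2 given survival, and the tip-count law sums to one."""
    lam, mu, t0 = 0.35, 0.15, 10.0
    k = PiecewiseBD([0.0], [lam], [mu])

    def integrand(t2, t1):
        return float(np.exp(k.log_p1(t1) + k.log_p1(t2))) * lam ** 2

    val, err = dblquad(integrand, 0, t0, 0, lambda t1: t1, epsabs=1e-10)
    u = float(k.u(t0))
    assert val == pytest.approx(u ** 2 / 2, abs=1e-4)
    p0 = float(k.p0(t0))
    p1 = float(np.exp(k.log_p1(t0)))
    # survival-conditioned tip-count law is geometric and sums to one
    total = sum((p1 / (1 - p0)) * u ** (n - 1) for n in range(1, 5000))
    assert total == pytest.approx(1.0, abs=1e-8)


def test_range_loglik_value_and_contracts():
    assert bc.range_loglik((0, 0, 10.0), 0.2, 0.1) == pytest.approx(-3.0)
    assert bc.range_loglik((2, 0, 10.0), 0.2, 0.0) == pytest.approx(
        2 * np.log(0.2) - 2.0
    )
    assert bc.range_loglik((2, 1, 10.0), 0.2, 0.0) == -np.inf
    with pytest.raises(ValueError):
        bc.range_loglik((1, 1, 0.0), 0.2, 0.1)
    with pytest.raises(ValueError):
        bc.range_loglik((1, 1, 5.0), 0.0, 0.1)


def test_range_mle_closed_form_vs_numeric():
    stats = (23, 11, 96.0)
    fr, boundary = bc.range_mle(stats)
    assert (fr.lambda_star, fr.mu_star) == pytest.approx((23 / 96, 11 / 96))
    assert not boundary

    res = minimize(
        lambda x: -bc.range_loglik(stats, np.exp(x[0]), np.exp(x[1])),
        [np.log(0.5), np.log(0.5)],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12},
    )
    assert np.exp(res.x[0]) == pytest.approx(fr.lambda_star, abs=1e-6)
    assert np.exp(res.x[1]) == pytest.approx(fr.mu_star, abs=1e-6)


def test_range_mle_boundary_flag():
    fr, boundary = bc.range_mle((0, 0, 12.0))
    assert boundary and fr.lambda_star == 0.0


def test_skyline_single_bin_equals_constant(phylo):
    lam, mu = 0.3, 0.12
    ll_const = bc.phylo_loglik(phylo, lam, mu)
    ll_sky = bc.skyline_phylo_loglik(phylo, SkylineRates((0.0,), (lam,), (mu,)))
    assert ll_sky == pytest.approx(ll_const, abs=1e-10)
    ll_split = bc.skyline_phylo_loglik(
        phylo, SkylineRates((0.0, 3.0, 8.0), (lam,) * 3, (mu,) * 3)
    )
    assert ll_split == pytest.approx(ll_const, abs=1e-10)


def test_skyline_range_consistency(small_tree):
    rs = bc.assign_chronospecies(small_tree,
                                 bc.BDCParams(0.2, 0.1, beta=0.5), seed=4)
    B, D, S = bc.range_statistics(rs)
    one = bc.range_bin_statistics(rs, [0.0])
    assert bc.skyline_range_loglik(one, [0.3], [0.2]) == pytest.approx(
        bc.range_loglik((B, D, S), 0.3, 0.2), abs=1e-10
    )
    three = bc.range_bin_statistics(rs, [0.0, 4.0, 9.0])
    assert bc.skyline_range_loglik(three, [0.3] * 3, [0.2] * 3) == pytest.approx(
        bc.range_loglik((B, D, S), 0.3, 0.2), abs=1e-10
    )
    assert three[:, 2].sum() == pytest.approx(S)


def test_skyline_phylo_against_distinct_rates(phylo):
    """Piecewise likelihood with genuinely different rates matches a
    direct evaluation via the ODE-validated kernels."""
    rates = SkylineRates((0.0, 3.0), (0.4, 0.2), (0.05, 0.15))
    k = PiecewiseBD(rates.boundaries, rates.lams, rates.mus)
    t0 = phylo.origin_age
    p0, lp1 = k.p0_logp1(np.array([t0]))
    expected = lp1[0] - np.log1p(-p0[0])
    for t in phylo.branching_ages:
        lam_t = 0.4 if t < 3.0 else 0.2
        expected += np.log(lam_t) + float(k.log_p1(t))
    assert bc.skyline_phylo_loglik(phylo, rates) == pytest.approx(
        expected, abs=1e-10
    )


def test_loglik_finite_in_interior(phylo):
    for lam, mu in [(0.05, 0.0), (0.5, 0.49), (2.0, 0.1)]:
        assert np.isfinite(bc.phylo_loglik(phylo, lam, mu))
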