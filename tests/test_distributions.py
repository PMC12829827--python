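"""Unit and oracle tests for the four count-family primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats
from scipy.integrate import quad

from countreg import distributions as d


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pig_pmf_quadrature(y: int, mu: float, tau: float) -> float:
    """Poisson(y; mu*v) integrated against the IG(mean 1, shape 1/tau) density."""
    shape = 1.0 / tau

    def integrand(v):
        ig = math.sqrt(shape / (2 * math.pi * v**3)) * math.exp(
            -shape * (v - 1) ** 2 / (2 * v)
        )
        logpois = -mu * v + y * math.log(mu * v) - special.gammaln(y + 1) if y else -mu * v
        return math.exp(logpois) * ig

    val, _ = quad(integrand, 0, np.inf, limit=200)
    return val


def bell_number_dobinski(y: int, terms: int = 400) -> float:
    """Dobinski series B_y = (1/e) * sum_d d^y / d!; float oracle."""
    ds = np.arange(1, terms)
    return float(np.exp(-1) * (np.sum(np.exp(y * np.log(ds) - special.gammaln(ds + 1))) + (1.0 if y == 0 else 0.0)))


# ---------------------------------------------------------------------------
# FamilySpec
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("family,disp,ok", [
    ("poisson", None, True), ("bell", None, True),
    ("negbin", 0.5, True), ("pig", 2.0, True),
    ("poisson", 0.5, False), ("bell", 1.0, False),
    ("negbin", -1.0, False), ("pig", 0.0, False),
    ("weibull", None, False),
])
def test_family_spec_validation(family, disp, ok):
    if ok:
        d.FamilySpec(family, disp)
    else:
        with pytest.raises(ValueError):
            d.FamilySpec(family, disp)


# ---------------------------------------------------------------------------
# Poisson / negative binomial
# ---------------------------------------------------------------------------

def test_poisson_logpmf_closed_forms():
    assert d.poisson_logpmf(0, 1.0) == pytest.approx(-1.0, abs=1e-14)
    assert d.poisson_logpmf(2, 2.0) == pytest.approx(math.log(2 * math.exp(-2)), abs=1e-12)
    ys = np.arange(201)
    assert np.exp(d.poisson_logpmf(ys, 5.0)).sum() == pytest.approx(1.0, abs=1e-12)


def test_poisson_negbin_match_scipy():
    ys = np.arange(30)
    assert np.allclose(d.poisson_logpmf(ys, 3.7), stats.poisson.logpmf(ys, 3.7))
    mu, nu = 2.5, 0.8
    n_sh, p_sh = 1 / nu, 1 / (1 + nu * mu)  # scipy nbinom parameterization
    assert np.allclose(d.negbin_logpmf(ys, mu, nu), stats.nbinom.logpmf(ys, n_sh, p_sh))


def test_negbin_p0_closed_form():
    # p(0) = (1 + nu*mu)^(-1/nu); at mu=nu=1 that is 1/2
    assert d.negbin_logpmf(0, 1.0, 1.0) == pytest.approx(math.log(0.5), abs=1e-12)


@pytest.mark.parametrize("fam_logpmf,disp", [
    (lambda y, mu: d.negbin_logpmf(y, mu, 1e-8), 1e-8),
    (lambda y, mu: d.pig_logpmf(y, np.full(len(np.atleast_1d(y)), mu), 1e-8), 1e-8),
])
def test_poisson_limit(fam_logpmf, disp):
    ys = np.arange(31)
    for mu in (0.5, 3.0, 10.0):
        diff = np.abs(fam_logpmf(ys, mu) - d.poisson_logpmf(ys, mu))
        assert diff.max() < 1e-4


def test_negbin_domain_errors():
    with pytest.raises(ValueError):
        d.negbin_logpmf(1, 2.0, -1.0)
    with pytest.raises(ValueError):
        d.poisson_logpmf(-1, 2.0)


# ---------------------------------------------------------------------------
# PIG
# ---------------------------------------------------------------------------

def test_pig_p0_closed_form():
    p = d.pig_pmf_vector(1.0, 1.0, 0)
    assert p[0] == pytest.approx(math.exp(1 - math.sqrt(3)), abs=1e-12)


def test_pig_normalizes():
    p = d.pig_pmf_vector(1.0, 1.0, 100)
    assert p.sum() == pytest.approx(1.0, abs=1e-10)


def test_pig_recurrence_matches_quadrature():
    p = d.pig_pmf_vector(3.0, 0.5, 30)
    q = np.array([pig_pmf_quadrature(y, 3.0, 0.5) for y in range(31)])
    assert np.abs(p - q).max() < 1e-8


def test_pig_log_space_deep_tail():
    lp = d.pig_logpmf(np.array([400]), np.array([2.0]), 0.5)
    assert np.isfinite(lp).all() and lp[0] < -100


def test_pig_domain_errors():
    with pytest.raises(ValueError):
        d.pig_pmf_vector(-1.0, 1.0, 10)
    with pytest.raises(ValueError):
        d.pig_pmf_vector(1.0, 1.0, -1)


# ---------------------------------------------------------------------------
# Bell
# ---------------------------------------------------------------------------

def test_bell_numbers_triangle_vs_dobinski():
    assert d.bell_numbers(5) == [1, 1, 2, 5, 15, 52]
    for y in (10, 25):
        exact = d.bell_numbers(y)[y]
        assert exact == pytest.approx(bell_number_dobinski(y), rel=1e-10)


def test_bell_logpmf_at_zero():
    assert d.bell_logpmf(0, 1.0) == pytest.approx(1 - math.e, abs=1e-12)


def test_bell_pmf_normalizes_and_mean():
    ys = np.arange(61)
    pm = np.exp(d.bell_logpmf(ys, np.ones(61)))
    assert pm.sum() == pytest.approx(1.0, abs=1e-10)
    assert (ys * pm).sum() == pytest.approx(math.e, abs=1e-10)


def test_bell_mean_to_lambda():
    assert d.bell_mean_to_lambda(math.e) == pytest.approx(1.0, abs=1e-12)
    assert d.bell_mean_to_lambda(1.0) == pytest.approx(0.5671432904097838, abs=1e-9)
    for lam in (0.1, 1.0, 3.0):
        assert d.bell_mean_to_lambda(lam * math.exp(lam)) == pytest.approx(lam, abs=1e-12)


# ---------------------------------------------------------------------------
# samplers: moment matching against the closed forms
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("spec,mu", [
    (d.FamilySpec("poisson"), 3.0),
    (d.FamilySpec("negbin", 0.5), 2.0),
    (d.FamilySpec("pig", 0.5), 3.0),
    (d.FamilySpec("bell"), math.e),
])
def test_sampler_moments(spec, mu, rng):
    n = 100_000
    x = d.family_rvs(spec, mu, (n,), rng)
    var = float(d.family_variance(spec, mu))
    # mean within 5 standard errors; variance within ~8 relative sigma
    assert abs(x.mean() - mu) < 5 * math.sqrt(var / n)
    assert x.var(ddof=1) == pytest.approx(var, rel=0.05)


def test_samplers_deterministic():
    a = d.family_rvs(d.FamilySpec("bell"), 2.0, (50,), np.random.default_rng(7))
    b = d.family_rvs(d.FamilySpec("bell"), 2.0, (50,), np.random.default_rng(7))
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    mu=st.floats(0.2, 8.0),
    tau=st.floats(0.05, 2.0),
)
def test_pig_pmf_is_a_distribution(mu, tau):
    # support long enough for the heavy PIG tail at large tau
    p = d.pig_pmf_vector(mu, tau, 600)
    assert np.all(p >= 0) and np.all(p <= 1)
    assert p.sum() == pytest.approx(1.0, abs=1e-8)
    ys = np.arange(601)
    assert (p * ys).sum() == pytest.approx(mu, rel=1e-6, abs=1e-6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(mean=st.floats(0.01, 50.0))
def test_lambert_round_trip(mean):
    lam = float(d.bell_mean_to_lambda(mean))
    assert lam > 0
    assert lam * math.exp(lam) == pytest.approx(mean, rel=1e-10)
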