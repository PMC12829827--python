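"""Exact pmf/log-pmf, moments and samplers for four count families.

The four families share a common mean parameterization ``E[Y] = mu`` used by
the log-link regressions in :mod:`countreg.glm`:

* Poisson(mu): equidispersed, Var = mu.
* Negative binomial NB(mu, nu): Poisson-gamma mixture, Var = mu + nu*mu**2.
* Poisson-inverse-Gaussian PIG(mu, tau): Poisson mean mixed over an
  inverse-Gaussian random effect with unit mean, Var = mu + tau*mu**2.
* Bell(lam): pmf proportional to lam**y * B_y / y! with Bell numbers B_y;
  mean lam*exp(lam), Var = lam*exp(lam)*(1 + lam).  The map between a Bell
  mean and its lam parameter is the principal Lambert W branch.

All likelihood-facing evaluation is done in log space; probability vectors
are only materialized on request.  Everything here is pure computation with
no file I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special

__all__ = [
    "FamilySpec",
    "FAMILIES",
    "poisson_logpmf",
    "negbin_logpmf",
    "pig_pmf_vector",
    "pig_logpmf",
    "bell_numbers",
    "log_bell_number",
    "bell_logpmf",
    "bell_mean_to_lambda",
    "poisson_rvs",
    "negbin_rvs",
    "pig_rvs",
    "bell_rvs",
    "family_rvs",
    "family_variance",
]

FAMILIES = ("poisson", "negbin", "pig", "bell")

#: families whose variance involves an extra dispersion parameter
DISPERSED_FAMILIES = ("negbin", "pig")


@dataclass(frozen=True)
class FamilySpec:
    """Identity of a count family plus its dispersion parameter, if any.

    Parameters
    ----------
    family : {"poisson", "negbin", "pig", "bell"}
    dispersion : float, optional
        ``nu`` for the negative binomial, ``tau`` for the PIG.  Must be
        strictly positive when given.  Poisson and Bell carry no dispersion
        parameter and reject one.
    """

    family: str
    dispersion: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family in DISPERSED_FAMILIES:
            if self.dispersion is not None and not self.dispersion > 0:
                raise ValueError(
                    f"{self.family} dispersion must be > 0, got {self.dispersion}"
                )
        elif self.dispersion is not None:
            raise ValueError(
                f"family {self.family!r} has no dispersion parameter "
                f"(got dispersion={self.dispersion})"
            )

    @property
    def has_dispersion(self) -> bool:
        return self.family in DISPERSED_FAMILIES


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    return y.astype(np.int64)


# ---------------------------------------------------------------------------
# Poisson
# ---------------------------------------------------------------------------

def poisson_logpmf(y, mu):
    """log P(Y=y) for Y ~ Poisson(mu); vectorized over both arguments."""
    y = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be > 0")
    return y * np.log(mu) - mu - special.gammaln(y + 1)


# ---------------------------------------------------------------------------
# Negative binomial (NB2: Poisson-gamma mixture, Var = mu + nu*mu^2)
# ---------------------------------------------------------------------------

def negbin_logpmf(y, mu, nu):
    """log P(Y=y) for the Poisson-gamma mixture with mean mu, Var mu+nu*mu^2.

    Parameterized so the gamma mixing density has shape 1/nu and unit mean;
    nu -> 0 recovers the Poisson.
    """
    y = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be > 0")
    if not np.all(np.asarray(nu) > 0):
        raise ValueError("nu must be > 0")
    a = 1.0 / nu  # gamma shape
    return (
        special.gammaln(y + a)
        - special.gammaln(a)
        - special.gammaln(y + 1)
        + a * np.log(a / (a + mu))
        + y * np.log(mu / (a + mu))
    )


# ---------------------------------------------------------------------------
# Poisson-inverse-Gaussian
# ---------------------------------------------------------------------------

def pig_pmf_vector(mu: float, tau: float, y_max: int) -> np.ndarray:
    """PIG probabilities p(0..y_max) at mean mu and dispersion tau.

    Seeded from the closed forms p(0) = exp([1 - sqrt(1+2*tau*mu)]/tau) (the
    pgf at z = 0) and p(1) = mu*(1+2*tau*mu)**-0.5 * p(0), then extended with
    the numerically stable two-term recurrence

        p(y) = 2*tau*mu/s * (1 - 3/(2y)) * p(y-1) + mu^2/s * p(y-2)/(y(y-1))

    with s = 1 + 2*tau*mu.  All terms are positive, so the recurrence incurs
    no cancellation.
    """
    if not (mu > 0 and tau > 0):
        raise ValueError("mu and tau must be > 0")
    if y_max < 0:
        raise ValueError("y_max must be >= 0")
    logp = pig_logpmf(np.arange(y_max + 1), mu, tau)
    return np.exp(logp)


def pig_logpmf(y, mu, tau):
    """log PIG pmf, vectorized over observations with per-observation means.

    Runs the probability recurrence up to max(y) for all means at once,
    rescaling whenever terms approach the underflow threshold so that counts
    far into the tail remain representable in log space.
    """
    scalar = np.isscalar(y) and np.isscalar(mu)
    y = _check_counts(np.atleast_1d(y))
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape).copy()
    if np.any(mu <= 0):
        raise ValueError("mu must be > 0")
    if not tau > 0:
        raise ValueError("tau must be > 0")

    s = 1.0 + 2.0 * tau * mu
    log_scale = np.zeros_like(mu)
    prev = np.exp((1.0 - np.sqrt(s)) / tau)          # p(0), scaled
    curr = mu / np.sqrt(s) * prev                     # p(1), scaled
    out = np.empty(y.shape, dtype=float)
    with np.errstate(divide="ignore"):
        out[y == 0] = np.log(prev[y == 0]) + log_scale[y == 0]
        out[y == 1] = np.log(curr[y == 1]) + log_scale[y == 1]
    ymax = int(y.max(initial=0))
    c1 = 2.0 * tau * mu / s
    c2 = mu * mu / s
    for n in range(2, ymax + 1):
        prev, curr = curr, c1 * (1.0 - 1.5 / n) * curr + c2 * prev / (n * (n - 1))
        tiny = curr < 1e-250
        if np.any(tiny):
            prev[tiny] *= 1e250
            curr[tiny] *= 1e250
            log_scale[tiny] -= 250 * math.log(10)
        sel = y == n
        if np.any(sel):
            with np.errstate(divide="ignore"):
                out[sel] = np.log(curr[sel]) + log_scale[sel]
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Bell
# ---------------------------------------------------------------------------

_BELL_CACHE: list[int] = [1]


def bell_numbers(n: int) -> list[int]:
    """Exact Bell numbers B_0..B_n via the Bell triangle.

    B_y counts the set partitions of y elements; B_0..B_5 = 1,1,2,5,15,52.
    Python integers keep the triangle exact at any order.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    global _BELL_CACHE
    while len(_BELL_CACHE) <= n:
        # row k of the triangle ends in B_{k+1}; rebuild from scratch each
        # extension -- cheap at the orders monthly counts reach
        row = [1]
        for _ in range(len(_BELL_CACHE) - 1):
            row = list(np.cumsum([row[-1]] + row, dtype=object))
        _BELL_CACHE.append(row[-1])
    return _BELL_CACHE[: n + 1]


def log_bell_number(y) -> np.ndarray:
    """log B_y as float; exact integers keep this correct to double precision."""
    y = _check_counts(np.atleast_1d(y))
    table = bell_numbers(int(y.max(initial=0)))
    return np.array([math.log(table[int(v)]) for v in y], dtype=float)


def bell_logpmf(y, lam):
    """log P(Y=y) = y*log(lam) + 1 - exp(lam) + log B_y - log y!  (lam > 0)."""
    scalar = np.isscalar(y) and np.isscalar(lam)
    y = _check_counts(np.atleast_1d(y))
    lam = np.broadcast_to(np.asarray(lam, dtype=float), y.shape)
    if np.any(lam <= 0):
        raise ValueError("lam must be > 0")
    out = (
        y * np.log(lam)
        + 1.0
        - np.exp(lam)
        + log_bell_number(y)
        - special.gammaln(y + 1)
    )
    return float(out[0]) if scalar else out


def bell_mean_to_lambda(mean):
    """Invert mean = lam*exp(lam) via the principal Lambert W branch."""
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("mean must be > 0")
    return np.real(special.lambertw(mean, k=0))


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def poisson_rvs(mu, size, rng: np.random.Generator):
    return rng.poisson(np.broadcast_to(mu, size))


def negbin_rvs(mu, nu, size, rng: np.random.Generator):
    """Gamma-Poisson mixture draw: exact for the NB2 parameterization."""
    g = rng.gamma(shape=1.0 / nu, scale=nu, size=size)
    return rng.poisson(np.broadcast_to(mu, size) * g)


def pig_rvs(mu, tau, size, rng: np.random.Generator):
    """Poisson mixed over IG(mean 1, shape 1/tau): exact PIG draw."""
    v = rng.wald(1.0, 1.0 / tau, size=size)
    return rng.poisson(np.broadcast_to(mu, size) * v)


def _ztp_rvs(lam: float, size: int, rng: np.random.Generator):
    """Zero-truncated Poisson via inverse cdf (stable for small lam)."""
    from scipy.stats import poisson as _pois

    if size == 0:
        return np.zeros(0, dtype=np.int64)
    p0 = math.exp(-lam)
    u = rng.uniform(size=size)
    return _pois.ppf(p0 + u * (1.0 - p0), lam).astype(np.int64)


def bell_rvs(lam, size, rng: np.random.Generator):
    """Exact Bell draws via the compound-Poisson construction.

    Y = sum of N iid zero-truncated Poisson(lam) variates with
    N ~ Poisson(exp(lam) - 1), which has exactly the Bell(lam) pgf.
    """
    lam = np.broadcast_to(np.asarray(lam, dtype=float), size)
    if np.any(lam <= 0):
        raise ValueError("lam must be > 0")
    n_summands = rng.poisson(np.expm1(lam))
    out = np.zeros(lam.shape, dtype=np.int64)
    # group identical lam values so the ZTP draws stay vectorized
    flat_lam = lam.ravel()
    flat_n = n_summands.ravel()
    flat_out = out.ravel()
    for value in np.unique(flat_lam):
        idx = np.flatnonzero(flat_lam == value)
        counts = flat_n[idx]
        total = int(counts.sum())
        draws = _ztp_rvs(float(value), total, rng)
        ends = np.cumsum(counts)
        sums = np.add.reduceat(draws, np.r_[0, ends[:-1]]) if total else np.zeros(len(idx))
        sums = np.where(counts > 0, sums, 0)
        flat_out[idx] = sums.astype(np.int64)
    return out


def family_rvs(spec: FamilySpec, mu, size, rng: np.random.Generator):
    """Draw counts with mean ``mu`` from the family named by ``spec``."""
    if spec.family == "poisson":
        return poisson_rvs(mu, size, rng)
    if spec.family == "negbin":
        if spec.dispersion is None:
            raise ValueError("negbin sampling requires a dispersion value")
        return negbin_rvs(mu, spec.dispersion, size, rng)
    if spec.family == "pig":
        if spec.dispersion is None:
            raise ValueError("pig sampling requires a dispersion value")
        return pig_rvs(mu, spec.dispersion, size, rng)
    lam = bell_mean_to_lambda(mu)
    return bell_rvs(lam, size, rng)


def family_variance(spec: FamilySpec, mu):
    """Closed-form Var[Y] at mean mu for the named family."""
    mu = np.asarray(mu, dtype=float)
    if spec.family == "poisson":
        return mu
    if spec.family in DISPERSED_FAMILIES:
        if spec.dispersion is None:
            raise ValueError(f"{spec.family} variance requires a dispersion value")
        return mu + spec.dispersion * mu**2
    lam = bell_mean_to_lambda(mu)
    return mu * (1.0 + lam)
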