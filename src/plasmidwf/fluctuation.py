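"""Luria-Delbruck fluctuation analysis of parallel-culture mutant counts.

The number of mutants in a culture grown from a small inoculum is highly
skewed ("jackpot" cultures), because a mutation arising early contributes
exponentially many descendants.  Under the classical model — deterministic
exponential growth, Poisson-distributed mutation events, relative mutant
fitness 1, no phenotypic delay, no plating losses — the mutant count is a
compound Poisson variable: the number of mutational events per culture is
``Poisson(m)`` and each event founds a clone whose size ``s`` has
``P(size >= s) = 1/s`` (equivalently ``P(size = k) = 1/(k(k+1))``).

The probability mass function ``p_k(m)`` follows the Ma-Sandri-Sarkar (MSS)
recursion, i.e. the Panjer recursion of this compound Poisson law::

    p_0 = exp(-m)
    p_k = (m / k) * sum_{j=0}^{k-1} p_j / (k - j + 1)

Two estimators of ``m`` (expected mutational events per culture) are
provided: the p0 method, ``m = -ln(z / R)`` from the fraction of cultures
with zero mutants, and the MSS maximum-likelihood estimator with
profile-likelihood confidence intervals.  The phenotypic mutation rate is
``m / N_t`` with ``N_t`` the final number of cells per culture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .errors import ConfigurationError, EstimationError

#: Half the chi-square(1 df) 95% quantile: profile log-likelihood drop for a 95% CI.
_PROFILE_DROP_95 = float(chi2.ppf(0.95, df=1) / 2.0)  # == 1.9207...

#: Counts at or above this value enter the likelihood as a censored tail class.
DEFAULT_CENSOR_AT = 1000


@dataclass
class FluctuationDataset:
    """Mutant counts from ``R`` parallel cultures of final size ``n_final`` cells."""

    counts: np.ndarray
    n_final: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) < 2:
            raise ConfigurationError("need counts from at least 2 parallel cultures")
        if (self.counts < 0).any():
            raise ConfigurationError("mutant counts must be non-negative")
        if self.n_final < self.counts.max():
            raise ConfigurationError("n_final must be >= the largest mutant count")

    @property
    def n_cultures(self) -> int:
        return len(self.counts)


@dataclass
class MutationRateEstimate:
    """Estimated mutational events per culture and per-cell mutation rate.

    ``rate = m_hat / n_final`` with a 95% confidence interval
    ``[ci_low, ci_high]`` on the rate scale; ``m_ci`` carries the same
    interval on the ``m`` scale.
    """

    m_hat: float
    rate: float
    ci_low: float
    ci_high: float
    method: str
    m_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "m_hat": self.m_hat,
            "rate": self.rate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
        }


def ld_pmf(m: float, k_max: int) -> np.ndarray:
    """Luria-Delbruck probabilities ``p_0 .. p_kmax`` via the MSS recursion."""
    if m < 0:
        raise ConfigurationError(f"m={m} must be non-negative")
    if k_max < 0:
        raise ConfigurationError("k_max must be non-negative")
    p = np.zeros(k_max + 1)
    p[0] = np.exp(-m)
    if k_max == 0 or m == 0.0:
        return p
    # Panjer weight i * q_i with clone-size pmf q_i = 1/(i(i+1)), i >= 1
    i = np.arange(1, k_max + 1, dtype=float)
    w = 1.0 / (i + 1.0)
    for k in range(1, k_max + 1):
        # sum_{j<k} p_j * w_{k-j}: dot with the reversed weight prefix
        p[k] = (m / k) * np.dot(p[:k], w[k - 1 :: -1])
    return p


def ld_sample(
    m: float,
    n_final: float,
    n_cultures: int,
    rng: np.random.Generator,
) -> FluctuationDataset:
    """Draw mutant counts for ``n_cultures`` parallel cultures.

    Events per culture are ``Poisson(m)``; each event founds a clone of
    size ``floor(1/u)`` with ``u ~ Uniform(0, 1]`` (so ``P(size >= s) = 1/s``),
    capped at the final population size.
    """
    if m < 0 or n_final < 1 or n_cultures < 2:
        raise ConfigurationError("require m >= 0, n_final >= 1, n_cultures >= 2")
    events = rng.poisson(m, n_cultures)
    total = int(events.sum())
    u = 1.0 - rng.random(total)  # in (0, 1]
    sizes = np.minimum(np.floor(1.0 / u), n_final).astype(np.int64)
    owner = np.repeat(np.arange(n_cultures), events)
    counts = np.bincount(owner, weights=sizes, minlength=n_cultures).astype(np.int64)
    counts = np.minimum(counts, int(n_final))
    return FluctuationDataset(counts=counts, n_final=float(n_final))


def pmf_total_variation(counts: Sequence[int] | np.ndarray, m: float, k_cap: int = 50) -> float:
    """Total-variation distance between empirical counts and ``ld_pmf(m)``.

    Both distributions are truncated to ``{0..k_cap-1}`` with all larger
    counts lumped into one tail class, which keeps the Monte-Carlo error of
    the statistic bounded despite the heavy tail.
    """
    counts = np.asarray(counts, dtype=np.int64)
    p = ld_pmf(m, k_cap)
    model = np.append(p[:k_cap], max(0.0, 1.0 - p[:k_cap].sum()))
    clipped = np.minimum(counts, k_cap)
    emp = np.bincount(clipped, minlength=k_cap + 1) / len(counts)
    return float(0.5 * np.abs(model - emp).sum())


def estimate_p0(data: FluctuationDataset, confidence: float = 0.95) -> MutationRateEstimate:
    """p0-method estimate ``m = -ln(z/R)`` from the zero-count culture fraction.

    The confidence interval is a Clopper-Pearson binomial interval on the
    zero fraction, propagated through ``-ln``.
    """
    r = data.n_cultures
    z = int((data.counts == 0).sum())
    if z == 0:
        raise EstimationError(
            "p0 method inapplicable: no culture with zero mutants; use the MLE"
        )
    alpha = 1.0 - confidence
    m_hat = -np.log(z / r)
    p_low = float(beta_dist.ppf(alpha / 2, z, r - z + 1)) if z > 0 else 0.0
    p_high = float(beta_dist.ppf(1 - alpha / 2, z + 1, r - z)) if z < r else 1.0
    m_low = -np.log(p_high)  # high zero-fraction -> low m
    m_high = -np.log(p_low) if p_low > 0 else np.inf
    m_low = max(0.0, m_low)
    return MutationRateEstimate(
        m_hat=float(m_hat),
        rate=float(m_hat / data.n_final),
        ci_low=float(m_low / data.n_final),
        ci_high=float(m_high / data.n_final),
        method="p0",
        m_ci=(float(m_low), float(m_high)),
    )


def _log_likelihood_factory(counts: np.ndarray, censor_at: int | None):
    """Build ``loglik(m)`` with counts >= censor_at pooled into a tail class."""
    k_obs = int(counts.max())
    if censor_at is not None and k_obs >= censor_at:
        cap = int(censor_at)
        censored = int((counts >= cap).sum())
        hist = np.bincount(counts[counts < cap], minlength=cap)
    else:
        cap = k_obs + 1
        censored = 0
        hist = np.bincount(counts, minlength=cap)
    k_eval = cap - 1

    def loglik(m: float) -> float:
        p = ld_pmf(m, k_eval)
        ll = float(np.dot(hist, np.log(np.maximum(p, 1e-300))))
        if censored:
            tail = max(1.0 - p.sum(), 1e-300)
            ll += censored * np.log(tail)
        return ll

    return loglik


def estimate_mle(
    data: FluctuationDataset,
    censor_at: int | None = DEFAULT_CENSOR_AT,
    confidence: float = 0.95,
) -> MutationRateEstimate:
    """MSS maximum-likelihood estimate of ``m`` with profile-likelihood CI.

    Counts at or above ``censor_at`` contribute through the exact censored
    tail probability, which keeps the recursion depth bounded for jackpot
    cultures without biasing the estimate.  When every culture has zero
    mutants the MLE sits on the boundary ``m = 0`` and a one-sided interval
    is returned.
    """
    counts = data.counts
    r = data.n_cultures
    drop = _PROFILE_DROP_95 if confidence == 0.95 else float(chi2.ppf(confidence, 1) / 2)

    if counts.max() == 0:
        # loglik(m) = -R m, maximised at the boundary m = 0.
        m_high = drop / r
        return MutationRateEstimate(
            m_hat=0.0,
            rate=0.0,
            ci_low=0.0,
            ci_high=float(m_high / data.n_final),
            method="mle",
            m_ci=(0.0, float(m_high)),
        )

    loglik = _log_likelihood_factory(counts, censor_at)

    hi = max(10.0, 2.0 * float(np.mean(np.minimum(counts, censor_at or counts.max()))) + 10.0)
    for _ in range(20):
        res = minimize_scalar(
            lambda m: -loglik(m), bounds=(1e-9, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        m_hat = float(res.x)
        if m_hat < 0.95 * hi:
            break
        hi *= 4.0
    ll_max = loglik(m_hat)
    target = ll_max - drop

    def profile(m: float) -> float:
        return loglik(m) - target

    # Lower bound: either interior root in (0, m_hat) or pinned at 0.
    lo_eps = m_hat * 1e-9
    if profile(lo_eps) >= 0:
        m_low = 0.0
    else:
        m_low = float(brentq(profile, lo_eps, m_hat, rtol=1e-10))
    # Upper bound: expand until the profile drops below the cutoff.
    upper = m_hat * 2 + 1.0
    for _ in range(200):
        if profile(upper) < 0:
            break
        upper *= 2.0
    else:
        raise EstimationError("profile likelihood upper bound not found")
    m_high = float(brentq(profile, m_hat, upper, rtol=1e-10))

    return MutationRateEstimate(
        m_hat=m_hat,
        rate=float(m_hat / data.n_final),
        ci_low=float(m_low / data.n_final),
        ci_high=float(m_high / data.n_final),
        method="mle",
        m_ci=(m_low, m_high),
    )


def estimate(
    data: FluctuationDataset,
    method: str = "mle",
    **kwargs,
) -> MutationRateEstimate:
    """Dispatch to :func:`estimate_p0` or :func:`estimate_mle`."""
    if method == "p0":
        return estimate_p0(data, **kwargs)
    if method == "mle":
        return estimate_mle(data, **kwargs)
    raise ConfigurationError(f"unknown estimation method {method!r}; use 'p0' or 'mle'")
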