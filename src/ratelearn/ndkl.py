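"""The nDKL statistic for comparing two exponential (Poisson) rates.

The Kullback-Leibler divergence of one exponential distribution from
another depends only on the two rate parameters,

    D_KL(X || Y) = ln(lambda_X / lambda_Y) + lambda_Y / lambda_X - 1 ,

and under the null hypothesis of equal true rates the divergence scaled by
the *effective* sample size

    n_e = n_X / (1 + n_X / n_Y)

is distributed Gamma(1/2, 1).  The product ``n_e * D_KL`` -- the nDKL -- is
therefore a self-calibrating measure of the strength of evidence that two
event rates differ: it can be evaluated after every new observation without
pre-committing to a sample size, and converts directly to odds or p-values
through the Gamma(1/2, 1) tail.

All values are in nats; multiply by log2(e) ~= 1.4427 to convert to bits.
The Gamma(1/2, 1) tail equals the upper tail of a chi-square(1) variable at
twice the statistic, so either special function may be used; scipy's gamma
distribution is used here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import gamma as _gamma

__all__ = [
    "RatePair",
    "NdklResult",
    "dkl_exponential",
    "effective_n",
    "ndkl",
    "ndkl_to_p",
    "p_to_ndkl",
    "odds_to_threshold",
    "threshold_to_odds",
    "NATS_TO_BITS",
]

#: multiply nats by this to obtain bits
NATS_TO_BITS = math.log2(math.e)

# Gamma(shape=1/2, scale=1): the null distribution of the nDKL for
# exponential data (one-parameter family).
_NULL = _gamma(0.5, scale=1.0)


@dataclass(frozen=True)
class RatePair:
    """Counts and estimated rates for the two samples being compared.

    ``x`` is the sample whose divergence *from* ``y`` is measured
    (conventionally the CS sample, with ``y`` the contextual sample).
    """

    n_x: float
    lambda_x: float
    n_y: float
    lambda_y: float

    @property
    def defined(self) -> bool:
        """The statistic requires positive rates and a nonempty x sample."""
        return self.n_x > 0 and self.lambda_x > 0 and self.lambda_y > 0 and self.n_y > 0


@dataclass(frozen=True)
class NdklResult:
    """Outcome of an nDKL evaluation.

    ``ndkl`` is the magnitude ``n_effective * dkl`` (always >= 0);
    ``sign`` is +1 when lambda_x > lambda_y, else -1; ``p_value`` is the
    Gamma(1/2, 1) upper-tail probability of the magnitude.  When the
    statistic is undefined (a zero rate or empty sample), ``defined`` is
    False and the numeric fields are NaN -- no value is fabricated.
    """

    dkl: float
    n_effective: float
    ndkl: float
    sign: int
    p_value: float
    defined: bool

    @property
    def signed_ndkl(self) -> float:
        return self.sign * self.ndkl

    @property
    def ndkl_bits(self) -> float:
        return self.ndkl * NATS_TO_BITS


def dkl_exponential(lambda_x: float, lambda_y: float) -> float:
    """KL divergence (nats) of an exponential with rate ``lambda_x`` from
    one with rate ``lambda_y``.

    Returns NaN (an undefined-result marker, not an exception) when either
    rate is non-positive.  The divergence is non-negative, zero iff the
    rates are equal, and asymmetric in its arguments.
    """
    if lambda_x <= 0 or lambda_y <= 0:
        return math.nan
    r = lambda_x / lambda_y
    return math.log(r) + 1.0 / r - 1.0


def effective_n(n_x: float, n_y: float) -> float:
    """Effective sample size ``n_x / (1 + n_x/n_y)``.

    Bounded above by ``n_x`` and tends to ``n_x`` as ``n_y`` grows; kept
    exact (fractional values like 2.5 are not rounded).  Returns NaN when
    either count is non-positive.
    """
    if n_x <= 0 or n_y <= 0:
        return math.nan
    return n_x / (1.0 + n_x / n_y)


def ndkl(pair: RatePair, signed: bool = True) -> NdklResult:
    """Evaluate the nDKL for a pair of rate estimates.

    The p-value is always computed from the magnitude; the sign (only
    attached when ``signed``) records the direction of the rate difference
    so that "CS rate below contextual rate" trials can be distinguished.
    """
    if not pair.defined:
        return NdklResult(math.nan, math.nan, math.nan, 0, math.nan, False)
    d = dkl_exponential(pair.lambda_x, pair.lambda_y)
    ne = effective_n(pair.n_x, pair.n_y)
    stat = ne * d
    sign = 1 if (pair.lambda_x >= pair.lambda_y or not signed) else -1
    return NdklResult(d, ne, stat, sign, ndkl_to_p(stat), True)


def ndkl_to_p(stat: float) -> float:
    """Upper-tail probability of Gamma(1/2, 1) at ``stat`` nats."""
    if math.isnan(stat):
        return math.nan
    return float(_NULL.sf(stat))


def p_to_ndkl(p: float) -> float:
    """Inverse of :func:`ndkl_to_p`."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    return float(_NULL.isf(p))


def odds_to_threshold(odds_against_null: float) -> float:
    """nDKL decision threshold (nats) for given odds against the null.

    Odds of q:1 correspond to a null tail probability of 1/(q+1); the
    threshold is the Gamma(1/2, 1) quantile at 1 - 1/(q+1).  Odds 4:1 give
    0.82 nats and 19:1 (p < .05) give 1.92 nats.
    """
    if odds_against_null <= 0:
        raise ValueError("odds must be positive")
    return p_to_ndkl(1.0 / (odds_against_null + 1.0))


def threshold_to_odds(threshold: float) -> float:
    """Odds against the null corresponding to an nDKL threshold."""
    p = ndkl_to_p(threshold)
    return 1.0 / p - 1.0
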