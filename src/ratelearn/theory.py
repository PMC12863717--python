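"""Informativeness, the learning-rate law, the generative response model,
and rate-estimation-theory credit assignment.

The informativeness of a conditioning protocol is iota = C/T, the ratio
of the reinforcement rate expected during the CS (1/T) to the contextual
rate (1/C).  Its natural log is the mutual information CS onset conveys
about the wait to the next reinforcement.  Trials-to-acquisition scales
inversely with informativeness: on log-log axes the group medians follow
a line of slope about -1 whose x-intercept is the informativeness that
yields one-trial acquisition.

The generative response model turns this law into a per-trial mechanism:
on every reinforced trial the subject starts responding to the CS with
probability

    p = 1 - exp(-k * (iota - 1)) ,

independently across trials (a geometric onset time).  With k = 1/297 the
median onset is 1 trial at iota = 300 and about 100 trials at iota = 3.

Rate estimation theory (RET) ascribes observed reinforcement rates to
co-occurring predictors under additivity: for a one-CS protocol the
ascribed rates solve a 2x2 linear system whose only non-unit element is
1/iota.  Ascribed rates may be negative and are reported raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .ndkl import NATS_TO_BITS

__all__ = [
    "InformativenessRecord",
    "informativeness",
    "prospective_mutual_info",
    "retrospective_mutual_info",
    "GenerativeModelParams",
    "response_probability",
    "ResponseProbability",
    "LearningRateModel",
    "LearningRateResults",
    "fit_learning_rate_regression",
    "RETRates",
    "ret_solve",
    "DEFAULT_K",
]

#: per-unit-informativeness probability constant of the generative model
DEFAULT_K = 1.0 / 297.0


@dataclass(frozen=True)
class InformativenessRecord:
    """Informativeness and its detection-delay-adjusted value."""

    iota: float
    mutual_info_nats: float
    effective_iota: float
    delay: float = 0.0

    @property
    def mutual_info_bits(self) -> float:
        return self.mutual_info_nats * NATS_TO_BITS


def informativeness(C: float, T: float, delay: float = 0.0) -> InformativenessRecord:
    """iota = C/T with an optional US-detection delay added to both terms.

    A delay of ``delta`` seconds in finding the pellet stretches both the
    effective CS-US and US-US intervals, giving effective informativeness
    (C + delta)/(T + delta) -- a large relative loss when iota is high.
    """
    if not (C > T > 0):
        raise ValueError("require C > T > 0")
    if delay < 0:
        raise ValueError("delay must be non-negative")
    iota = C / T
    return InformativenessRecord(iota, math.log(iota), (C + delay) / (T + delay), delay)


def prospective_mutual_info(wait_unconditional: float, wait_conditional: float) -> float:
    """ln(unconditional wait / conditional wait), in nats.

    Negative when the cue lengthens the expected wait (an inhibitory cue);
    the value is returned as-is.
    """
    if wait_unconditional <= 0 or wait_conditional <= 0:
        raise ValueError("waits must be positive")
    return math.log(wait_unconditional / wait_conditional)


#: identical in form to the prospective variant, looking back from each
#: reinforcement to the most recent cue event
retrospective_mutual_info = prospective_mutual_info


@dataclass(frozen=True)
class GenerativeModelParams:
    k_rate: float = DEFAULT_K

    def __post_init__(self):
        if self.k_rate <= 0:
            raise ValueError("k must be positive")


@dataclass(frozen=True)
class ResponseProbability:
    """Per-trial and cumulative response probabilities under the model."""

    iota: float
    k_rate: float
    p_per_trial: float
    cumulative: float  # after n trials
    n: int
    median_trials: Optional[int]  # None when p == 0


def response_probability(
    iota: float, params: GenerativeModelParams = GenerativeModelParams(), n: int = 1
) -> ResponseProbability:
    """Probability of response onset within ``n`` reinforced trials.

    p = 1 - exp(-k*(iota-1)) per trial, independent across trials, so the
    cumulative probability after n trials is 1 - (1-p)**n and the median
    onset is the smallest n with cumulative probability >= 0.5.
    """
    if iota < 1:
        raise ValueError("informativeness must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    p = 1.0 - math.exp(-params.k_rate * (iota - 1.0))
    cum = 1.0 - (1.0 - p) ** n
    if p <= 0:
        median = None
    else:
        median = max(1, math.ceil(math.log(0.5) / math.log(1.0 - p)))
    return ResponseProbability(iota, params.k_rate, p, cum, n, median)


@dataclass
class LearningRateResults:
    """Fitted learning-rate law: RtoAcq = ((iota - 1)/k) ** s.

    ``k`` is the x-intercept on the (iota - 1) axis -- the excess
    informativeness producing one-trial acquisition regardless of the
    fitted slope ``s`` (this re-parameterisation keeps the intercept
    interpretation when s != -1).  ``one_trial_iota`` = k + 1.
    """

    slope: float
    slope_ci: tuple[float, float]
    k: float
    r_squared: float
    n_groups: int
    intercept_log10: float

    @property
    def one_trial_iota(self) -> float:
        return self.k + 1.0

    def predict_median(self, iota: np.ndarray) -> np.ndarray:
        return ((np.asarray(iota, float) - 1.0) / self.k) ** self.slope

    def summary(self) -> str:
        return (
            f"Learning-rate law fit over {self.n_groups} groups\n"
            f"  slope s        {self.slope:8.3f}  CI95 [{self.slope_ci[0]:.3f}, "
            f"{self.slope_ci[1]:.3f}]\n"
            f"  x-intercept k  {self.k:8.1f}  (one-trial informativeness "
            f"{self.one_trial_iota:.1f})\n"
            f"  R^2            {self.r_squared:8.3f}"
        )


class LearningRateModel:
    """log-log regression of group-median trials-to-acquisition on iota - 1."""

    def __init__(self, medians: Sequence[float], iotas: Sequence[float]):
        med = np.asarray(medians, dtype=float)
        iot = np.asarray(iotas, dtype=float)
        if len(med) != len(iot) or len(med) < 3:
            raise ValueError("need >= 3 aligned (median, iota) pairs")
        if np.any(iot <= 1):
            raise ValueError("all informativeness values must exceed 1")
        if np.any(med <= 0):
            raise ValueError("medians must be positive")
        self.medians = med
        self.iotas = iot

    def fit(self) -> LearningRateResults:
        x = np.log10(self.iotas - 1.0)
        y = np.log10(self.medians)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        a, s = res.params
        ci = res.conf_int()[1]
        # y = a + s*x  ==>  log10 RtoAcq = s * log10((iota-1)/k), k = 10**(-a/s)
        k = 10.0 ** (-a / s) if s != 0 else math.nan
        return LearningRateResults(
            slope=float(s),
            slope_ci=(float(ci[0]), float(ci[1])),
            k=float(k),
            r_squared=float(res.rsquared),
            n_groups=len(x),
            intercept_log10=float(a),
        )


def fit_learning_rate_regression(
    medians: Sequence[float], iotas: Sequence[float]
) -> LearningRateResults:
    """Functional wrapper around :class:`LearningRateModel`."""
    return LearningRateModel(medians, iotas).fit()


@dataclass(frozen=True)
class RETRates:
    """Observed and ascribed reinforcement rates for a one-CS protocol."""

    iota: float
    observed_context: float  # lambda_R|C
    observed_cs_context: float  # lambda_R|C&CS
    ascribed_context: float  # lambda-hat_R|C&~CS
    ascribed_cs: float  # lambda-hat_R|CS

    @property
    def observed(self) -> tuple[float, float]:
        return (self.observed_context, self.observed_cs_context)

    @property
    def ascribed(self) -> tuple[float, float]:
        return (self.ascribed_context, self.ascribed_cs)


def ret_solve(iota: float, observed: tuple[float, float]) -> RETRates:
    """Ascribe observed reinforcement rates to context and CS.

    Solves [[1, 1/iota], [1, 1]] @ ascribed = observed exactly.  Singular
    at iota = 1 (the truly random control, where credit cannot be
    assigned); negative ascribed rates are reported raw, without clamping.
    """
    if iota == 1:
        raise ValueError("matrix is singular at informativeness 1")
    m = np.array([[1.0, 1.0 / iota], [1.0, 1.0]])
    asc = np.linalg.solve(m, np.asarray(observed, dtype=float))
    return RETRates(iota, observed[0], observed[1], float(asc[0]), float(asc[1]))
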