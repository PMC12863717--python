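"""Trials-to-acquisition estimation from cumulative response rates.

A subject has acquired the conditioned response when its response rate
during the CS exceeds the overall (contextual) response rate.  Working
trial by trial, we form the cumulative CS response rate (cumulative CS
pokes / cumulative CS exposure) and the cumulative contextual rate
(CS + pre-CS pokes over CS + pre-CS exposure, so the context includes the
CS), attach the signed nDKL to each trial, and define:

* the *exceedance* trial: when the CS-minus-context rate difference
  becomes permanently positive within the observed record (reinforcements
  to acquisition is the trial before);
* threshold criteria: the trial when the nDKL -- recomputed starting from
  the exceedance trial, so that pre-acquisition trials do not dilute the
  evidence -- permanently exceeds a decision threshold such as 0.82 nats
  (odds 4:1) or 1.92 nats (p < .05).

"Permanently" is judged within the record; trials where the statistic is
undefined (no pokes yet in one of the samples) are skipped, and exact
zeros count as not-greater.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .events import TrialSummary
from .ndkl import RatePair, ndkl, odds_to_threshold

__all__ = [
    "CumulativeRateSeries",
    "AcquisitionProfile",
    "cumulative_rate_series",
    "permanent_exceedance",
    "trials_to_statistical_criterion",
    "fixed_point_exceedance",
    "acquisition_profile",
    "DEFAULT_ODDS",
]

#: odds thresholds reported by default: 4:1, 19:1 (p<.05), 99:1, 999:1
DEFAULT_ODDS = (4.0, 19.0, 99.0, 999.0)


@dataclass
class CumulativeRateSeries:
    """Per-trial cumulative CS and contextual rates with the signed nDKL.

    Entries are NaN while a rate (or the statistic) is not yet computable.
    ``diff`` is the CS-minus-context rate difference used for the
    exceedance criterion.
    """

    cum_cs_rate: np.ndarray
    cum_context_rate: np.ndarray
    signed_ndkl: np.ndarray

    @property
    def diff(self) -> np.ndarray:
        return self.cum_cs_rate - self.cum_context_rate

    def __len__(self) -> int:
        return len(self.cum_cs_rate)


def cumulative_rate_series(
    trials: Sequence[TrialSummary], start: int = 1
) -> CumulativeRateSeries:
    """Cumulative CS and contextual response rates from trial ``start`` on.

    Cumulation begins at 1-based trial ``start``; earlier trials appear as
    NaN so that indices in the output always align with trial numbers.
    The contextual sample pools CS and pre-CS pokes over the combined
    exposure (the CS is part of the context).
    """
    if not trials:
        raise ValueError("need at least one trial")
    n = len(trials)
    cs_rate = np.full(n, np.nan)
    ctx_rate = np.full(n, np.nan)
    sndkl = np.full(n, np.nan)
    cs_n = cs_t = ctx_n = ctx_t = 0.0
    for i, tr in enumerate(trials):
        if tr.trial_index < start:
            continue
        cs_n += tr.n_cs_pokes
        cs_t += tr.cs_duration
        ctx_n += tr.n_cs_pokes + tr.n_pre_pokes
        ctx_t += tr.cs_duration + tr.pre_exposure
        if cs_t > 0:
            cs_rate[i] = cs_n / cs_t
        if ctx_t > 0:
            ctx_rate[i] = ctx_n / ctx_t
        res = ndkl(RatePair(cs_n, cs_rate[i] if cs_t > 0 else 0.0,
                            ctx_n, ctx_rate[i] if ctx_t > 0 else 0.0))
        if res.defined:
            sndkl[i] = res.signed_ndkl
    return CumulativeRateSeries(cs_rate, ctx_rate, sndkl)


def permanent_exceedance(diff_series: Sequence[float]) -> Optional[int]:
    """Smallest 1-based index from which the series stays strictly positive.

    NaN entries (undefined statistic) are skipped: they neither establish
    nor break permanence.  Returns None when the last defined value is not
    positive (no exceedance within the record).  Exact zeros are treated as
    not-greater.
    """
    arr = np.asarray(diff_series, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    t_star = None
    for i, v in enumerate(arr):
        if math.isnan(v):
            continue
        if v > 0:
            if t_star is None:
                t_star = i + 1
        else:
            t_star = None
    return t_star


def trials_to_statistical_criterion(
    trials: Sequence[TrialSummary],
    start: Optional[int],
    threshold: float,
) -> Optional[int]:
    """First trial at which the restarted nDKL permanently exceeds ``threshold``.

    Rates and the nDKL are recomputed using only trials >= ``start`` (the
    permanent-exceedance trial); evidence accumulated before acquisition
    would otherwise dilute the comparison.  Returns None when ``start`` is
    None or the threshold is never permanently exceeded.
    """
    if start is None:
        return None
    if threshold <= 0:
        raise ValueError("threshold must be positive (nats)")
    series = cumulative_rate_series(trials, start=start)
    return permanent_exceedance(series.signed_ndkl - threshold)


def fixed_point_exceedance(trials: Sequence[TrialSummary]) -> Optional[int]:
    """Self-consistent variant of the exceedance criterion.

    Finds the smallest trial t such that the cumulative rate difference,
    when cumulation itself starts at t, is positive at every defined entry
    from t onward.  The default criterion (:func:`permanent_exceedance` on
    the from-trial-1 series) is the primary definition; this optional mode
    restarts the cumulation at the candidate acquisition point itself.
    """
    n = len(trials)
    for t in range(1, n + 1):
        series = cumulative_rate_series(trials, start=t)
        d = series.diff[t - 1:]
        d = d[~np.isnan(d)]
        if d.size and np.all(d > 0):
            return t
    return None


@dataclass
class AcquisitionProfile:
    """Trials-to-acquisition for one subject under each criterion.

    ``t_exceed`` is the permanent-exceedance trial (reinforcements to
    acquisition is ``t_exceed - 1``); ``t_by_threshold`` maps odds against
    the null to the trial satisfying the corresponding nDKL threshold;
    ``t_min_ndkl`` is the trial of the minimum signed nDKL, reported as a
    secondary marker only (it can be a poor localiser).
    """

    subject_id: str
    t_exceed: Optional[int]
    t_by_threshold: dict[float, Optional[int]] = field(default_factory=dict)
    t_min_ndkl: Optional[int] = None

    @property
    def reinforcements_to_acquisition(self) -> Optional[int]:
        return None if self.t_exceed is None else self.t_exceed - 1


def acquisition_profile(
    trials: Sequence[TrialSummary],
    subject_id: str = "",
    odds: Sequence[float] = DEFAULT_ODDS,
) -> AcquisitionProfile:
    """Full per-subject acquisition summary (exceedance + odds thresholds)."""
    series = cumulative_rate_series(trials)
    t_exceed = permanent_exceedance(series.diff)
    by_thresh = {
        q: trials_to_statistical_criterion(trials, t_exceed, odds_to_threshold(q))
        for q in odds
    }
    sn = series.signed_ndkl
    t_min = int(np.nanargmin(sn)) + 1 if np.any(~np.isnan(sn)) else None
    return AcquisitionProfile(subject_id, t_exceed, by_thresh, t_min)
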