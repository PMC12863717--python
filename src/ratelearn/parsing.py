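"""Recursive change-point parsing of inter-poke-interval records.

The parser segments a vector of inter-poke intervals into stretches of
statistically constant rate.  Working on the current (sub)vector, it
scores every candidate truncation point with the nDKL of the two
sub-sequences against the full-sequence rate estimate: the summed extra
coding cost of treating prefix and remainder as draws from the pooled
rate, which equals the exponential likelihood-ratio statistic and keeps
the Gamma(1/2, 1) null of the nDKL framework.  When the maximum of that
profile exceeds a user-supplied criterion ``c`` (in nats; conservative
values of 2-6 are customary, and 6 nats is exceeded by chance roughly
once in 1800 tests), the vector is truncated at the location of the
maximum -- earliest index on ties -- the prefix becomes a segment with
rate (count / summed intervals), and the parser recurses on the
remainder.  Otherwise the whole subvector is one segment.

The first segment's rate estimate extends back to the start of
observation: a long wait before the first poke splits off as its own
(zero-rate-like) segment only when it is implausibly long relative to the
subsequent intervals; otherwise the initial rate covers the opening
stretch of the record as well.

CS interval vectors follow the corrected-rate conventions: the first poke
of each CS is not counted (its latency comes from a different
distribution), its latency and all head-in-magazine time are excluded
from exposure, and CSs with no pokes are omitted entirely.  Pre-CS (ITI)
vectors use raw counts and durations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .events import PokeStream, TrialSummary, pokes_in_window
from .ndkl import dkl_exponential, effective_n

__all__ = [
    "IntervalVector",
    "ParseSegment",
    "ParseSegmentation",
    "build_cs_intervals",
    "build_pre_intervals",
    "parse_intervals",
    "segment_rate_by_trial",
    "parse_based_acquisition",
]


@dataclass
class IntervalVector:
    """Ordered positive inter-poke intervals with their trial origins.

    ``origin_trial[i]`` is the 1-based trial contributing interval ``i``.
    When ``first_is_time_to_event`` the first entry is the wait from the
    start of observation to the first event (pre-CS vectors) rather than a
    between-poke gap (CS vectors, where each CS's first poke is excluded).
    """

    intervals: np.ndarray
    origin_trial: np.ndarray
    first_is_time_to_event: bool = False

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.origin_trial = np.asarray(self.origin_trial, dtype=int)
        if np.any(self.intervals <= 0):
            raise ValueError("all intervals must be positive")
        if self.intervals.shape != self.origin_trial.shape:
            raise ValueError("intervals and origin_trial must align")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class ParseSegment:
    start_index: int  # 0-based, inclusive
    end_index: int  # 0-based, inclusive
    rate: float  # events per second within the segment

    @property
    def n_events(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class ParseSegmentation:
    """Deterministic partition of an interval vector into rate segments."""

    segments: list[ParseSegment]
    criterion_c: float

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def rates(self) -> np.ndarray:
        return np.array([s.rate for s in self.segments])


def build_cs_intervals(
    trials: Sequence[TrialSummary], stream: PokeStream
) -> IntervalVector:
    """CS inter-poke intervals under the corrected-rate conventions.

    Each CS with k >= 2 pokes contributes k-1 head-out gaps (end of one
    poke to start of the next); the first poke and its latency never enter,
    so a CS with a single poke contributes nothing.  Gaps therefore exclude
    first-poke latencies and head-in-magazine time by construction, and the
    countable-event count always equals the interval count.
    """
    gaps, origins = [], []
    for tr in trials:
        pokes = pokes_in_window(stream, tr.cs_onset, tr.cs_onset + tr.cs_duration)
        if len(pokes) < 2:
            # empty CSs are excluded outright; a single poke is the
            # (uncounted) first poke, so it contributes no countable event
            continue
        for (_a0, b0), (a1, _b1) in zip(pokes, pokes[1:]):
            gap = a1 - b0
            if gap <= 0:
                gap = 1e-6  # adjacent beam breaks; keep the interval positive
            gaps.append(gap)
            origins.append(tr.trial_index)
    return IntervalVector(np.array(gaps), np.array(origins, dtype=int),
                          first_is_time_to_event=False)


def build_pre_intervals(
    trials: Sequence[TrialSummary], stream: PokeStream
) -> IntervalVector:
    """Pre-CS inter-poke intervals on the concatenated pre-window timeline.

    Pre-period rates use raw counts over raw exposure (no first-poke
    exclusion), so each poke closes an interval equal to the observation
    time since the previous pre-CS poke, accumulated across successive
    pre-windows.
    """
    gaps, origins = [], []
    since_last = 0.0  # observed pre-window time since the previous pre poke
    for tr in trials:
        w_start = tr.cs_onset - tr.pre_exposure
        pokes = pokes_in_window(stream, w_start, tr.cs_onset)
        cursor = w_start
        for a, _b in pokes:
            interval = since_last + (a - cursor)
            gaps.append(interval if interval > 0 else 1e-6)
            origins.append(tr.trial_index)
            since_last = 0.0
            cursor = a
        since_last += tr.cs_onset - cursor
    return IntervalVector(np.array(gaps), np.array(origins, dtype=int),
                          first_is_time_to_event=True)


def _ndkl_profile(intervals: np.ndarray) -> np.ndarray:
    """Two-part coding-cost profile over candidate split points.

    For a split after ``n_s`` intervals the statistic is the total extra
    cost of encoding the two sub-sequences at the full-sequence rate,

        nDKL(n_s) = n_s * D(rate_prefix || rate_full)
                  + (n - n_s) * D(rate_rest || rate_full) ,

    which is exactly the exponential generalised-likelihood-ratio for a
    one-change model and is distributed Gamma(1/2, 1) under the null of a
    single rate, so the decision criterion c keeps its odds
    interpretation (c = 6 nats is exceeded by chance roughly once in 1800
    tests).  The final entry (no remainder) is -inf.
    """
    n = len(intervals)
    csum = np.cumsum(intervals)
    ns = np.arange(1, n + 1, dtype=float)
    with np.errstate(all="ignore"):
        rate_prefix = ns / csum
        n_rest = n - ns
        rate_rest = n_rest / (csum[-1] - csum)
        rate_full = n / csum[-1]
        d_pre = np.log(rate_prefix / rate_full) + rate_full / rate_prefix - 1.0
        d_rest = np.log(rate_rest / rate_full) + rate_full / rate_rest - 1.0
        prof = ns * d_pre + n_rest * d_rest
    prof[~np.isfinite(prof)] = -np.inf
    return prof


def parse_intervals(vec: IntervalVector | np.ndarray, c: float = 6.0) -> ParseSegmentation:
    """Greedy recursive segmentation at decision criterion ``c`` nats.

    Deterministic: ties at the profile maximum break toward the earliest
    index, and recursion applies to the post-truncation remainder only.
    Vectors of fewer than two intervals form a single segment.
    """
    if c <= 0:
        raise ValueError("criterion c must be positive (nats)")
    intervals = vec.intervals if isinstance(vec, IntervalVector) else np.asarray(vec, float)
    segments: list[ParseSegment] = []
    offset = 0
    rest = intervals
    while len(rest) > 0:
        if len(rest) < 2:
            segments.append(ParseSegment(offset, offset + len(rest) - 1,
                                         len(rest) / float(np.sum(rest))))
            break
        prof = _ndkl_profile(rest)
        k = int(np.argmax(prof))  # earliest max under argmax's first-hit rule
        if prof[k] > c and k < len(rest) - 1:
            n_seg = k + 1
            segments.append(ParseSegment(offset, offset + n_seg - 1,
                                         n_seg / float(np.sum(rest[:n_seg]))))
            offset += n_seg
            rest = rest[n_seg:]
        else:
            segments.append(ParseSegment(offset, offset + len(rest) - 1,
                                         len(rest) / float(np.sum(rest))))
            break
    return ParseSegmentation(segments, c)


def segment_rate_by_trial(
    vec: IntervalVector, seg: ParseSegmentation, n_trials: int
) -> np.ndarray:
    """Express a segmentation as one parsed rate per trial (1..n_trials).

    A trial takes the rate of the segment holding its last interval; trials
    before the first interval inherit the first segment's rate (the initial
    estimate extends back to the start of observation), and trials between
    intervals carry the most recent segment's rate forward.  With no
    intervals at all the parsed rate is zero throughout.
    """
    rates = np.zeros(n_trials)
    if len(vec) == 0 or not seg.segments:
        return rates
    seg_of_interval = np.empty(len(vec), dtype=int)
    for si, s in enumerate(seg.segments):
        seg_of_interval[s.start_index:s.end_index + 1] = si
    current = seg.segments[0].rate  # extends back to start of observation
    idx = 0
    for t in range(1, n_trials + 1):
        while idx < len(vec) and vec.origin_trial[idx] <= t:
            current = seg.segments[seg_of_interval[idx]].rate
            idx += 1
        rates[t - 1] = current
    return rates


def parse_based_acquisition(
    cs_rates_by_trial: np.ndarray,
    iti_rates_by_trial: np.ndarray,
    frac: float = 0.95,
) -> Optional[int]:
    """Acquisition trial from parsed rates.

    Returns the smallest trial t (0 allowed, meaning responding from the
    start) such that over trials > t the parsed CS rate is greater than
    the parsed pre-CS rate on at least ``frac`` of trials; None when no
    such t exists.
    """
    cs = np.asarray(cs_rates_by_trial, float)
    iti = np.asarray(iti_rates_by_trial, float)
    if cs.shape != iti.shape:
        raise ValueError("per-trial rate vectors must align")
    n = len(cs)
    greater = cs > iti
    # suffix counts of CS-dominant trials
    suffix = np.concatenate([np.cumsum(greater[::-1])[::-1], [0]])
    for t in range(0, n):
        remaining = n - t
        if remaining > 0 and suffix[t] >= frac * remaining:
            return t
    return None
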