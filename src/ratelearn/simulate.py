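"""Synthetic cohorts of magazine-approach conditioning with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so that every estimator can be scored against generating values
without any downloaded data:

* protocol timelines: CS durations uniform on [2, 2T-2] s; inter-trial
  intervals uniform, mean C - T, minimum 15 s (mean-centred upper bound);
  pellet at CS offset; daily sessions of 10 (or 3) trials;
* poking as a renewal process: exponential head-out gaps at the current
  rate, poke durations with mean 0.5 s (shifted exponential), and a ~2 s
  floor on the first poke latency after CS onset;
* acquisition: the trial on which conditioned responding begins is drawn
  from the generative response model, geometric with per-trial probability
  p = 1 - exp(-k*(iota - 1)), k = 1/297 by default;
* rates: before acquisition the CS and ITI share a common contextual rate
  beta/(g*C); from the first post-acquisition trial the CS rate steps to
  a substantial fraction of its terminal value beta/T and ramps linearly
  the rest of the way, where beta = 22 is the response scalar and g = 1.9
  the ITI overshadowing factor; subject-level terminal rates carry
  independent log-normal noise with multiplicative spread 2.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .events import (
    PokeStream,
    ProtocolSpec,
    STANDARD_GROUPS,
    TrialSummary,
    summarize_trials,
    write_events_csv,
    write_trials_csv,
)
from .theory import DEFAULT_K

__all__ = [
    "BehaviorParams",
    "GroundTruth",
    "TrialSchedule",
    "SubjectRecord",
    "CohortBundle",
    "generate_protocol",
    "generate_rat",
    "generate_cohort",
]


@dataclass(frozen=True)
class BehaviorParams:
    """Generating parameters for a simulated subject.

    ``response_scalar`` (beta) ties terminal rates to reinforcement rates
    (CS rate beta/T, ITI rate beta/(iti_overshadow_factor * C));
    ``acquisition_k`` is the generative model's probability constant;
    ``initial_response_fraction`` sets the size of the first post-
    acquisition step as a fraction of the terminal-minus-baseline rate
    difference; ``ramp_slope_per_trial`` (rate increment per trial) covers
    the remainder, by default spread over 100 trials; ``noise_factor`` is
    the multiplicative spread of subject-level terminal rates.
    """

    response_scalar: float = 22.0
    iti_overshadow_factor: float = 1.9
    acquisition_k: float = DEFAULT_K
    baseline_rate: Optional[float] = None  # None: beta/(g*C) from the protocol
    initial_response_fraction: float = 0.5
    ramp_slope_per_trial: Optional[float] = None  # None: (terminal-initial)/100
    ramp_trials: int = 100
    poke_duration_mean: float = 0.5
    poke_duration_floor: float = 0.05
    first_poke_latency_floor: float = 2.0
    noise_factor: float = 2.5

    def __post_init__(self):
        if self.response_scalar <= 0 or self.poke_duration_mean <= 0:
            raise ValueError("rates and durations must be positive")
        if not 0 <= self.initial_response_fraction <= 1:
            raise ValueError("initial_response_fraction must lie in [0, 1]")

    @property
    def sigma_log10(self) -> float:
        """Log10 standard deviation of the subject-level rate noise."""
        return math.log10(self.noise_factor)


@dataclass(frozen=True)
class TrialSchedule:
    """Realised timeline for one subject: (cs_onset, cs_duration) pairs."""

    protocol: ProtocolSpec
    trials: list[tuple[float, float]]
    session_boundaries: list[float]


@dataclass
class GroundTruth:
    """Generating values against which every estimator can be scored."""

    protocol: ProtocolSpec
    acquisition_trial: Optional[int]  # reinforcements before responding; None = never
    true_cs_rate_by_trial: np.ndarray
    true_iti_rate_by_trial: np.ndarray
    terminal_cs_rate: float
    terminal_iti_rate: float
    baseline_rate: float


@dataclass
class SubjectRecord:
    subject_id: str
    protocol: ProtocolSpec
    schedule: TrialSchedule
    stream: PokeStream
    trials: list[TrialSummary]
    truth: GroundTruth


@dataclass
class CohortBundle:
    subjects: list[SubjectRecord] = field(default_factory=list)

    def by_group(self) -> dict[str, list[SubjectRecord]]:
        out: dict[str, list[SubjectRecord]] = {}
        for s in self.subjects:
            out.setdefault(s.protocol.group_id, []).append(s)
        return out

    def write_csvs(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in self.subjects:
            write_events_csv(s.stream, out / f"{s.subject_id}_events.csv")
            write_trials_csv(s.trials, s.subject_id, out / f"{s.subject_id}_trials.csv")


def generate_protocol(spec: ProtocolSpec, rng: np.random.Generator) -> TrialSchedule:
    """Draw a full trial timeline for one subject under ``spec``.

    CS durations are uniform on [T_min, T_max]; ITIs uniform on
    [iti_min, 2*(C - T) - iti_min] so their mean is C - T.  Sessions are
    laid end to end on one time axis.
    """
    iti_mean = spec.iti_mean
    iti_hi = 2.0 * iti_mean - spec.iti_min
    if iti_hi < spec.iti_min:
        raise ValueError("infeasible protocol: C - T below the minimum ITI")
    trials: list[tuple[float, float]] = []
    boundaries = []
    t = 0.0
    for _ in range(spec.n_sessions):
        boundaries.append(t)
        for _ in range(spec.trials_per_session):
            iti = rng.uniform(spec.iti_min, iti_hi) if iti_hi > spec.iti_min else iti_mean
            dur = rng.uniform(spec.T_min, spec.T_max) if spec.T_max > spec.T_min else spec.T_min
            onset = t + iti
            trials.append((onset, dur))
            t = onset + dur
    return TrialSchedule(spec, trials, boundaries)


def _window_pokes(rng, rate, window_start, window_end, params, start_at,
                  first_wait_floor=0.0):
    """Renewal-process pokes in [window_start, window_end).

    Head-out gaps are exponential at ``rate``; poke durations are a small
    floor plus an exponential keeping the stated mean.  Generation resumes
    at ``start_at`` (>= window_start) so a poke spanning the previous
    boundary cannot overlap a new one.  Returns (pokes, end_of_last_poke).
    """
    pokes = []
    t = max(window_start, start_at)
    if rate <= 0 or t >= window_end:
        return pokes, start_at
    dur_scale = params.poke_duration_mean - params.poke_duration_floor
    first = True
    while True:
        n = max(8, int((window_end - t) * rate * 1.5) + 4)
        gaps = rng.exponential(1.0 / rate, n)
        durs = params.poke_duration_floor + rng.exponential(dur_scale, n)
        done = False
        for g, d in zip(gaps, durs):
            wait = g + (first_wait_floor if first else 0.0)
            first = False
            entry = t + wait
            if entry >= window_end:
                done = True
                break
            pokes.append((entry, entry + d))
            t = entry + d
        if done:
            break
    last_exit = pokes[-1][1] if pokes else start_at
    return pokes, last_exit


def generate_rat(
    schedule: TrialSchedule,
    behavior: BehaviorParams,
    rng: np.random.Generator,
    subject_id: str = "sim",
) -> tuple[PokeStream, GroundTruth]:
    """Simulate one subject's poke stream over a realised timeline."""
    spec = schedule.protocol
    n_trials = len(schedule.trials)
    f_cs = 10.0 ** rng.normal(0.0, behavior.sigma_log10)
    f_iti = 10.0 ** rng.normal(0.0, behavior.sigma_log10)
    terminal_cs = behavior.response_scalar / spec.T_mean * f_cs
    terminal_iti = (
        behavior.response_scalar / (behavior.iti_overshadow_factor * spec.C) * f_iti
    )
    baseline = behavior.baseline_rate if behavior.baseline_rate is not None else terminal_iti

    p = 1.0 - math.exp(-behavior.acquisition_k * (spec.iota - 1.0))
    acq = int(rng.geometric(p)) if p > 0 else None
    if acq is not None and acq >= n_trials:
        acq_recorded = None  # responding never starts within the record
    else:
        acq_recorded = acq

    r1 = baseline + behavior.initial_response_fraction * (terminal_cs - baseline)
    slope = (
        behavior.ramp_slope_per_trial
        if behavior.ramp_slope_per_trial is not None
        else (terminal_cs - r1) / behavior.ramp_trials
    )
    cs_rates = np.full(n_trials, baseline)
    if acq is not None:
        for i in range(acq, n_trials):  # responding starts on trial acq + 1
            ramped = r1 + slope * (i - acq)
            cs_rates[i] = min(max(ramped, min(r1, terminal_cs)), max(r1, terminal_cs))
    iti_rates = np.full(n_trials, baseline)

    events: list[tuple[float, float]] = []
    cursor = 0.0
    prev_end = 0.0
    for i, (onset, dur) in enumerate(schedule.trials):
        iti_pokes, cursor = _window_pokes(
            rng, iti_rates[i], prev_end, onset, behavior, cursor
        )
        cs_pokes, cursor = _window_pokes(
            rng, cs_rates[i], onset, onset + dur, behavior, cursor,
            first_wait_floor=behavior.first_poke_latency_floor,
        )
        events.extend(iti_pokes)
        events.extend(cs_pokes)
        prev_end = onset + dur
    stream = PokeStream(subject_id, events, list(schedule.session_boundaries))
    truth = GroundTruth(
        protocol=spec,
        acquisition_trial=acq_recorded,
        true_cs_rate_by_trial=cs_rates,
        true_iti_rate_by_trial=iti_rates,
        terminal_cs_rate=terminal_cs,
        terminal_iti_rate=terminal_iti,
        baseline_rate=baseline,
    )
    return stream, truth


def generate_cohort(
    groups: Sequence[ProtocolSpec] = STANDARD_GROUPS,
    n_per_group: int = 12,
    behavior: BehaviorParams = BehaviorParams(),
    seed: int = 0,
) -> CohortBundle:
    """Independent subjects per group, each with a derived child seed.

    The same master seed always reproduces the identical cohort.
    """
    bundle = CohortBundle()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(groups) * n_per_group)
    k = 0
    for spec in groups:
        for j in range(n_per_group):
            rng = np.random.default_rng(children[k])
            k += 1
            sched = generate_protocol(spec, rng)
            sid = f"g{spec.group_id}_r{j + 1}"
            stream, truth = generate_rat(sched, behavior, rng, subject_id=sid)
            trials = summarize_trials(stream, spec, sched.trials)
            bundle.subjects.append(
                SubjectRecord(sid, spec, sched, stream, trials, truth)
            )
    return bundle
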