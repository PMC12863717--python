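"""Domain types and tabular I/O for magazine-entry event streams.

A conditioning protocol presents a light CS inside the food magazine and
delivers a pellet at CS offset.  The raw behavioural record for a subject
is a stream of photo-beam interruptions: (entry, exit) time pairs marking
when the head was in the magazine.  Analysis consumes two views of the
record: the raw :class:`PokeStream` and per-trial :class:`TrialSummary`
rows giving counts and exposures during the CS and during a fixed
observation window immediately before CS onset (the pre-CS window).

Conventions
-----------
* Times are seconds on a single axis starting at the beginning of training
  (session start times are carried in ``session_boundaries``); stored to
  millisecond precision; trials are numbered from 1.
* A poke that spans a context boundary belongs to the context in which it
  begins, so counts stay additive across contexts.
* Reinforcement coincides with CS termination; no separate consumption
  event is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "ProtocolSpec",
    "PokeStream",
    "TrialSummary",
    "STANDARD_GROUPS",
    "summarize_trials",
    "pokes_in_window",
    "read_events_csv",
    "write_events_csv",
    "read_trials_csv",
    "write_trials_csv",
    "read_event_table",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """A group's conditioning protocol.

    ``T_mean`` is the mean CS-US interval (CS duration, since the pellet
    arrives at CS offset); ``C`` the mean US-US interval.  CS durations are
    drawn uniformly on [T_min, T_max]; the default bounds [2, 2*T_mean - 2]
    keep the mean at ``T_mean`` with a 2 s floor.  Inter-trial intervals are
    uniform with minimum ``iti_min`` and mean ``C - T_mean``.  The
    informativeness of the protocol is C/T.
    """

    group_id: str
    T_mean: float
    C: float
    trials_per_session: int
    n_sessions: int
    T_min: float = 2.0
    T_max: Optional[float] = None
    iti_min: float = 15.0
    pre_cs_window: float = 10.0

    def __post_init__(self):
        if self.T_max is None:
            object.__setattr__(self, "T_max", 2.0 * self.T_mean - self.T_min)
        if self.T_min < 0 or self.T_mean < self.T_min:
            raise ValueError("require 0 <= T_min <= T_mean")
        if self.C <= self.T_mean:
            raise ValueError("C must exceed T (informativeness > 1)")
        if self.trials_per_session < 1 or self.n_sessions < 1:
            raise ValueError("trial and session counts must be positive")

    @property
    def iota(self) -> float:
        """Informativeness C/T."""
        return self.C / self.T_mean

    @property
    def iti_mean(self) -> float:
        return self.C - self.T_mean

    @property
    def n_trials(self) -> int:
        return self.trials_per_session * self.n_sessions


#: The 14 protocols of the rat experiment: (T, C) in seconds, with 10
#: trials/session for groups 1-11 and 3 trials/session for groups 12-14,
#: 42 daily sessions, informativeness C/T from 1.5 to 300.
STANDARD_GROUPS: tuple[ProtocolSpec, ...] = tuple(
    ProtocolSpec(group_id=str(i + 1), T_mean=T, C=C,
                 trials_per_session=(10 if i < 11 else 3), n_sessions=42)
    for i, (T, C) in enumerate([
        (42, 63), (48, 144), (21, 94.5), (12, 72), (6, 54), (62, 930),
        (30, 600), (18, 486), (36, 1296), (26, 1404), (8, 576),
        (16, 1760), (10, 1800), (14, 4200),
    ])
)


@dataclass
class PokeStream:
    """Ordered, non-overlapping magazine entry/exit events for one subject."""

    subject_id: str
    events: list[tuple[float, float]]
    session_boundaries: list[float] = field(default_factory=lambda: [0.0])

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        prev_exit = float("-inf")
        for i, (a, b) in enumerate(self.events):
            if b < a:
                raise ValueError(f"event {i}: exit {b} precedes entry {a}")
            if a < prev_exit:
                raise ValueError(f"event {i}: overlaps previous poke")
            prev_exit = b

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class TrialSummary:
    """Counts and exposures for one trial (CS period and pre-CS window)."""

    trial_index: int  # 1-based
    cs_onset: float
    cs_duration: float
    n_cs_pokes: int
    cs_first_poke_latency: Optional[float]
    cs_in_magazine_time: float
    n_pre_pokes: int
    pre_exposure: float
    pre_in_magazine_time: float
    session: int = 1

    def __post_init__(self):
        if (self.cs_first_poke_latency is None) != (self.n_cs_pokes == 0):
            raise ValueError("first-poke latency must be absent iff no CS pokes")
        if self.cs_in_magazine_time > self.cs_duration + 1e-9:
            raise ValueError("in-magazine time exceeds CS duration")


def pokes_in_window(stream: PokeStream, start: float, end: float) -> list[tuple[float, float]]:
    """Pokes assigned to [start, end): those whose entry falls inside it."""
    return [(a, b) for a, b in stream.events if start <= a < end]


def _window_stats(stream, start, end):
    pokes = pokes_in_window(stream, start, end)
    n = len(pokes)
    latency = pokes[0][0] - start if pokes else None
    in_mag = sum(min(b, end) - a for a, b in pokes)
    return n, latency, in_mag


def summarize_trials(
    stream: PokeStream,
    protocol: ProtocolSpec,
    trial_schedule: Sequence[tuple[float, float]],
) -> list[TrialSummary]:
    """Reduce a poke stream to per-trial CS / pre-CS counts and exposures.

    ``trial_schedule`` holds (cs_onset, cs_duration) pairs in trial order.
    The pre-CS window is the ``protocol.pre_cs_window`` seconds ending at CS
    onset, truncated at the start of the trial's session if the CS comes on
    sooner than that.
    """
    out = []
    bounds = sorted(stream.session_boundaries)
    prev_end = None
    for i, (onset, dur) in enumerate(trial_schedule, start=1):
        if prev_end is not None and onset < prev_end:
            raise ValueError(f"trial {i} overlaps trial {i - 1}")
        prev_end = onset + dur
        session_start = max((b for b in bounds if b <= onset), default=0.0)
        session = 1 + sum(1 for b in bounds if 0.0 < b <= onset)
        pre_start = max(onset - protocol.pre_cs_window, session_start)
        if onset < 0:
            raise ValueError(f"trial {i} lies outside the recorded time span")
        n_cs, latency, cs_mag = _window_stats(stream, onset, onset + dur)
        n_pre, _, pre_mag = _window_stats(stream, pre_start, onset)
        out.append(
            TrialSummary(
                trial_index=i,
                cs_onset=onset,
                cs_duration=dur,
                n_cs_pokes=n_cs,
                cs_first_poke_latency=latency,
                cs_in_magazine_time=min(cs_mag, dur),
                n_pre_pokes=n_pre,
                pre_exposure=onset - pre_start,
                pre_in_magazine_time=pre_mag,
                session=session,
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV I/O.  Events CSV: subject_id, session, poke_start_s, poke_end_s.
# Trials CSV: subject_id, session, trial, cs_onset_s, cs_duration_s,
# reinforced.  Times are written to millisecond precision.
# ---------------------------------------------------------------------------

def _session_of(t: float, boundaries: Sequence[float]) -> int:
    return 1 + sum(1 for b in sorted(boundaries) if 0.0 < b <= t)


def write_events_csv(stream: PokeStream, path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": stream.subject_id,
            "session": [_session_of(a, stream.session_boundaries) for a, _ in stream.events],
            "poke_start_s": [round(a, 3) for a, _ in stream.events],
            "poke_end_s": [round(b, 3) for _, b in stream.events],
        }
    )
    df.to_csv(path, index=False)


def read_events_csv(path, subject_id: Optional[str] = None) -> PokeStream:
    """Read one subject's events; raises on malformed or overlapping rows."""
    df = pd.read_csv(path)
    required = {"subject_id", "session", "poke_start_s", "poke_end_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"events CSV must have columns {sorted(required)}")
    if subject_id is not None:
        df = df[df["subject_id"].astype(str) == str(subject_id)]
    subjects = df["subject_id"].astype(str).unique()
    if len(subjects) != 1:
        raise ValueError(f"expected one subject, found {list(subjects)}")
    bad = df[df[["poke_start_s", "poke_end_s"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"malformed event row at line {bad.index[0] + 2}")
    events = list(zip(df["poke_start_s"].astype(float), df["poke_end_s"].astype(float)))
    events.sort(key=lambda e: e[0])
    # session boundaries: first event time of each session is a lower bound;
    # streams written by this package carry them implicitly via trials.
    return PokeStream(subject_id=str(subjects[0]), events=events)


def write_trials_csv(trials: Sequence[TrialSummary], subject_id: str, path,
                     reinforced: Optional[Sequence[int]] = None) -> None:
    if reinforced is None:
        reinforced = [1] * len(trials)
    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "session": [t.session for t in trials],
            "trial": [t.trial_index for t in trials],
            "cs_onset_s": [round(t.cs_onset, 3) for t in trials],
            "cs_duration_s": [round(t.cs_duration, 3) for t in trials],
            "reinforced": list(reinforced),
        }
    )
    df.to_csv(path, index=False)


def read_trials_csv(path, subject_id: Optional[str] = None) -> list[tuple[float, float]]:
    """Read a trial schedule: ordered (cs_onset, cs_duration) pairs."""
    df = pd.read_csv(path)
    required = {"subject_id", "session", "trial", "cs_onset_s", "cs_duration_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"trials CSV must have columns {sorted(required)}")
    if subject_id is not None:
        df = df[df["subject_id"].astype(str) == str(subject_id)]
    df = df.sort_values("trial")
    return list(zip(df["cs_onset_s"].astype(float), df["cs_duration_s"].astype(float)))


def read_event_table(events_path, trials_path, protocol: ProtocolSpec,
                     subject_id: Optional[str] = None):
    """Read events + trial schedule and reconstruct per-trial summaries.

    Returns ``(stream, trials)`` with pre-CS windows of
    ``protocol.pre_cs_window`` seconds ending at each CS onset.
    """
    stream = read_events_csv(events_path, subject_id=subject_id)
    schedule = read_trials_csv(trials_path, subject_id=stream.subject_id)
    # infer session boundaries from the schedule: a session starts at 0 and
    # whenever the trial counter wraps in the CSV's session column
    df = pd.read_csv(trials_path)
    if subject_id is not None:
        df = df[df["subject_id"].astype(str) == str(subject_id)]
    df = df.sort_values("trial")
    boundaries = [0.0]
    prev_session = None
    prev_end = 0.0
    for _, row in df.iterrows():
        s = int(row["session"])
        if prev_session is not None and s != prev_session:
            boundaries.append(prev_end)  # session starts no earlier than the last CS of the previous one ended
        prev_session = s
        prev_end = float(row["cs_onset_s"]) + float(row["cs_duration_s"])
    stream = replace(stream, session_boundaries=sorted(set(b for b in boundaries if b >= 0.0)) or [0.0])
    trials = summarize_trials(stream, protocol, schedule)
    return stream, trials
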