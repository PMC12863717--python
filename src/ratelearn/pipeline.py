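"""End-to-end orchestration: simulate -> summarize -> acquisition ->
parse -> terminal rates -> deciles -> theory fits, with CSV/JSON artifacts
and a reproducible run manifest.

Each stage is also usable on its own; the pipeline simply threads a
simulated (or loaded) cohort through the per-subject estimators and the
group-level fits, writing the tables that mirror the analysis outputs:
acquisition trials per criterion, parsed rate segments, corrected
terminal rates, trials-to-decile records with the growth-model
comparison, and the learning-rate regression over group medians.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .acquisition import AcquisitionProfile, acquisition_profile
from .events import ProtocolSpec, STANDARD_GROUPS
from .growth import GrowthDecileRecord, GrowthCurveModel, find_peak, trials_to_deciles
from .parsing import (
    build_cs_intervals,
    build_pre_intervals,
    parse_based_acquisition,
    parse_intervals,
    segment_rate_by_trial,
)
from .rates import ScalarRateModel, corrected_rate, terminal_rates
from .simulate import BehaviorParams, CohortBundle, SubjectRecord, generate_cohort
from .theory import LearningRateModel

__all__ = [
    "RunConfig",
    "run_pipeline",
    "subject_parse",
    "subject_growth_record",
    "acquisition_table",
    "parse_table",
    "terminal_table",
    "learning_rate_table",
]


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run."""

    out_dir: str = "ratelearn_run"
    seed: int = 0
    n_per_group: int = 12
    groups: Optional[list[str]] = None  # group ids from the standard table
    odds_criteria: tuple[float, ...] = (4.0, 19.0, 99.0, 999.0)
    parse_criterion_nats: float = 6.0
    final_window_sessions: int = 5
    behavior: BehaviorParams = field(default_factory=BehaviorParams)

    def __post_init__(self):
        if any(q <= 0 for q in self.odds_criteria):
            raise ValueError("odds criteria must be positive")
        if self.final_window_sessions not in (5, 10):
            raise ValueError("final analysis window must be 5 or 10 sessions")

    def selected_groups(self) -> list[ProtocolSpec]:
        if self.groups is None:
            return list(STANDARD_GROUPS)
        by_id = {g.group_id: g for g in STANDARD_GROUPS}
        return [by_id[g] for g in self.groups]

    def config_hash(self) -> str:
        payload = json.dumps(
            {**{k: v for k, v in asdict(self).items() if k != "behavior"},
             "behavior": asdict(self.behavior)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        behavior = BehaviorParams(**raw.pop("behavior", {}))
        if "odds_criteria" in raw:
            raw["odds_criteria"] = tuple(raw["odds_criteria"])
        return cls(behavior=behavior, **raw)


def subject_parse(sub: SubjectRecord, c: float = 6.0):
    """Parse one subject's CS and pre-CS interval vectors.

    Returns (cs_segmentation, pre_segmentation, cs_rate_by_trial,
    pre_rate_by_trial, parse_acquisition_trial).
    """
    n = len(sub.trials)
    cs_vec = build_cs_intervals(sub.trials, sub.stream)
    pre_vec = build_pre_intervals(sub.trials, sub.stream)
    cs_seg = parse_intervals(cs_vec, c)
    pre_seg = parse_intervals(pre_vec, c)
    cs_rates = segment_rate_by_trial(cs_vec, cs_seg, n)
    pre_rates = segment_rate_by_trial(pre_vec, pre_seg, n)
    t_parse = parse_based_acquisition(cs_rates, pre_rates)
    return cs_seg, pre_seg, cs_rates, pre_rates, t_parse


def _session_corrected_rates(trials) -> tuple[np.ndarray, list[int]]:
    """Corrected CS response rate per session (first-poke and head-in
    exclusions); sessions with no countable pokes get rate 0."""
    sessions = sorted({t.session for t in trials})
    rates = []
    for s in sessions:
        block = [t for t in trials if t.session == s and t.n_cs_pokes > 0]
        if not block:
            rates.append(0.0)
            continue
        num = sum(t.n_cs_pokes - 1 for t in block)
        den = sum(t.cs_duration - t.cs_first_poke_latency - t.cs_in_magazine_time
                  for t in block)
        rates.append(num / den if den > 0 else 0.0)
    return np.asarray(rates), sessions


def subject_growth_record(
    sub: SubjectRecord, t1: Optional[int], window: int = 3
) -> Optional[GrowthDecileRecord]:
    """Trials-to-decile record for one subject.

    ``t1`` is the trial on which CS responding became reliably greater
    than pre-CS responding (the odds-4:1 criterion by default upstream);
    R1 is the corrected CS rate over the session containing t1, Rmax the
    peak of the 3-session moving average of corrected session rates, and
    the cumulative record uses countable pokes over corrected exposure.
    Returns None when t1 is undefined or too little of the record remains.
    """
    if t1 is None:
        return None
    rates, sessions = _session_corrected_rates(sub.trials)
    if len(rates) < window:
        return None
    end_session, rmax = find_peak(rates, window)
    t1_session = next(t.session for t in sub.trials if t.trial_index == t1)
    r1 = rates[sessions.index(t1_session)]
    t_end = max(t.trial_index for t in sub.trials if t.session == sessions[end_session - 1])
    seg = [t for t in sub.trials if t1 <= t.trial_index <= t_end]
    if len(seg) < 9:
        return None
    cum_n, cum_t = [], []
    n_acc = t_acc = 0.0
    for t in seg:
        if t.n_cs_pokes > 0:
            n_acc += t.n_cs_pokes - 1
            t_acc += t.cs_duration - t.cs_first_poke_latency - t.cs_in_magazine_time
        else:
            t_acc += t.cs_duration  # head out for the whole empty CS
        cum_n.append(n_acc)
        cum_t.append(t_acc)
    deciles = trials_to_deciles(cum_n, cum_t, r1, rmax)
    return GrowthDecileRecord(sub.subject_id, t1, t_end, r1, rmax,
                              trials_at_decile=deciles + t1 - 1)


def acquisition_table(bundle: CohortBundle, odds: Sequence[float]) -> pd.DataFrame:
    rows = []
    for sub in bundle.subjects:
        prof = acquisition_profile(sub.trials, sub.subject_id, odds)
        row = {
            "subject_id": sub.subject_id,
            "group_id": sub.protocol.group_id,
            "iota": sub.protocol.iota,
            "t_exceed": prof.t_exceed,
            "t_min_ndkl": prof.t_min_ndkl,
            "true_acquisition_trial": sub.truth.acquisition_trial,
        }
        names = {4.0: "t_odds4", 19.0: "t_p05", 99.0: "t_p01", 999.0: "t_p001"}
        for q, t in prof.t_by_threshold.items():
            row[names.get(q, f"t_odds{q:g}")] = t
        rows.append(row)
    return pd.DataFrame(rows)


def parse_table(bundle: CohortBundle, c: float) -> pd.DataFrame:
    rows = []
    for sub in bundle.subjects:
        n = len(sub.trials)
        for context, vec in {
            "CS": build_cs_intervals(sub.trials, sub.stream),
            "ITI": build_pre_intervals(sub.trials, sub.stream),
        }.items():
            seg = parse_intervals(vec, c)
            for s in seg.segments:
                start_tr = int(vec.origin_trial[s.start_index]) if len(vec) else 1
                end_tr = int(vec.origin_trial[s.end_index]) if len(vec) else n
                rows.append({
                    "subject_id": sub.subject_id,
                    "context": context,
                    "segment_start_trial": 1 if s.start_index == 0 else start_tr,
                    "segment_end_trial": end_tr,
                    "rate_per_s": s.rate,
                })
    return pd.DataFrame(rows)


def terminal_table(bundle: CohortBundle, final_sessions: int) -> pd.DataFrame:
    rows = []
    for sub in bundle.subjects:
        try:
            tr = terminal_rates(sub.trials, sub.subject_id, sub.protocol.T_mean,
                                sub.protocol.C, final_sessions)
        except ValueError:
            continue  # no CS responding in the final window
        rows.append({
            "subject_id": tr.subject_id,
            "group_id": sub.protocol.group_id,
            "cs_rate": tr.cs_rate,
            "iti_rate": tr.iti_rate,
            "cs_reinf_rate": tr.cs_reinf_rate,
            "context_reinf_rate": tr.context_reinf_rate,
            "T": sub.protocol.T_mean,
            "C": sub.protocol.C,
        })
    return pd.DataFrame(rows)


def learning_rate_table(acq: pd.DataFrame, criterion: str = "t_exceed",
                        min_iota: float = 1.0) -> pd.DataFrame:
    """Group medians of reinforcements-to-acquisition for the regression.

    Estimates are ``criterion`` trial minus 1 (reinforcements before
    responding), floored at the analytic lower limit of one reinforcement;
    subjects with no acquisition under the criterion are excluded.
    """
    df = acq.dropna(subset=[criterion]).copy()
    df["r_to_acq"] = np.maximum(df[criterion].astype(float) - 1.0, 1.0)
    med = df.groupby(["group_id", "iota"])["r_to_acq"].median().reset_index()
    med = med.rename(columns={"r_to_acq": "median"})
    return med[med["iota"] > min_iota].sort_values("iota").reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the artifact bundle to ``config.out_dir``.

    Returns a manifest dict (also written as manifest.json) recording the
    seed, configuration hash, stage outputs and any stage failures.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "failures": {},
    }

    bundle = generate_cohort(config.selected_groups(), config.n_per_group,
                             config.behavior, config.seed)
    bundle.write_csvs(out / "cohort")
    manifest["stages"]["simulate"] = {"n_subjects": len(bundle.subjects)}

    acq = acquisition_table(bundle, config.odds_criteria)
    acq.to_csv(out / "acquisition.csv", index=False)
    manifest["stages"]["acquisition"] = {"rows": len(acq)}

    try:
        parses = parse_table(bundle, config.parse_criterion_nats)
        parses.to_csv(out / "parse.csv", index=False)
        manifest["stages"]["parse"] = {"rows": len(parses)}
    except Exception as exc:  # pragma: no cover - defensive
        manifest["failures"]["parse"] = repr(exc)

    term = terminal_table(bundle, config.final_window_sessions)
    term.to_csv(out / "terminal_rates.csv", index=False)
    manifest["stages"]["terminal_rates"] = {"rows": len(term)}

    scalar_fits = {}
    if len(term) >= 2:
        model = ScalarRateModel.from_dataframe(term)
        scalar_fits = {k: _fit_json(v) for k, v in model.fit().items()}
        (out / "scalar_fits.json").write_text(json.dumps(scalar_fits, indent=2))
        manifest["stages"]["rates"] = {"variants": list(scalar_fits)}

    # growth deciles, using the odds-4:1 acquisition trial as segment start
    odds4_col = "t_odds4"
    records = []
    for sub in bundle.subjects:
        row = acq[acq.subject_id == sub.subject_id].iloc[0]
        t1 = row[odds4_col]
        rec = subject_growth_record(sub, int(t1) if pd.notna(t1) else None)
        if rec is not None and rec.included:
            records.append(rec)
    dec_rows = [
        {"subject_id": r.subject_id, "d": round(d, 1), "trial": int(t)}
        for r in records for d, t in zip(np.arange(0.1, 0.95, 0.1), r.trials_at_decile)
    ]
    pd.DataFrame(dec_rows).to_csv(out / "deciles.csv", index=False)
    growth_report = {}
    if records:
        results = GrowthCurveModel(records).fit()
        growth_report = {
            "sum_bic": results.sum_bic(),
            "winner_counts": results.winner_counts(),
        }
        (out / "growth_models.json").write_text(json.dumps(growth_report, indent=2))
    manifest["stages"]["deciles"] = {"n_records": len(records)}

    theory_report = {}
    med = learning_rate_table(acq)
    if len(med) >= 3:
        fit = LearningRateModel(med["median"], med["iota"]).fit()
        theory_report = {
            "slope": fit.slope,
            "slope_ci": list(fit.slope_ci),
            "x_intercept_k": fit.k,
            "one_trial_iota": fit.one_trial_iota,
            "r_squared": fit.r_squared,
            "n_groups": fit.n_groups,
        }
        (out / "learning_rate_fit.json").write_text(json.dumps(theory_report, indent=2))
    manifest["stages"]["theory"] = {"n_groups": len(med)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "manifest": manifest,
        "acquisition": acq,
        "terminal": term,
        "scalar_fits": scalar_fits,
        "growth": growth_report,
        "theory": theory_report,
    }


def _fit_json(fit) -> dict:
    return {
        "variant": fit.variant,
        "slope": fit.slope,
        "intercept_log10": fit.intercept_log10,
        "scalar": fit.scalar,
        "r_squared": fit.r_squared,
        "bic": fit.bic,
        "shift_log10": fit.shift_log10,
        "shift_factor": fit.shift_factor,
        "n": fit.n,
    }
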