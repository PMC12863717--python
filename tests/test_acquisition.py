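"""Cumulative rate series, permanent exceedance, and the restart rule."""

import math

import numpy as np
import pytest

from ratelearn.acquisition import (
    acquisition_profile,
    cumulative_rate_series,
    fixed_point_exceedance,
    permanent_exceedance,
    trials_to_statistical_criterion,
)
from ratelearn.ndkl import RatePair, ndkl, odds_to_threshold

from conftest import make_trial


def test_worked_example_rates():
    """5 CS pokes in 20 s cumulative CS against 1000 s of observed context."""
    trials = [
        make_trial(1, 3, cs_dur=12.0, pre_exp=490.0),
        make_trial(2, 2, cs_dur=8.0, pre_exp=490.0),
    ]
    s = cumulative_rate_series(trials)
    assert s.cum_cs_rate[-1] == pytest.approx(0.25)
    assert s.cum_context_rate[-1] == pytest.approx(0.005)
    assert s.cum_cs_rate[-1] / s.cum_context_rate[-1] == pytest.approx(50.0)
    assert s.signed_ndkl[-1] == pytest.approx(2.5 * 2.932, abs=2e-3)


def test_series_matches_brute_force_oracle(rng):
    """Cross-check every entry against independent cumulative sums."""
    trials = []
    for i in range(1, 41):
        n_cs = int(rng.poisson(0.5 if i < 20 else 4.0))
        trials.append(make_trial(i, n_cs, cs_dur=float(rng.uniform(5, 25)),
                                 n_pre=int(rng.poisson(0.5)), latency=1.0))
    s = cumulative_rate_series(trials)
    cs_n = cs_t = ctx_n = ctx_t = 0.0
    for i, t in enumerate(trials):
        cs_n += t.n_cs_pokes
        cs_t += t.cs_duration
        ctx_n += t.n_cs_pokes + t.n_pre_pokes
        ctx_t += t.cs_duration + t.pre_exposure
        assert s.cum_cs_rate[i] == pytest.approx(cs_n / cs_t)
        assert s.cum_context_rate[i] == pytest.approx(ctx_n / ctx_t)
        expected = ndkl(RatePair(cs_n, cs_n / cs_t, ctx_n, ctx_n / ctx_t))
        if expected.defined:
            assert s.signed_ndkl[i] == pytest.approx(expected.signed_ndkl)


def test_equal_rates_hover_near_zero():
    trials = [make_trial(i, 1, cs_dur=10.0, n_pre=1) for i in range(1, 31)]
    s = cumulative_rate_series(trials)
    # identical CS and pre rates: the signed statistic stays at 0 exactly
    assert np.nanmax(np.abs(s.signed_ndkl)) < 1e-12
    assert permanent_exceedance(s.diff) is None


@pytest.mark.parametrize(
    "series, expected",
    [
        ([0.1, 0.2, 0.3], 1),
        ([-1, 0.5, -0.2, 0.3, 0.4], 4),
        ([-1, -2, 0.0], None),
        ([0.0, 0.1, 0.1], 2),  # an exact tie is not `greater'
        ([math.nan, -1, math.nan, 2.0], 4),
    ],
)
def test_permanent_exceedance(series, expected):
    assert permanent_exceedance(series) == expected


def test_permanent_exceedance_backward_scan_oracle(rng):
    for _ in range(200):
        s = rng.normal(0, 1, size=rng.integers(1, 40))
        got = permanent_exceedance(s)
        # oracle: scan backwards until a non-positive value
        exp = None
        for i in range(len(s) - 1, -1, -1):
            if s[i] > 0:
                exp = i + 1
            else:
                break
        assert got == exp


def test_permanent_exceedance_empty_errors():
    with pytest.raises(ValueError):
        permanent_exceedance([])


def _step_trials(n=60, step=10, lo=0, hi=5):
    """CS responding jumps from `lo` to `hi` pokes per 10 s CS at `step`."""
    return [
        make_trial(i, lo if i < step else hi, cs_dur=10.0, n_pre=0,
                   latency=1.0 if (lo if i < step else hi) else None)
        for i in range(1, n + 1)
    ]


def test_restart_criterion_matches_prefix_oracle():
    trials = _step_trials()
    start = permanent_exceedance(cumulative_rate_series(trials).diff)
    thr = odds_to_threshold(4)
    got = trials_to_statistical_criterion(trials, start, thr)
    # oracle: recompute restarted cumulative sums over every prefix
    sub = [t for t in trials if t.trial_index >= start]
    cs_n = cs_t = ctx_n = ctx_t = 0.0
    vals = {}
    for t in sub:
        cs_n += t.n_cs_pokes
        cs_t += t.cs_duration
        ctx_n += t.n_cs_pokes + t.n_pre_pokes
        ctx_t += t.cs_duration + t.pre_exposure
        r = ndkl(RatePair(cs_n, cs_n / cs_t, ctx_n, ctx_n / ctx_t))
        vals[t.trial_index] = r.signed_ndkl if r.defined else math.nan
    expected = None
    for idx in sorted(vals, reverse=True):
        v = vals[idx]
        if math.isnan(v):
            continue
        if v > thr:
            expected = idx
        else:
            break
    assert got == expected is not None


def test_strong_signal_meets_criterion_quickly():
    trials = _step_trials(n=30, step=1, lo=0, hi=8)
    prof = acquisition_profile(trials, "r", odds=(4.0, 19.0))
    assert prof.t_exceed == 1
    assert prof.t_by_threshold[4.0] is not None
    assert prof.t_by_threshold[4.0] <= 5
    # more stringent odds can never be met earlier
    assert prof.t_by_threshold[19.0] >= prof.t_by_threshold[4.0]


def test_infinite_threshold_never_met():
    trials = _step_trials()
    start = permanent_exceedance(cumulative_rate_series(trials).diff)
    assert trials_to_statistical_criterion(trials, start, math.inf) is None
    assert trials_to_statistical_criterion(trials, None, 1.0) is None


def test_restart_no_later_than_from_trial_one():
    """Dropping pre-acquisition trials never delays the criterion."""
    trials = _step_trials(n=80, step=40, lo=1, hi=6)
    start = permanent_exceedance(cumulative_rate_series(trials).diff)
    thr = odds_to_threshold(19)
    restarted = trials_to_statistical_criterion(trials, start, thr)
    from_one = permanent_exceedance(cumulative_rate_series(trials).signed_ndkl - thr)
    if restarted is not None and from_one is not None:
        assert restarted <= from_one


def test_fixed_point_variant_on_step_data():
    trials = _step_trials(n=40, step=15, lo=0, hi=5)
    t_fp = fixed_point_exceedance(trials)
    assert t_fp is not None
    assert t_fp <= 15 + 1


def test_profile_reports_reinforcements():
    trials = _step_trials(n=30, step=5, lo=0, hi=6)
    prof = acquisition_profile(trials, "r", odds=(4.0,))
    assert prof.reinforcements_to_acquisition == prof.t_exceed - 1
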