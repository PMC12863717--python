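"""Corrected rates and the scalar rate-law regressions."""

import math

import numpy as np
import pandas as pd
import pytest

from ratelearn.rates import (
    ScalarRateModel,
    TerminalRates,
    bic_from_rss,
    corrected_rate,
    fit_scalar_regression,
    fit_shifted_shared_model,
    group_correlates,
    terminal_rates,
)

from conftest import make_trial


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        # 10 pokes over 3 CSs (3 first pokes excluded), 60 s, 6 s latency, 3.5 s head-in
        (dict(count=10, exposure=60.0, excluded_count=3, excluded_time=6.0,
              in_magazine_time=3.5), 7 / 50.5),
        # 0 ITI pokes over 2100 s under the half-count convention
        (dict(count=0, exposure=2100.0, zero_count_convention=True), 0.5 / 2100),
        # no exclusions: the naive estimator
        (dict(count=12, exposure=48.0), 0.25),
    ],
)
def test_corrected_rate_values(kwargs, expected):
    assert corrected_rate(**kwargs) == pytest.approx(expected, rel=1e-9)


def test_corrected_rate_guards():
    with pytest.raises(ValueError):
        corrected_rate(count=1, exposure=5.0, in_magazine_time=5.0)
    with pytest.raises(ValueError):
        corrected_rate(count=1, exposure=5.0, excluded_count=2)


def test_corrected_exceeds_conventional_when_time_removed():
    naive = corrected_rate(count=20, exposure=100.0)
    corr = corrected_rate(count=20, exposure=100.0, in_magazine_time=10.0)
    assert corr > naive


def test_terminal_rates_window_selection():
    trials = []
    k = 0
    for session in range(1, 8):
        for j in range(3):
            k += 1
            n = 0 if session <= 2 else 4
            trials.append(make_trial(k, n, cs_dur=10.0, latency=1.0,
                                     in_mag=0.5 * n, n_pre=0, session=session))
    tr = terminal_rates(trials, "r", T=10.0, C=90.0, final_sessions=5)
    # 15 trials in sessions 3-7, 4 pokes each: (4-1)*15 / (10-1-2)*15
    assert tr.cs_rate == pytest.approx((3 * 15) / (7.0 * 15))
    assert tr.iti_rate == pytest.approx(0.5 / (15 * 10.0))  # half-count convention
    assert tr.cs_reinf_rate == pytest.approx(0.1)
    assert tr.context_reinf_rate == pytest.approx(1 / 90)


def test_slope1_fit_exact_law():
    """y = 21.8 x exactly: intercept log10(21.8), R^2 = 1."""
    x = np.linspace(-3, -1, 12)
    pts = [(xi, xi + math.log10(21.8)) for xi in x]
    fit = fit_scalar_regression(pts, "single-slope1")
    assert fit.intercept_log10 == pytest.approx(math.log10(21.8), abs=1e-12)
    assert fit.intercept_log10 == pytest.approx(1.338, abs=5e-4)
    assert fit.r_squared == pytest.approx(1.0)


def test_identity_law_free_fit():
    pts = [(x, x) for x in np.linspace(-2, 0, 8)]
    fit = fit_scalar_regression(pts, "single-free")
    assert fit.slope == pytest.approx(1.0, abs=1e-9)
    assert fit.intercept_log10 == pytest.approx(0.0, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0)


def test_free_fit_degenerate_x_errors():
    with pytest.raises(ValueError):
        fit_scalar_regression([(0.0, 1.0), (0.0, 2.0)], "single-free")


def test_slope1_intercept_is_least_squares(rng):
    """The analytic slope-1 intercept beats any gridded alternative."""
    x = rng.uniform(-3, -1, 30)
    y = x + math.log10(22) + rng.normal(0, 0.4, 30)
    fit = fit_scalar_regression(list(zip(x, y)), "single-slope1")
    rss_best = np.sum((y - x - fit.intercept_log10) ** 2)
    for a in np.linspace(fit.intercept_log10 - 0.5, fit.intercept_log10 + 0.5, 101):
        assert rss_best <= np.sum((y - x - a) ** 2) + 1e-12


def test_shifted_model_recovers_shift_noiseless():
    x_cs = np.linspace(-2, -1, 10)
    x_iti = np.linspace(-3.5, -2.5, 10)
    beta = 22.0
    cs = [(x, x + math.log10(beta)) for x in x_cs]
    iti = [(x, x + math.log10(beta) - math.log10(1.9)) for x in x_iti]
    fit = fit_shifted_shared_model(cs, iti)
    assert fit.shift_log10 == pytest.approx(math.log10(1.9), abs=1e-12)
    assert fit.shift_log10 == pytest.approx(0.28, abs=0.005)
    assert fit.shift_factor == pytest.approx(1.9, rel=1e-9)
    assert fit.scalar == pytest.approx(beta, rel=1e-9)


def test_identical_laws_zero_shift():
    pts = [(x, x + 1.0) for x in np.linspace(-2, -1, 5)]
    fit = fit_shifted_shared_model(pts, pts)
    assert fit.shift_log10 == pytest.approx(0.0, abs=1e-12)


def test_shift_recovery_across_seeds():
    """Noisy cohorts recover the generating shift within a tolerance band."""
    true_shift = math.log10(1.9)
    for seed in range(10):
        r = np.random.default_rng(seed)
        x_cs = r.uniform(-2, -0.8, 80)
        x_iti = r.uniform(-3.6, -1.8, 80)
        cs = [(x, x + math.log10(22) + r.normal(0, 0.39)) for x in x_cs]
        iti = [(x, x + math.log10(22) - true_shift + r.normal(0, 0.39)) for x in x_iti]
        fit = fit_shifted_shared_model(cs, iti)
        assert fit.shift_log10 == pytest.approx(true_shift, abs=0.2)


def test_free_slope_concentrates_with_n(rng):
    """Free-slope estimates tighten around 1 as the cohort grows."""
    err = {}
    for n in (20, 2000):
        x = rng.uniform(-3, -1, n)
        y = x + math.log10(22) + rng.normal(0, 0.39, n)
        err[n] = abs(fit_scalar_regression(list(zip(x, y)), "single-free").slope - 1)
    assert err[2000] < 0.05


def test_bic_formula():
    assert bic_from_rss(0.9, 9, 2) == pytest.approx(9 * math.log(0.1) + 2 * math.log(9))


def test_model_object_round_trip():
    rows = [
        TerminalRates(f"r{i}", cs_rate=22 / T, iti_rate=22 / (1.9 * C),
                      cs_reinf_rate=1 / T, context_reinf_rate=1 / C)
        for i, (T, C) in enumerate([(6, 54), (12, 72), (30, 600), (14, 4200)])
    ]
    fits = ScalarRateModel(rows).fit()
    assert fits["shifted-shared"].shift_log10 == pytest.approx(math.log10(1.9), abs=1e-9)
    assert fits["shifted-shared"].scalar == pytest.approx(22.0, rel=1e-9)
    # pooling the offset CS and ITI lines tilts a pooled free fit above 1
    assert 1.0 <= fits["single-free"].slope <= 1.3
    assert "slope" in fits["shifted-shared"].summary()


def test_group_correlates_collinear_and_partials():
    df = pd.DataFrame({
        "median": [100, 50, 10, 5, 2],
        "T": [40, 30, 20, 12, 8],
        "C": [60, 90, 180, 216, 480],
    })
    # make the median exactly collinear with log(C/T)
    df["median"] = 10 ** (2.0 - 1.0 * np.log10(df["C"] / df["T"]))
    out = group_correlates(df)
    r_ct = out[(out.predictor == "log(C/T)") & out.partial_controlling.isna()]["r"].iloc[0]
    assert r_ct == pytest.approx(-1.0, abs=1e-9)


def test_group_correlates_partials_match_residual_oracle(rng):
    n = 12
    T = rng.uniform(5, 60, n)
    C = T * rng.uniform(1.5, 100, n)
    med = 10 ** (1.5 - 0.8 * np.log10(C / T) + rng.normal(0, 0.1, n))
    df = pd.DataFrame({"median": med, "T": T, "C": C})
    out = group_correlates(df)
    got = out[(out.predictor == "log(C/T)") & (out.partial_controlling == "log(C)")][
        "r_partial"].iloc[0]
    # independent oracle: pingouin's partial correlation
    pg = pytest.importorskip("pingouin")
    pdf = pd.DataFrame({
        "y": np.log10(med), "a": np.log10(C / T), "ctrl": np.log10(C),
    })
    expected = pg.partial_corr(pdf, x="a", y="y", covar="ctrl")["r"].iloc[0]
    assert got == pytest.approx(expected, abs=1e-9)


def test_group_correlates_guards():
    df = pd.DataFrame({"median": [1, 2], "T": [1, 2], "C": [3, 4]})
    with pytest.raises(ValueError):
        group_correlates(df)
    const = pd.DataFrame({"median": [1, 2, 3], "T": [5, 5, 5], "C": [10, 20, 30]})
    out = group_correlates(const)
    r_t = out[(out.predictor == "log(T)") & out.partial_controlling.isna()]["r"].iloc[0]
    assert math.isnan(r_t)
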