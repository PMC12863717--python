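"""Corrected response-rate estimation and scalar rate-law regressions.

Terminal behaviour is summarised by corrected response rates over the
final training sessions.  The correction removes time during which a poke
could not be initiated: for CS rates, the first poke of each CS and its
latency are excluded (first-poke latencies come from a different
distribution than inter-poke intervals) along with head-in-magazine time;
for pre-CS (ITI) rates only head-in time matters in principle, and a
subject with zero pre-CS pokes is assigned a count of 0.5 -- an unbiased
stand-in for a true count between 0 and 1 that keeps the log rate
defined.

The scalar rate law states that response rate is directly proportional to
reinforcement rate: on double-log (base-10) axes a line of slope 1.  The
regression variants mirror the model ladder used to test it:

* ``single-free``   -- one line, free slope and intercept (2 parameters);
* ``single-slope1`` -- one line, slope fixed at 1 (1 parameter);
* ``separate-slope1`` -- separate slope-1 lines for CS and ITI points
  (2 parameters);
* ``shifted-shared`` -- one slope-1 scaling shared by CS and ITI, with the
  ITI reinforcement rate uniformly shifted down by a fitted factor
  (2 parameters: the scalar and the shift).

Model scores use BIC = n*ln(RSS/n) + p*ln(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TerminalRates",
    "ScalarFit",
    "corrected_rate",
    "terminal_rates",
    "ScalarRateModel",
    "fit_scalar_regression",
    "fit_shifted_shared_model",
    "group_correlates",
    "bic_from_rss",
]


def bic_from_rss(rss: float, n: int, p: int) -> float:
    """BIC = n*ln(RSS/n) + p*ln(n); shared by every model ladder here.

    A perfect fit (RSS = 0) scores -inf, which preserves the ordering.
    """
    if rss <= 0:
        return -math.inf
    return n * math.log(rss / n) + p * math.log(n)


def corrected_rate(
    count: float,
    exposure: float,
    *,
    excluded_count: float = 0.0,
    excluded_time: float = 0.0,
    in_magazine_time: float = 0.0,
    zero_count_convention: bool = False,
) -> float:
    """Response rate with curtailed time removed from the denominator.

    rate = (count - excluded_count) / (exposure - excluded_time -
    in_magazine_time).  ``excluded_count``/``excluded_time`` carry the
    first-poke exclusions (CS rates only); ``in_magazine_time`` is the
    cumulative head-in duration.  With ``zero_count_convention``, a zero
    adjusted count becomes 0.5 so the log rate stays defined.
    """
    num = count - excluded_count
    denom = exposure - excluded_time - in_magazine_time
    if denom <= 0:
        raise ValueError("adjusted exposure must be positive")
    if num < 0:
        raise ValueError("excluded count exceeds count")
    if num == 0 and zero_count_convention:
        num = 0.5
    return num / denom


@dataclass(frozen=True)
class TerminalRates:
    """Corrected terminal rates and protocol reinforcement rates for one rat."""

    subject_id: str
    cs_rate: float
    iti_rate: float
    cs_reinf_rate: float  # 1/T
    context_reinf_rate: float  # 1/C


def terminal_rates(
    trials,
    subject_id: str,
    T: float,
    C: float,
    final_sessions: int = 5,
) -> TerminalRates:
    """Corrected CS and pre-CS rates over the last ``final_sessions`` sessions.

    CS rates exclude each CS's first poke, its latency, and head-in time,
    and skip CSs with no pokes; pre-CS rates are raw counts over raw
    exposure with the 0.5-count convention when no poke was recorded.
    """
    last = max(t.session for t in trials)
    window = [t for t in trials if t.session > last - final_sessions]
    cs_n = cs_t = cs_lat = cs_mag = 0.0
    pre_n = pre_t = 0.0
    for t in window:
        if t.n_cs_pokes > 0:
            cs_n += t.n_cs_pokes
            cs_t += t.cs_duration
            cs_lat += t.cs_first_poke_latency
            cs_mag += t.cs_in_magazine_time
        pre_n += t.n_pre_pokes
        pre_t += t.pre_exposure
    n_active = sum(1 for t in window if t.n_cs_pokes > 0)
    if n_active == 0:
        raise ValueError(f"subject {subject_id}: no CS pokes in the final window")
    cs_rate = corrected_rate(
        cs_n, cs_t, excluded_count=n_active, excluded_time=cs_lat,
        in_magazine_time=cs_mag,
    )
    iti_rate = corrected_rate(pre_n, pre_t, zero_count_convention=True)
    return TerminalRates(subject_id, cs_rate, iti_rate, 1.0 / T, 1.0 / C)


@dataclass
class ScalarFit:
    """Result of one scalar rate-law regression (log10 domain)."""

    variant: str
    slope: float
    intercept_log10: float
    r_squared: float
    bic: float
    n: int
    shift_log10: Optional[float] = None  # shifted-shared only
    slope_ci: Optional[tuple[float, float]] = None
    extra: dict = field(default_factory=dict)

    @property
    def scalar(self) -> float:
        """The proportionality constant in the non-log domain."""
        return 10.0 ** self.intercept_log10

    @property
    def shift_factor(self) -> Optional[float]:
        return None if self.shift_log10 is None else 10.0 ** self.shift_log10

    def summary(self) -> str:
        lines = [
            f"Scalar rate-law fit ({self.variant}), n={self.n}",
            f"  slope           {self.slope:8.4f}"
            + (f"  CI95 [{self.slope_ci[0]:.4f}, {self.slope_ci[1]:.4f}]" if self.slope_ci else ""),
            f"  intercept log10 {self.intercept_log10:8.4f}  (scalar {self.scalar:.3g})",
            f"  R^2             {self.r_squared:8.4f}",
            f"  BIC             {self.bic:8.2f}",
        ]
        if self.shift_log10 is not None:
            lines.append(
                f"  ITI shift       {self.shift_log10:8.4f} log10 units"
                f"  (factor {self.shift_factor:.3g})"
            )
        return "\n".join(lines)


def _r2_rss(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)
    return r2, rss


def fit_scalar_regression(
    points: Sequence[tuple[float, float]], variant: str = "single-free"
) -> ScalarFit:
    """Least-squares fit of log10 response rate on log10 reinforcement rate.

    ``points`` are (log10 reinforcement rate, log10 response rate) pairs.
    ``single-free`` fits slope and intercept by OLS; ``single-slope1``
    fixes the slope at 1, leaving the intercept (the log scalar) as the
    single free parameter.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2 or not np.all(np.isfinite(pts)):
        raise ValueError("need >= 2 finite (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    n = len(x)
    if variant == "single-free":
        if np.ptp(x) == 0:
            raise ValueError("degenerate x-spread for a free-slope fit")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        inter, slope = res.params
        ci = res.conf_int()[1]
        yhat = inter + slope * x
        r2, rss = _r2_rss(y, yhat)
        return ScalarFit("single-free", float(slope), float(inter), r2,
                         bic_from_rss(rss, n, 2), n, slope_ci=(float(ci[0]), float(ci[1])))
    if variant == "single-slope1":
        inter = float(np.mean(y - x))  # LS solution with slope fixed at 1
        yhat = inter + x
        r2, rss = _r2_rss(y, yhat)
        return ScalarFit("single-slope1", 1.0, inter, r2, bic_from_rss(rss, n, 1), n)
    raise ValueError(f"unknown variant {variant!r}")


def fit_shifted_shared_model(
    cs_points: Sequence[tuple[float, float]],
    iti_points: Sequence[tuple[float, float]],
    variant: str = "shifted-shared",
) -> ScalarFit:
    """Two-sample slope-1 models over CS and ITI point sets.

    ``shifted-shared``: one scaling shared by both sets, with the ITI
    reinforcement rates uniformly shifted down by a fitted amount ``s``
    (log10 units): y_cs = a + x, y_iti = a + (x - s).  The least-squares
    solution is a = mean(y_cs - x_cs), s = a - mean(y_iti - x_iti); the
    shift is reported both in log units and as the factor 10**s.

    ``separate-slope1``: independent slope-1 intercepts for the two sets
    (reported intercept is the CS one; the ITI intercept is in ``extra``).
    """
    cs = np.asarray(cs_points, dtype=float)
    iti = np.asarray(iti_points, dtype=float)
    if len(cs) == 0 or len(iti) == 0:
        raise ValueError("both point sets must be non-empty")
    a_cs = float(np.mean(cs[:, 1] - cs[:, 0]))
    a_iti = float(np.mean(iti[:, 1] - iti[:, 0]))
    y = np.concatenate([cs[:, 1], iti[:, 1]])
    n = len(y)
    if variant == "shifted-shared":
        shift = a_cs - a_iti
        yhat = np.concatenate([a_cs + cs[:, 0], a_cs + iti[:, 0] - shift])
        r2, rss = _r2_rss(y, yhat)
        return ScalarFit("shifted-shared", 1.0, a_cs, r2, bic_from_rss(rss, n, 2),
                         n, shift_log10=shift)
    if variant == "separate-slope1":
        yhat = np.concatenate([a_cs + cs[:, 0], a_iti + iti[:, 0]])
        r2, rss = _r2_rss(y, yhat)
        return ScalarFit("separate-slope1", 1.0, a_cs, r2, bic_from_rss(rss, n, 2),
                         n, extra={"intercept_iti_log10": a_iti})
    raise ValueError(f"unknown variant {variant!r}")


class ScalarRateModel:
    """Model object for the scalar rate law over a terminal-rates table.

    Built from :class:`TerminalRates` rows (or a DataFrame with columns
    ``cs_rate``, ``iti_rate``, ``cs_reinf_rate``, ``context_reinf_rate``);
    ``fit`` evaluates the model ladder and returns the per-variant
    :class:`ScalarFit` results keyed by variant name.
    """

    def __init__(self, rows: Sequence[TerminalRates]):
        if not rows:
            raise ValueError("no terminal-rate rows")
        self.rows = list(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ScalarRateModel":
        rows = [
            TerminalRates(str(r.get("subject_id", i)), r["cs_rate"], r["iti_rate"],
                          r["cs_reinf_rate"], r["context_reinf_rate"])
            for i, r in df.iterrows()
        ]
        return cls(rows)

    @property
    def cs_points(self) -> list[tuple[float, float]]:
        return [(math.log10(r.cs_reinf_rate), math.log10(r.cs_rate))
                for r in self.rows if r.cs_rate > 0]

    @property
    def iti_points(self) -> list[tuple[float, float]]:
        return [(math.log10(r.context_reinf_rate), math.log10(r.iti_rate))
                for r in self.rows if r.iti_rate > 0]

    def fit(self) -> dict[str, ScalarFit]:
        pooled = self.cs_points + self.iti_points
        return {
            "single-free": fit_scalar_regression(pooled, "single-free"),
            "single-slope1": fit_scalar_regression(pooled, "single-slope1"),
            "separate-slope1": fit_shifted_shared_model(self.cs_points, self.iti_points,
                                                        "separate-slope1"),
            "shifted-shared": fit_shifted_shared_model(self.cs_points, self.iti_points),
        }


def group_correlates(group_stats: pd.DataFrame) -> pd.DataFrame:
    """Correlations of log medians with log(C/T), log C and log T.

    ``group_stats`` needs columns ``median`` (trials to criterion), ``C``
    and ``T``, one row per group.  Returns a table of product-moment
    correlations plus partial correlations of log(C/T) controlling log C
    and vice versa (residual-based formula).  Columns with no variance
    yield NaN rather than an error.
    """
    if len(group_stats) < 3:
        raise ValueError("need >= 3 groups")
    y = np.log10(group_stats["median"].to_numpy(float))
    preds = {
        "log(C/T)": np.log10(group_stats["C"].to_numpy(float) / group_stats["T"].to_numpy(float)),
        "log(C)": np.log10(group_stats["C"].to_numpy(float)),
        "log(T)": np.log10(group_stats["T"].to_numpy(float)),
    }

    def _corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return math.nan
        return float(np.corrcoef(a, b)[0, 1])

    def _partial(a, b, control):
        # residualise both a-side and y against the control, then correlate
        def resid(v):
            X = sm.add_constant(control)
            return v - X @ np.linalg.lstsq(X, v, rcond=None)[0]
        return _corr(resid(a), resid(b))

    rows = [
        {"predictor": name, "r": _corr(v, y), "partial_controlling": None, "r_partial": math.nan}
        for name, v in preds.items()
    ]
    rows.append({"predictor": "log(C/T)", "r": _corr(preds["log(C/T)"], y),
                 "partial_controlling": "log(C)",
                 "r_partial": _partial(preds["log(C/T)"], y, preds["log(C)"])})
    rows.append({"predictor": "log(C)", "r": _corr(preds["log(C)"], y),
                 "partial_controlling": "log(C/T)",
                 "r_partial": _partial(preds["log(C)"], y, preds["log(C/T)"])})
    return pd.DataFrame(rows)
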