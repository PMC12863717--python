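"""Post-acquisition growth of responding: deciles of the cumulative record
and growth-curve model comparison.

The trajectory from the onset of conditioned responding to peak
responding is summarised by the trials needed for the slope of the
cumulative response record to climb through each decile of the total rate
change.  Let R1 be the corrected CS response rate at the start of the
post-acquisition segment and Rmax the peak rate (maximum of a 3-session
centred moving average); dR = Rmax - R1.  For each decile q = 0.1..0.9 a
reference cumulative record with constant slope R1 + q*dR is laid over
the observed record,

    cumR'_t = (R1 + q*dR) * cumT_t ,

and the trial maximising cumR'_t - cumR_t marks when the observed slope
first sustainedly exceeded that reference rate.

Four growth forms compete to describe trials-to-decile t_c as a function
of decile d, scored with BIC = n*ln(RSS/n) + p*ln(n) at n = 9 points:

* line          t_c = m*d + c                       (p = 2)
* exponential   t_c = c * exp(m*d)                  (p = 2)
* inverse cumulative Gaussian
                t_c = s*sqrt(2)*erfinv(2*(m*d + 0.5) - 1) + c   (p = 3)
* log           t_c = -ln(1 - d)/k + c              (p = 2)

A BIC difference above 4.6 (odds 10:1) counts as strong evidence.
Nonlinear forms are fitted from a deterministic grid of starts; a form
whose fit fails to converge (or whose erfinv argument leaves (-1, 1)) is
flagged rather than silently clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erfinv

from .rates import bic_from_rss

__all__ = [
    "DECILES",
    "GrowthDecileRecord",
    "GrowthModelFit",
    "GrowthCurveModel",
    "find_peak",
    "trials_to_deciles",
    "fit_growth_models",
    "MIN_DELTA_R",
    "STRONG_DELTA_BIC",
]

DECILES = np.arange(0.1, 0.95, 0.1)
#: records with a total rate change below this (responses/s) are excluded
MIN_DELTA_R = 0.1
#: BIC difference corresponding to odds of 10:1
STRONG_DELTA_BIC = 4.6


@dataclass
class GrowthDecileRecord:
    """Trials to each decile of the rate change for one subject."""

    subject_id: str
    t1: int
    t_end: int
    R1: float
    Rmax: float
    trials_at_decile: np.ndarray  # 9 values, d = 0.1 .. 0.9

    @property
    def delta_R(self) -> float:
        return self.Rmax - self.R1

    @property
    def included(self) -> bool:
        return self.delta_R >= MIN_DELTA_R


def find_peak(
    session_rates: Sequence[float], window: int = 3
) -> tuple[int, float]:
    """Peak response rate from a centred moving average of session rates.

    Returns ``(end_session, Rmax)`` where ``Rmax`` is the maximum of the
    ``window``-wide moving average and ``end_session`` the 1-based last
    session of the earliest maximising window (ties break early).
    """
    rates = np.asarray(session_rates, dtype=float)
    if len(rates) < window:
        raise ValueError(f"need at least {window} sessions")
    kernel = np.ones(window) / window
    ma = np.convolve(rates, kernel, mode="valid")
    i = int(np.argmax(ma))  # argmax returns the first maximum
    return i + window, float(ma[i])


def trials_to_deciles(
    cum_counts: Sequence[float],
    cum_exposure: Sequence[float],
    R1: float,
    Rmax: float,
    deciles: np.ndarray = DECILES,
) -> np.ndarray:
    """Trial index (1-based) at which each decile of dR = Rmax - R1 is reached.

    For each decile q the reference record (R1 + q*dR)*cumT is compared to
    the observed cumulative count; the argmax of the difference marks the
    last trial before the observed slope permanently outruns the reference.
    """
    cumR = np.asarray(cum_counts, dtype=float)
    cumT = np.asarray(cum_exposure, dtype=float)
    if cumR.shape != cumT.shape:
        raise ValueError("cumulative count and exposure must align")
    dR = Rmax - R1
    out = np.empty(len(deciles), dtype=int)
    for j, q in enumerate(deciles):
        ref = (R1 + q * dR) * cumT
        out[j] = int(np.argmax(ref - cumR)) + 1
    return out


@dataclass
class GrowthModelFit:
    """One growth form's least-squares fit to the 9 decile points."""

    form: str
    params: dict[str, float]
    rss: float
    bic: float
    n_params: int
    converged: bool = True

    def predict(self, d: np.ndarray) -> np.ndarray:
        return _FORMS[self.form](np.asarray(d, float), self.params)


def _f_line(d, p):
    return p["m"] * d + p["c"]


def _f_exp(d, p):
    return p["c"] * np.exp(p["m"] * d)


def _f_invgauss(d, p):
    arg = 2.0 * (p["m"] * d + 0.5) - 1.0
    return p["s"] * math.sqrt(2.0) * erfinv(arg) + p["c"]


def _f_log(d, p):
    return -np.log(1.0 - d) / p["k"] + p["c"]


_FORMS = {"line": _f_line, "exponential": _f_exp,
          "inverse-cumulative-gaussian": _f_invgauss, "log": _f_log}


def _fit_linear_in_basis(t, X, names) -> tuple[dict, float]:
    beta, *_ = np.linalg.lstsq(X, t, rcond=None)
    rss = float(np.sum((t - X @ beta) ** 2))
    return dict(zip(names, beta)), rss


def _fit_line(d, t):
    params, rss = _fit_linear_in_basis(t, np.column_stack([d, np.ones_like(d)]), ["m", "c"])
    return GrowthModelFit("line", params, rss, bic_from_rss(rss, len(d), 2), 2)


def _fit_log(d, t):
    # linear in (1/k, c) for the regressor -ln(1-d)
    x = -np.log(1.0 - d)
    params, rss = _fit_linear_in_basis(t, np.column_stack([x, np.ones_like(x)]), ["inv_k", "c"])
    if params["inv_k"] == 0:
        return GrowthModelFit("log", {"k": math.inf, "c": params["c"]}, rss,
                              bic_from_rss(rss, len(d), 2), 2, converged=False)
    out = {"k": 1.0 / params["inv_k"], "c": params["c"]}
    return GrowthModelFit("log", out, rss, bic_from_rss(rss, len(d), 2), 2)


def _nls(d, t, form, starts, names, bounds=None):
    """Deterministic multi-start nonlinear least squares for one form."""
    f = _FORMS[form]
    best = None
    for x0 in starts:
        def resid(v):
            p = dict(zip(names, v))
            with np.errstate(all="ignore"):
                pred = f(d, p)
            pred = np.where(np.isfinite(pred), pred, 1e12)
            return pred - t
        try:
            sol = least_squares(resid, x0, bounds=bounds or (-np.inf, np.inf),
                                max_nfev=2000)
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, dict(zip(names, sol.x)), bool(sol.success))
    return best


def _fit_exponential(d, t):
    n = len(d)
    starts = []
    if np.all(t > 0):
        # log-linear start: ln t = ln c + m*d
        b, *_ = np.linalg.lstsq(np.column_stack([d, np.ones_like(d)]), np.log(t), rcond=None)
        starts.append(np.array([math.exp(b[1]), b[0]]))
    starts += [np.array([c0, m0]) for m0 in (0.5, 2.0, 5.0) for c0 in (1.0, 10.0, 50.0)]
    best = _nls(d, t, "exponential", starts, ["c", "m"])
    if best is None:
        return GrowthModelFit("exponential", {}, math.inf, math.inf, 2, converged=False)
    rss, params, ok = best
    return GrowthModelFit("exponential", params, rss, bic_from_rss(max(rss, 1e-300), n, 2), 2, ok)


def _fit_invgauss(d, t):
    n = len(d)
    span = max(float(np.ptp(t)), 1.0)
    starts = [np.array([s0, m0, c0])
              for s0 in (span / 4.0, span)
              for m0 in (0.3, 0.6, 0.9)
              for c0 in (float(np.mean(t)),)]
    # m must keep m*d + 0.5 inside (0, 1) for d in [0.1, 0.9]
    best = _nls(d, t, "inverse-cumulative-gaussian", starts, ["s", "m", "c"],
                bounds=([1e-9, 1e-6, -np.inf], [np.inf, 0.5 / float(np.max(d)) - 1e-6, np.inf]))
    if best is None:
        return GrowthModelFit("inverse-cumulative-gaussian", {}, math.inf, math.inf, 3,
                              converged=False)
    rss, params, ok = best
    return GrowthModelFit("inverse-cumulative-gaussian", params, rss,
                          bic_from_rss(max(rss, 1e-300), n, 3), 3, ok)


def fit_growth_models(
    record: GrowthDecileRecord | Sequence[float],
    deciles: np.ndarray = DECILES,
) -> tuple[dict[str, GrowthModelFit], str]:
    """Fit the four growth forms to a subject's trials-to-decile points.

    Accepts a :class:`GrowthDecileRecord` or a bare 9-vector of trial
    indices.  Returns the per-form fits and the name of the BIC-best form;
    non-converged forms keep infinite BIC and never win.
    """
    t = np.asarray(
        record.trials_at_decile if isinstance(record, GrowthDecileRecord) else record,
        dtype=float,
    )
    d = np.asarray(deciles, dtype=float)
    if t.shape != d.shape:
        raise ValueError("decile points must align with the decile grid")
    fits = {
        "line": _fit_line(d, t),
        "exponential": _fit_exponential(d, t),
        "inverse-cumulative-gaussian": _fit_invgauss(d, t),
        "log": _fit_log(d, t),
    }
    best = min(fits, key=lambda k: fits[k].bic)
    return fits, best


@dataclass
class GrowthCurveModel:
    """Model object: decile extraction plus model comparison for a cohort.

    ``records`` holds one :class:`GrowthDecileRecord` per subject; ``fit``
    runs the four-form comparison on every included record and returns a
    results object with per-subject winners and the BIC totals.
    """

    records: list[GrowthDecileRecord]

    def fit(self) -> "GrowthCurveResults":
        per_subject = {}
        for rec in self.records:
            if not rec.included:
                continue
            fits, best = fit_growth_models(rec)
            per_subject[rec.subject_id] = (fits, best)
        return GrowthCurveResults(per_subject)


@dataclass
class GrowthCurveResults:
    per_subject: dict[str, tuple[dict[str, GrowthModelFit], str]]
    forms: tuple[str, ...] = tuple(_FORMS)

    def sum_bic(self) -> dict[str, float]:
        out = {}
        for form in self.forms:
            vals = [fits[form].bic for fits, _ in self.per_subject.values()
                    if math.isfinite(fits[form].bic)]
            out[form] = float(sum(vals)) if vals else math.inf
        return out

    def winner_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(self.forms, 0)
        for _, best in self.per_subject.values():
            counts[best] += 1
        return counts

    def summary(self) -> str:
        sb = self.sum_bic()
        wc = self.winner_counts()
        n = len(self.per_subject)
        lines = [f"Growth-curve comparison over {n} subjects (BIC, lower is better)"]
        for form in sorted(self.forms, key=lambda f: sb[f]):
            lines.append(f"  {form:28s} sum BIC {sb[form]:10.1f}   best for {wc[form]}/{n}")
        return "\n".join(lines)
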