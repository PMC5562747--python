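"""Pharmacology readouts built on beat metrics.

Percent change from baseline, saturating (Hill) dose-response fits,
beta-blockade inhibition fractions, recovery fractions, and a rule-based
classification of beat-rate time courses.  The dose-response model is

    response(c) = Rmax * c**n / (c**n + EC50**n)

which passes through the origin (a zero dose produces zero percent change),
matching a chronotropic response that saturates at high agonist dose.  The
Hill coefficient is free; fitting uses multistart nonlinear least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ArgumentError

__all__ = [
    "DoseResponse",
    "HillFit",
    "TimecourseThresholds",
    "percent_change",
    "hill_response",
    "fit_dose_response",
    "blockade_analysis",
    "fraction_recovered",
    "classify_timecourse",
]


@dataclass
class DoseResponse:
    """Mean percent beat-rate change per (ascending) dose."""

    doses_uM: np.ndarray
    responses_pct: np.ndarray
    replicates: list[list[float]] | None = None

    def __post_init__(self) -> None:
        self.doses_uM = np.asarray(self.doses_uM, dtype=float)
        self.responses_pct = np.asarray(self.responses_pct, dtype=float)
        if self.doses_uM.size != self.responses_pct.size:
            raise ArgumentError("doses and responses must have equal length")
        if np.any(self.doses_uM < 0):
            raise ArgumentError("doses must be non-negative")
        if np.any(np.diff(self.doses_uM) <= 0):
            raise ArgumentError("doses must be strictly ascending")


@dataclass
class HillFit:
    """Fitted saturating dose-response parameters."""

    Rmax_pct: float
    EC50_uM: float
    hill_n: float
    rss: float
    unidentifiable: bool = False


@dataclass
class TimecourseThresholds:
    """Classification bands for beat-rate time courses.

    ``stable_band`` (percent) separates noise-level fluctuation from real
    change; the default 15% places a mild (~10%) antagonist-alone effect
    inside the stable band.  ``ceased_pct`` is the percent change treated as
    complete beat cessation.
    """

    stable_band: float = 15.0
    ceased_pct: float = -99.9


def percent_change(baseline_bpm: float, treated_bpm: float) -> float:
    """Percent change of a treated beat rate relative to baseline."""
    if baseline_bpm <= 0:
        raise ArgumentError(
            "baseline BPM must be positive for a percent change "
            "(a zero baseline is cessation, not a definable change)"
        )
    return 100.0 * (treated_bpm - baseline_bpm) / baseline_bpm


def hill_response(c: np.ndarray, rmax: float, ec50: float, n: float) -> np.ndarray:
    """Saturating response through the origin: Rmax * c^n / (c^n + EC50^n)."""
    c = np.asarray(c, dtype=float)
    out = np.zeros_like(c)
    pos = c > 0
    cn = np.power(c[pos], n)
    out[pos] = rmax * cn / (cn + ec50**n)
    return out


def fit_dose_response(dr: DoseResponse) -> HillFit:
    """Least-squares Hill fit with multistart initialization.

    Starts span Hill coefficients {0.5, 1, 2, 4} crossed with EC50 values
    log-spaced over the positive dose range; the best residual sum of
    squares wins, ties resolved toward the smallest Hill coefficient.  If
    every response is (near) zero the fit is flagged unidentifiable with
    ``Rmax ~ 0``.
    """
    if dr.doses_uM.size < 4 or dr.doses_uM[0] != 0:
        raise ArgumentError("need >= 4 doses including a zero dose")
    doses = dr.doses_uM
    resp = dr.responses_pct

    scale = float(np.max(np.abs(resp)))
    if scale < 1e-9:
        return HillFit(Rmax_pct=0.0, EC50_uM=float("nan"), hill_n=1.0, rss=0.0,
                       unidentifiable=True)

    pos = doses[doses > 0]
    ec50_starts = np.geomspace(pos.min(), pos.max(), 4)
    n_starts = [0.5, 1.0, 2.0, 4.0]
    rmax0 = float(resp.max()) if resp.max() > 0 else scale

    def residuals(theta):
        rmax, log_ec50, log_n = theta
        return hill_response(doses, rmax, np.exp(log_ec50), np.exp(log_n)) - resp

    best = None
    for n0 in n_starts:
        for e0 in ec50_starts:
            try:
                sol = least_squares(
                    residuals, x0=[rmax0, np.log(e0), np.log(n0)],
                    bounds=([-np.inf, np.log(pos.min() / 1e3), np.log(0.05)],
                            [np.inf, np.log(pos.max() * 1e3), np.log(10.0)]),
                )
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            n_fit = float(np.exp(sol.x[2]))
            if best is None or rss < best[0] - 1e-12 or (
                    abs(rss - best[0]) <= 1e-12 and n_fit < best[1]):
                best = (rss, n_fit, sol)
    if best is None:
        raise ArgumentError("dose-response fit failed to converge from any start")
    rss, n_fit, sol = best
    return HillFit(
        Rmax_pct=float(sol.x[0]),
        EC50_uM=float(np.exp(sol.x[1])),
        hill_n=n_fit,
        rss=rss,
    )


def blockade_analysis(control_response_pct: float, responses_by_antagonist_dose: DoseResponse
                      ) -> tuple[np.ndarray, bool]:
    """Per-antagonist-dose inhibition of an agonist response.

    ``inhibition(d) = 1 - response(d) / control``; 0 means no blockade, 1
    complete blockade (values below 0 indicate potentiation).  Also returns
    a monotonicity flag: True when inhibition is non-decreasing with dose.
    """
    if control_response_pct <= 0:
        raise ArgumentError("control response must be positive")
    inhibition = 1.0 - responses_by_antagonist_dose.responses_pct / control_response_pct
    monotone = bool(np.all(np.diff(inhibition) >= -1e-9))
    return inhibition, monotone


def fraction_recovered(treated_pct: float, control_pct: float) -> float:
    """Fraction of the control response recovered under treatment."""
    if control_pct <= 0:
        raise ArgumentError("control response must be positive")
    return treated_pct / control_pct


def classify_timecourse(series, thresholds: TimecourseThresholds | None = None) -> str:
    """Label a beat-rate time course.

    ``series`` is a sequence of (time, percent change from baseline) pairs.
    Labels, in precedence order:

    - ``ceased``: any point at or below the cessation level (bpm = 0);
    - ``stable``: every |change| inside the stable band;
    - ``increase_then_decrease``: a supra-band rise whose final value falls
      below the negative band or at least one band below the maximum;
    - ``sustained_increase``: a supra-band rise maintained at the end;
    - ``sustained_decrease``: no supra-band rise and a sub-band fall;
    - otherwise ``stable`` (sub-band by the above, e.g. a recovered dip).
    """
    thresholds = thresholds or TimecourseThresholds()
    pts = list(series)
    if len(pts) < 3:
        raise ArgumentError("need at least 3 time points")
    change = np.asarray([p[1] for p in pts], dtype=float)
    band = thresholds.stable_band

    if np.any(change <= thresholds.ceased_pct):
        return "ceased"
    if np.all(np.abs(change) < band):
        return "stable"
    peak = change.max()
    final = change[-1]
    if peak > band and (final < -band or final < peak - band):
        return "increase_then_decrease"
    if peak > band and final > band:
        return "sustained_increase"
    if peak <= band and change.min() < -band:
        return "sustained_decrease"
    return "stable"
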