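"""Exponential-decay fit and its goodness-of-fit p-value.

The C->T frequency profile y_i at 5' positions x_i = 1..P is fitted with

    y = N * exp(-rate * x)

by nonlinear least squares. Significant exponential decay — the ancient-DNA
signature — is scored with a one-sided t-test on the rate parameter
(H1: rate > 0): t = rate / SE(rate) with P - 2 degrees of freedom, and the
goodness-of-fit p-value is the upper tail of Student's t at that statistic.
Small p means pronounced decay (ancient-like); flat or increasing profiles
give p near or above 0.5.

Policy for degenerate cases: a fit that fails to converge, or whose rate
standard error is not a positive finite number, is reported with gof_p = 1
(no evidence of decay, conservative towards modernity); a numerically
perfect fit (zero residual, SE undefined) is reported with gof_p = 0 when
the fitted rate is positive and 1 otherwise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import optimize, stats

from .damage import DamageProfile

RATE_RESTARTS = (0.5, 0.01, 0.1, 1.0)


class FitError(ValueError):
    """Raised when a profile has too few defined points to fit."""


@dataclass
class ExpFitResult:
    amplitude: float
    rate: float
    rate_se: float
    t_value: float
    df: int
    gof_p: float
    n_points: int
    converged: bool

    def to_json(self) -> str:
        d = asdict(self)
        d["amplitude_N"] = d.pop("amplitude")
        return json.dumps(d, indent=2)


def _model(x: np.ndarray, n: float, rate: float) -> np.ndarray:
    return n * np.exp(-rate * x)


def fit_exponential(profile: DamageProfile) -> ExpFitResult:
    """Least-squares fit of N*exp(-rate*x) to the defined profile points."""
    freq = profile.freq
    mask = ~np.isnan(freq)
    x = profile.positions[mask].astype(float)
    y = freq[mask]
    n_points = int(mask.sum())
    if n_points < 2:
        raise FitError("need at least two positions with defined frequency")
    df = n_points - 2

    n0 = float(max(y.max(), 1e-6))
    popt = pcov = None
    for rate0 in RATE_RESTARTS:
        try:
            popt, pcov, infodict, mesg, ier = optimize.curve_fit(
                _model, x, y, p0=[n0, rate0], maxfev=10000, full_output=True)
        except RuntimeError:
            continue
        if ier in (1, 2, 3, 4) and np.all(np.isfinite(popt)):
            break
        popt = pcov = None
    if popt is None:
        return ExpFitResult(amplitude=float("nan"), rate=float("nan"),
                            rate_se=float("nan"), t_value=float("nan"),
                            df=df, gof_p=1.0, n_points=n_points,
                            converged=False)

    amplitude, rate = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - _model(x, *popt)) ** 2))
    scale = max(1.0, float(np.sum(y ** 2)))
    if rss <= 1e-16 * scale or df < 1:
        # zero-residual (or zero-df) fit: SE of the rate is undefined
        gof = 0.0 if rate > 0 else 1.0
        return ExpFitResult(amplitude=amplitude, rate=rate, rate_se=0.0,
                            t_value=float("inf") if rate > 0 else float("-inf"),
                            df=df, gof_p=gof, n_points=n_points,
                            converged=True)

    rate_se = float(np.sqrt(pcov[1, 1]))  # curve_fit scales cov by rss/df
    if not np.isfinite(rate_se) or rate_se <= 0:
        return ExpFitResult(amplitude=amplitude, rate=rate,
                            rate_se=float("nan"), t_value=float("nan"),
                            df=df, gof_p=1.0, n_points=n_points,
                            converged=False)
    t_value = rate / rate_se
    fit = ExpFitResult(amplitude=amplitude, rate=rate, rate_se=rate_se,
                       t_value=t_value, df=df, gof_p=1.0,
                       n_points=n_points, converged=True)
    fit.gof_p = gof_pvalue(fit)
    return fit


def gof_pvalue(fit: ExpFitResult) -> float:
    """Upper-tail t probability for H1: rate > 0."""
    if not fit.converged:
        return 1.0
    if fit.rate_se == 0.0:
        return 0.0 if fit.rate > 0 else 1.0
    return float(stats.t.sf(fit.t_value, fit.df))
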