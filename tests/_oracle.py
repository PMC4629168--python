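"""Independent brute-force oracle for the exponential-decay fit.

Deliberately avoids the package's optimizer: the least-squares optimum is
located by an iteratively refined 1-D grid search over the rate (the
amplitude has a closed form at fixed rate), and the rate standard error is
obtained from a central finite-difference Jacobian. Used only to check
fit_exponential against an implementation-independent route.
"""

import numpy as np
from scipy import stats


def _best_amplitude(x, y, rate):
    e = np.exp(-rate * x)
    denom = np.sum(e * e)
    return np.sum(y * e) / denom if denom > 0 else 0.0


def _rss(x, y, rate):
    n = _best_amplitude(x, y, rate)
    return np.sum((y - n * np.exp(-rate * x)) ** 2)


def grid_fit(x, y, rate_lo=-1.0, rate_hi=3.0, n_grid=161, n_zoom=8):
    """Grid-search least squares for y = N*exp(-rate*x) plus a t-test on rate."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lo, hi = rate_lo, rate_hi
    for _ in range(n_zoom):
        grid = np.linspace(lo, hi, n_grid)
        rss = np.array([_rss(x, y, r) for r in grid])
        k = int(np.argmin(rss))
        step = grid[1] - grid[0]
        lo, hi = grid[k] - 2 * step, grid[k] + 2 * step
    rate = grid[k]
    amp = _best_amplitude(x, y, rate)
    rss_min = _rss(x, y, rate)
    df = len(x) - 2

    # central finite-difference Jacobian at the optimum
    def model(theta):
        return theta[0] * np.exp(-theta[1] * x)

    theta = np.array([amp, rate])
    jac = np.empty((len(x), 2))
    for j in range(2):
        h = 1e-6 * max(abs(theta[j]), 1e-3)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        jac[:, j] = (model(tp) - model(tm)) / (2 * h)
    cov = rss_min / df * np.linalg.inv(jac.T @ jac)
    se = float(np.sqrt(cov[1, 1]))
    t = rate / se
    p = float(stats.t.sf(t, df))
    return {"amplitude": float(amp), "rate": float(rate), "rate_se": se,
            "t_value": float(t), "df": df, "gof_p": p}
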