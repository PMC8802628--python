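"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's fitting code paths: the 4PL
oracle is a coarse grid over (midpoint, scale) with a linear solve for
the plateaus followed by a Nelder-Mead polish, and the Tm oracle is a
numeric bisection on the curve rather than the analytic inversion.
"""

import numpy as np
from scipy.optimize import brentq, minimize


def _logistic_weight(temps, midpoint, scale):
    z = np.clip((temps - midpoint) / scale, -700, 700)
    return 1.0 / (1.0 + np.exp(z))


def grid_polish_4pl_sse(temps, ys):
    """Global 4PL least-squares objective by grid search + polish."""
    temps = np.asarray(temps, dtype=float)
    ys = np.asarray(ys, dtype=float)
    t0, t1 = temps.min(), temps.max()
    best = (np.inf, None)
    scales = np.concatenate([np.geomspace(0.3, 15.0, 14), -np.geomspace(0.3, 15.0, 14)])
    for m in np.linspace(t0 - 5.0, t1 + 5.0, 41):
        for s in scales:
            w = _logistic_weight(temps, m, s)
            design = np.column_stack([1.0 - w, w])  # f = lower*(1-w) + upper*w
            coef, *_ = np.linalg.lstsq(design, ys, rcond=None)
            sse = float(np.sum((design @ coef - ys) ** 2))
            if sse < best[0]:
                best = (sse, (coef[0], coef[1], m, s))

    def objective(p):
        lower, upper, m, s = p
        w = _logistic_weight(temps, m, s)
        return float(np.sum((lower * (1 - w) + upper * w - ys) ** 2))

    res = minimize(
        objective,
        np.asarray(best[1], dtype=float),
        method="Nelder-Mead",
        options=dict(xatol=1e-12, fatol=1e-14, maxiter=40000, maxfev=40000),
    )
    return min(float(res.fun), best[0])


def bisect_tm(lower, upper, midpoint, scale, t_min, t_max):
    """Window-endpoint Tm of an exact 4PL, found by root bracketing."""

    def f(t):
        return lower + (upper - lower) / (1.0 + np.exp((t - midpoint) / scale))

    y_star = 0.5 * (f(t_min) + f(t_max))
    return brentq(lambda t: f(t) - y_star, t_min, t_max, xtol=1e-10)
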