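"""Closed-form curve models shared by the simulator and the fitters.

All sigmoid-shaped quantities in the package derive from two families:

* the four-parameter logistic (4PL) in temperature, used for melting
  curves — decreasing in ``T`` when ``scale > 0``;
* the four-parameter log-logistic in concentration, used for
  activator EC50 and inhibitor IC50 dose-response fits.
"""

from __future__ import annotations

import numpy as np

# exp() overflows float64 beyond ~709; clipping keeps the logistic exact
# in the saturated tails while avoiding RuntimeWarnings inside optimizers.
_EXP_CLIP = 700.0


def four_pl(t, lower, upper, midpoint, scale):
    """Four-parameter logistic melting curve.

    ``f(T) = lower + (upper - lower) / (1 + exp((T - midpoint) / scale))``

    With ``scale > 0`` the curve decreases from ``upper`` (low T) to
    ``lower`` (high T); the inflection sits at ``midpoint``.
    """
    t = np.asarray(t, dtype=float)
    z = np.clip((t - midpoint) / scale, -_EXP_CLIP, _EXP_CLIP)
    return lower + (upper - lower) / (1.0 + np.exp(z))


def soluble_fraction(t, tm, scale, floor):
    """Fraction of a protein remaining soluble after heating to ``t`` °C.

    A 4PL between ``floor`` (fully melted plateau, kept > 0 so log
    transforms downstream are defined) and 1 (fully soluble), with
    midpoint ``tm``.
    """
    return four_pl(t, floor, 1.0, tm, scale)


def hill(s, vmax, k_half, h):
    """Hill saturation curve ``v = vmax * S^h / (k_half^h + S^h)``."""
    s = np.asarray(s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = s**h / (k_half**h + s**h)
    return vmax * np.where(s > 0, r, 0.0)


def log_logistic(c, floor, ceiling, c50, h):
    """Ascending four-parameter log-logistic in concentration.

    ``v(c) = floor + (ceiling - floor) / (1 + (c50 / c)^h)``

    Rises from ``floor`` at c -> 0 to ``ceiling`` at c -> inf for
    ``h > 0``; ``v(c50)`` is the half-way point. Evaluates to ``floor``
    at c == 0.
    """
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 / (1.0 + (c50 / c) ** h)
    return floor + (ceiling - floor) * np.where(c > 0, frac, 0.0)


def log_logistic_desc(c, floor, ceiling, c50, h):
    """Descending log-logistic: ``ceiling`` at c -> 0, ``floor`` at c -> inf."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 / (1.0 + (c / c50) ** h)
    return floor + (ceiling - floor) * np.where(c > 0, frac, 1.0)


def exp_decay(t, a0, k):
    """First-order inactivation ``a(t) = a0 * exp(-k t)``."""
    t = np.asarray(t, dtype=float)
    return a0 * np.exp(-k * t)
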