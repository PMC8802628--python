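"""Per-protein 4PL melting-curve fits, Tm extraction and ΔTm ranking.

Each protein/condition pair gets a four-parameter logistic fit in
temperature with a self-starting initialization (plateaus from the
10th/90th abundance percentiles, midpoint at the temperature nearest
their mean, scale from the central-difference slope there). The melting
temperature is the temperature at 50% between the fitted intensities at
the lowest and highest assayed temperatures — obtained by analytic
inversion of the logistic, not by root finding. A [0,1] quality score
combines both conditions' goodness of fit, curve steepness and slope
similarity so flat or discordant curve pairs rank low.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .curves import four_pl
from .psm import ProteinQuantTable

#: Minimal plateau separation (log2 units) for a Tm to be considered defined.
MIN_PLATEAU_SPAN = 0.1


@dataclass
class FourPLParams:
    lower: float
    upper: float
    midpoint: float  # °C
    scale: float  # °C; positive => decreasing curve


@dataclass
class MeltFit:
    params: FourPLParams
    r_squared: float
    converged: bool
    residuals: np.ndarray

    @property
    def slope_at_midpoint(self) -> float:
        """Signed slope of the fitted curve at its inflection, log2/°C."""
        p = self.params
        return (p.lower - p.upper) / (4.0 * p.scale)

    def predict(self, t):
        p = self.params
        return four_pl(t, p.lower, p.upper, p.midpoint, p.scale)


def _self_start(temps: np.ndarray, ys: np.ndarray) -> tuple[float, float, float, float]:
    lower0 = float(np.percentile(ys, 10))
    upper0 = float(np.percentile(ys, 90))
    mid_y = 0.5 * (lower0 + upper0)
    i = int(np.argmin(np.abs(ys - mid_y)))
    # central-difference slope at the candidate midpoint
    j0, j1 = max(i - 1, 0), min(i + 1, len(ys) - 1)
    dy = ys[j1] - ys[j0]
    dt = temps[j1] - temps[j0]
    slope = dy / dt if dt != 0 else 0.0
    if slope != 0 and upper0 > lower0:
        scale0 = (lower0 - upper0) / (4.0 * slope)
    else:
        scale0 = (temps[-1] - temps[0]) / 8.0
    scale0 = float(np.clip(abs(scale0), 0.2, (temps[-1] - temps[0]) / 2.0))
    if slope > 0:
        scale0 = -scale0  # increasing data: allow a rising logistic
    return lower0, upper0, float(temps[i]), scale0


def _canonical(popt) -> FourPLParams:
    lower, upper, midpoint, scale = (float(v) for v in popt)
    # (l, u, m, s) and (u, l, m, -s) describe the same curve; report the
    # branch with upper >= lower.
    if upper < lower:
        lower, upper, scale = upper, lower, -scale
    return FourPLParams(lower, upper, midpoint, scale)


def fit_4pl(temperatures, abundances) -> MeltFit:
    """Least-squares 4PL fit; returns ``converged=False`` instead of raising.

    Requires at least 5 observed (non-missing) points and strictly
    increasing temperatures. Constant abundances yield a flat,
    non-converged fit.
    """
    temps = np.asarray(temperatures, dtype=float)
    ys = np.asarray(abundances, dtype=float)
    mask = np.isfinite(ys) & np.isfinite(temps)
    temps, ys = temps[mask], ys[mask]
    if len(temps) < 5:
        raise ValueError(f"need >= 5 observed points to fit, got {len(temps)}")
    if not np.all(np.diff(temps) > 0):
        raise ValueError("temperatures must be strictly increasing")
    sstot = float(np.sum((ys - ys.mean()) ** 2))
    if sstot == 0.0:
        flat = FourPLParams(float(ys[0]), float(ys[0]), float(temps.mean()), 1.0)
        return MeltFit(flat, 0.0, converged=False, residuals=np.zeros_like(ys))
    p0 = _self_start(temps, ys)
    # second start with the opposite transition direction guards against
    # the self-start mis-reading noisy, nearly flat curves
    starts = [p0, (p0[0], p0[1], p0[2], -p0[3])]
    popt, best_sse = None, np.inf
    for start in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                cand, _ = curve_fit(four_pl, temps, ys, p0=start, maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((ys - four_pl(temps, *cand)) ** 2))
        if sse < best_sse:
            popt, best_sse = cand, sse
    if popt is None:
        flat = FourPLParams(float(ys.mean()), float(ys.mean()), float(temps.mean()), 1.0)
        return MeltFit(flat, 0.0, converged=False, residuals=ys - ys.mean())
    params = _canonical(popt)
    pred = four_pl(temps, params.lower, params.upper, params.midpoint, params.scale)
    resid = ys - pred
    r2 = 1.0 - float(np.sum(resid**2)) / sstot
    converged = bool(np.isfinite(r2)) and params.scale != 0.0
    return MeltFit(params, r2, converged=converged, residuals=resid)


def compute_tm(fit: MeltFit, t_min: float, t_max: float) -> float | None:
    """Temperature at 50% between fitted intensity at ``t_min`` and ``t_max``.

    Analytic inversion of the fitted logistic:
    ``Tm = midpoint + scale * ln((upper - y*) / (y* - lower))`` with
    ``y* = (f(t_min) + f(t_max)) / 2``. Returns ``None`` (undefined, as
    opposed to a numerical failure) when the plateau separation is below
    tolerance, when ``y*`` falls outside the open plateau interval, or
    when the inverted Tm lies outside ``[t_min, t_max]``.
    """
    if not fit.converged:
        raise ValueError("compute_tm requires a converged fit")
    p = fit.params
    if (p.upper - p.lower) < MIN_PLATEAU_SPAN:
        return None
    y_star = 0.5 * float(fit.predict(t_min) + fit.predict(t_max))
    if y_star <= p.lower or y_star >= p.upper:
        return None
    tm = p.midpoint + p.scale * math.log((p.upper - y_star) / (y_star - p.lower))
    if not (t_min <= tm <= t_max):
        return None
    return float(tm)


def quality_score(
    fit_vehicle: MeltFit, fit_treated: MeltFit, slope_gate_c: float = 0.05
) -> float:
    """Two-curve quality score in [0, 1].

    ``QS = min(R²_v, R²_t) * g(|slope_v|) * g(|slope_t|) * s(ratio)``
    with the saturating steepness gate ``g(x) = x² / (x² + c²)`` and the
    slope-similarity penalty ``s(r) = exp(-(ln r)² / 0.5)``. ``c`` is
    typically set to 25% of the proteome's median transition slope (see
    :func:`thermal_shift_table`); the default suits log2-scale melting
    curves with ~3 log2-unit transitions.

    Monotone non-decreasing in each R²; -> 0 as either curve flattens;
    maximal when both curves are steep, well fit and equally sloped.
    """
    r2 = max(0.0, min(fit_vehicle.r_squared, fit_treated.r_squared))
    sv = abs(fit_vehicle.slope_at_midpoint)
    st = abs(fit_treated.slope_at_midpoint)
    if sv == 0.0 or st == 0.0:
        return 0.0

    def g(x: float) -> float:
        return x**2 / (x**2 + slope_gate_c**2)

    s = math.exp(-(math.log(sv / st) ** 2) / 0.5)
    return float(r2 * g(sv) * g(st) * s)


def _condition_series(pq: ProteinQuantTable, design: dict, condition: str):
    chans = [
        ch for ch, meta in design.items() if meta["condition"] == condition
    ]
    temps = np.array([float(design[ch]["temperature"]) for ch in chans])
    order = np.argsort(temps)
    return [chans[i] for i in order], temps[order]


def thermal_shift_table(
    pq: ProteinQuantTable,
    design: dict,
    t_window: tuple[float, float] | None = None,
    min_points: int = 6,
) -> pd.DataFrame:
    """Fit both conditions for every protein and rank by ΔTm (descending).

    ``t_window`` defaults to the design's temperature extremes. Proteins
    with fewer than ``min_points`` observed temperatures in either
    condition, or with a non-converged fit or undefined Tm, carry NaN
    ΔTm and sort to the bottom. The steepness gate of the quality score
    is calibrated to 25% of the median |slope at midpoint| over all
    converged fits.
    """
    v_chans, v_temps = _condition_series(pq, design, "vehicle")
    t_chans, t_temps = _condition_series(pq, design, "treated")
    if t_window is None:
        all_t = np.concatenate([v_temps, t_temps])
        t_window = (float(all_t.min()), float(all_t.max()))
    t_lo, t_hi = t_window

    fits: dict[str, tuple[MeltFit | None, MeltFit | None]] = {}
    slopes: list[float] = []
    for pid, row in pq.log2_abundance.iterrows():
        pair = []
        for chans, temps in ((v_chans, v_temps), (t_chans, t_temps)):
            ys = row[chans].to_numpy(dtype=float)
            if np.isfinite(ys).sum() < max(min_points, 5):
                pair.append(None)
                continue
            fit = fit_4pl(temps, ys)
            pair.append(fit)
            if fit.converged:
                slopes.append(abs(fit.slope_at_midpoint))
        fits[pid] = tuple(pair)

    gate_c = 0.25 * float(np.median(slopes)) if slopes else 0.05
    records = []
    for pid, (fv, ft) in fits.items():
        rec = {
            "protein_id": pid,
            "tm_vehicle": np.nan,
            "tm_treated": np.nan,
            "delta_tm": np.nan,
            "r2_vehicle": np.nan,
            "r2_treated": np.nan,
            "quality_score": np.nan,
            "converged_vehicle": fv is not None and fv.converged,
            "converged_treated": ft is not None and ft.converged,
        }
        if fv is not None:
            rec["r2_vehicle"] = fv.r_squared
        if ft is not None:
            rec["r2_treated"] = ft.r_squared
        if fv is not None and ft is not None and fv.converged and ft.converged:
            tm_v = compute_tm(fv, t_lo, t_hi)
            tm_t = compute_tm(ft, t_lo, t_hi)
            rec["quality_score"] = quality_score(fv, ft, slope_gate_c=gate_c)
            if tm_v is not None:
                rec["tm_vehicle"] = tm_v
            if tm_t is not None:
                rec["tm_treated"] = tm_t
            if tm_v is not None and tm_t is not None:
                rec["delta_tm"] = tm_t - tm_v
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    return out.sort_values(
        "delta_tm", ascending=False, na_position="last", kind="mergesort"
    ).reset_index(drop=True)
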