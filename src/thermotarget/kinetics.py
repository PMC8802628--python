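"""Enzyme-assay computations for allosteric PFK1 characterization.

Covers the full in-vitro arc: extraction of specific activity from
NADH-coupled A340 traces, Hill fits of the F6P saturation curve
(V_max, K_M, Hill coefficient h — PFK1 is strongly cooperative, h ~ 3),
log-logistic EC50 fits for small-molecule relief of ATP inhibition,
descending dose-response IC50 fits for cellular readouts (% NETosis),
and first-order thermal-inactivation fits with a bootstrap ligand-
protection contrast.

Units follow enzymology convention: specific activity in µmol product
per minute per mg enzyme, K_M in mM substrate, EC50/IC50 in nM
compound, inactivation rate in 1/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .curves import exp_decay, hill, log_logistic, log_logistic_desc

#: NADH molar extinction coefficient at 340 nm (M^-1 cm^-1).
EPSILON_NADH = 6220.0

#: NADH consumed (or produced) per unit of product, by assay chemistry.
#: The aldolase/TPI/GPDH readout oxidizes one NADH per triose phosphate,
#: i.e. two per FBP; the PK/LDH readout oxidizes one NADH per ADP.
STOICHIOMETRY = {
    "aldolase_coupled": 2.0,
    "lysate_pfk1": 2.0,
    "pk_ldh_coupled": 1.0,
}


@dataclass
class KineticTrace:
    """One plate-reader absorbance trace from a coupled PFK1 assay."""

    times: np.ndarray  # seconds
    a340: np.ndarray  # absorbance units
    assay_chemistry: str  # key of STOICHIOMETRY
    enzyme_mass_mg: float
    well_volume_l: float = 200e-6
    path_length_cm: float = 1.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.a340 = np.asarray(self.a340, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.a340 < 0):
            raise ValueError("absorbance must be non-negative")
        if self.assay_chemistry not in STOICHIOMETRY:
            raise ValueError(f"unknown assay chemistry {self.assay_chemistry!r}")


@dataclass
class HillParams:
    vmax: float  # µmol FBP min^-1 mg^-1
    k_half: float  # mM (K_M for F6P)
    hill_h: float
    se: dict = field(default_factory=dict)


@dataclass
class ActivationFit:
    ec50: float  # nM
    hill_act: float
    v_floor: float  # rate at zero activator under inhibitory ATP
    v_ceiling: float  # maximal relieved rate
    se: dict = field(default_factory=dict)

    @property
    def fractional_inhibition_at_zero(self) -> float:
        """1 − v_floor / v_ceiling: depth of the ATP inhibition relieved."""
        return 1.0 - self.v_floor / self.v_ceiling


@dataclass
class DoseResponseFit:
    ic50: float  # nM
    hill: float
    floor: float  # % response at saturating inhibitor (spontaneous)
    ceiling: float  # % response without inhibitor (stimulated)
    extrapolated: bool = False
    se: dict = field(default_factory=dict)


@dataclass
class DecayFit:
    k_inact: float  # min^-1
    a0: float  # initial fractional activity


@dataclass
class InactivationResult:
    fits: dict  # condition -> DecayFit
    contrasts: dict  # ligand condition -> (k_control − k_ligand, bootstrap p)


def trace_to_rate(
    trace: KineticTrace, fit_window: tuple[float, float] | None = None
) -> float:
    """Specific activity (µmol product min^-1 mg^-1) from a linear A340 window.

    Fits a straight line to A340 vs time over ``fit_window`` (seconds;
    default: whole trace), converts the absorbance slope to a molar NADH
    rate by Beer-Lambert (ε = 6220 M^-1 cm^-1), scales by well volume
    and the chemistry's NADH-per-product stoichiometry, and normalizes
    by enzyme mass. Signals a curved window (substrate exhaustion) by
    raising, so the caller can shrink the window.
    """
    t, y = trace.times, trace.a340
    if fit_window is not None:
        lo, hi = fit_window
        mask = (t >= lo) & (t <= hi)
        t, y = t[mask], y[mask]
    if len(t) < 4:
        raise ValueError("need at least 4 points in the fit window")
    slope_per_s, intercept = np.polyfit(t, y, 1)
    pred = slope_per_s * t + intercept
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot > 0:
        r2 = 1.0 - float(np.sum((y - pred) ** 2)) / sstot
        # Curvature check: a flat first/second-half slope mismatch with a
        # poor linear fit indicates the window left the initial-rate regime.
        half = len(t) // 2
        s1 = np.polyfit(t[:half], y[:half], 1)[0]
        s2 = np.polyfit(t[half:], y[half:], 1)[0]
        if r2 < 0.9 and abs(s1) > 0 and abs(s2) < 0.5 * abs(s1):
            raise RuntimeError(
                "A340 trace is non-linear over the window (substrate "
                "exhaustion?); shrink fit_window"
            )
    slope_per_min = abs(slope_per_s) * 60.0
    molar_rate = slope_per_min / (EPSILON_NADH * trace.path_length_cm)  # M/min
    mol_per_min = molar_rate * trace.well_volume_l
    umol_product_per_min = mol_per_min * 1e6 / STOICHIOMETRY[trace.assay_chemistry]
    return float(umol_product_per_min / trace.enzyme_mass_mg)


def _se_from_cov(pcov, names) -> dict:
    if pcov is None or not np.all(np.isfinite(pcov)):
        return {k: float("nan") for k in names}
    return {k: float(np.sqrt(max(pcov[i, i], 0.0))) for i, k in enumerate(names)}


def fit_hill(f6p_concs, rates) -> HillParams:
    """Nonlinear least-squares Hill fit of a substrate saturation curve.

    ``v = vmax * S^h / (k_half^h + S^h)`` with S in mM. Accepts
    replicate observations (repeated concentrations). Raises on data
    with no curvature.
    """
    s = np.asarray(f6p_concs, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(np.unique(s)) < 5:
        raise ValueError("need at least 5 distinct concentrations")
    if np.allclose(v, v[0]):
        raise RuntimeError("rates carry no curvature; Hill fit is undefined")
    vmax0 = float(v.max())
    half = vmax0 / 2.0
    k0 = float(s[np.argmin(np.abs(v - half))])
    k0 = k0 if k0 > 0 else float(np.median(s[s > 0]))
    try:
        popt, pcov = optimize.curve_fit(
            hill, s, v, p0=[vmax0, k0, 2.0],
            bounds=([0, 1e-9, 0.1], [np.inf, np.inf, 20.0]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as err:
        raise RuntimeError(f"Hill fit failed to converge: {err}") from err
    se = _se_from_cov(pcov, ("vmax", "k_half", "hill_h"))
    return HillParams(float(popt[0]), float(popt[1]), float(popt[2]), se=se)


def _fit_log_logistic(concs, resp, ascending, bounds=None):
    """Shared EC50/IC50 machinery on log10 concentration.

    Zero-concentration wells cannot enter a log-scale model directly;
    they are retained as direct observations of the zero-compound
    asymptote (floor for ascending, ceiling for descending fits).
    """
    c = np.asarray(concs, dtype=float)
    y = np.asarray(resp, dtype=float)
    pos = c > 0
    if pos.sum() < 4 or len(np.unique(c[pos])) < 4:
        raise ValueError("need at least 4 distinct non-zero concentrations")
    model = log_logistic if ascending else log_logistic_desc
    lo_y, hi_y = float(y.min()), float(y.max())
    span = hi_y - lo_y
    if span <= 0:
        raise RuntimeError("responses carry no dose dependence")
    c50_0 = float(np.exp(np.mean(np.log(c[pos]))))
    p0 = [lo_y, hi_y, c50_0, 1.0]
    if bounds is None:
        bounds = ([-np.inf, -np.inf, 1e-12, 0.05], [np.inf, np.inf, np.inf, 20.0])

    def resid(theta):
        floor, ceiling, c50, h = theta
        pred = model(c, floor, ceiling, c50, h)
        return pred - y

    p0[0] = float(np.clip(p0[0], bounds[0][0], bounds[1][0]))
    p0[1] = float(np.clip(p0[1], bounds[0][1], bounds[1][1]))
    res = optimize.least_squares(
        resid, p0, bounds=tuple(bounds),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    if not res.success:
        raise RuntimeError("log-logistic fit failed to converge")
    # covariance from the Jacobian at the solution
    dof = max(len(y) - 4, 1)
    s2 = float(np.sum(res.fun**2)) / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
    except np.linalg.LinAlgError:
        cov = None
    return res.x, cov


def fit_activation(activator_concs, rates, fixed_atp_mm: float | None = None) -> ActivationFit:
    """EC50 fit for relief of ATP inhibition by an allosteric activator.

    Ascending four-parameter log-logistic in log10 concentration (nM).
    Zero-activator wells pin the inhibited floor. ``fixed_atp_mm`` is
    carried for provenance only; the fit itself is at one ATP level.
    Raises if no non-zero concentrations are present (floor estimable,
    EC50 undefined).
    """
    c = np.asarray(activator_concs, dtype=float)
    if not np.any(c > 0):
        raise ValueError("only zero-activator wells: EC50 is undefined")
    popt, pcov = _fit_log_logistic(c, rates, ascending=True)
    floor, ceiling, ec50, h = (float(x) for x in popt)
    se = _se_from_cov(pcov, ("v_floor", "v_ceiling", "ec50", "hill_act"))
    return ActivationFit(ec50=ec50, hill_act=h, v_floor=floor, v_ceiling=ceiling, se=se)


def fit_ic50(concs, response_fraction) -> DoseResponseFit:
    """Descending dose-response fit of a cellular readout (% of cells).

    Floor constrained >= 0 and ceiling <= 100. Monotone-increasing
    responses are rejected (wrong sign for an inhibitor). The
    ``extrapolated`` flag is set when the fitted IC50 falls outside the
    tested concentration range.
    """
    c = np.asarray(concs, dtype=float)
    y = np.asarray(response_fraction, dtype=float)
    pos = c > 0
    if pos.sum() >= 3:
        rho = stats.spearmanr(c[pos], y[pos]).statistic
        if np.isfinite(rho) and rho > 0.5:
            raise RuntimeError(
                "response increases with inhibitor concentration; "
                "descending dose-response fit rejected"
            )
    bounds = ([0.0, 0.0, 1e-12, 0.05], [100.0, 100.0, np.inf, 20.0])
    popt, pcov = _fit_log_logistic(c, y, ascending=False, bounds=bounds)
    floor, ceiling, ic50, h = (float(x) for x in popt)
    extrapolated = bool(ic50 < c[pos].min() or ic50 > c[pos].max())
    se = _se_from_cov(pcov, ("floor", "ceiling", "ic50", "hill"))
    return DoseResponseFit(
        ic50=ic50, hill=h, floor=floor, ceiling=ceiling,
        extrapolated=extrapolated, se=se,
    )


def _fit_decay(times, activity) -> DecayFit:
    t = np.asarray(times, dtype=float)
    a = np.asarray(activity, dtype=float)
    popt, _ = optimize.curve_fit(
        exp_decay, t, a, p0=[max(a.max(), 1e-6), 0.05],
        bounds=([1e-9, 0.0], [1.5, np.inf]), maxfev=10000,
    )
    return DecayFit(k_inact=float(popt[1]), a0=float(popt[0]))


def fit_inactivation(
    times,
    residual_activity,
    conditions,
    control_condition: str = "control",
    n_boot: int = 500,
    seed: int = 0,
) -> InactivationResult:
    """Per-condition first-order inactivation fits + ligand-protection test.

    Fits ``a0 * exp(-k t)`` for every condition label and, for each
    non-control condition, reports the protection contrast
    ``k_control − k_ligand`` with a two-sided bootstrap p value
    (case resampling within condition, seeded).
    """
    df = pd.DataFrame(
        {
            "time": np.asarray(times, dtype=float),
            "activity": np.asarray(residual_activity, dtype=float),
            "condition": list(conditions),
        }
    )
    labels = list(dict.fromkeys(df["condition"]))
    if control_condition not in labels:
        raise ValueError(f"control condition {control_condition!r} not in data")
    fits = {
        lab: _fit_decay(g["time"], g["activity"])
        for lab, g in df.groupby("condition", sort=False)
    }
    rng = np.random.default_rng(seed)
    contrasts: dict[str, tuple[float, float]] = {}
    ctrl = df[df["condition"] == control_condition]
    for lab in labels:
        if lab == control_condition:
            continue
        lig = df[df["condition"] == lab]
        point = fits[control_condition].k_inact - fits[lab].k_inact
        boot = np.empty(n_boot)
        for b in range(n_boot):
            ic = rng.integers(0, len(ctrl), len(ctrl))
            il = rng.integers(0, len(lig), len(lig))
            try:
                kc = _fit_decay(
                    ctrl["time"].to_numpy()[ic], ctrl["activity"].to_numpy()[ic]
                ).k_inact
                kl = _fit_decay(
                    lig["time"].to_numpy()[il], lig["activity"].to_numpy()[il]
                ).k_inact
                boot[b] = kc - kl
            except RuntimeError:
                boot[b] = np.nan
        boot = boot[np.isfinite(boot)]
        if len(boot) == 0:
            p = float("nan")
        else:
            # add-one correction keeps p strictly positive at finite n_boot
            nb = len(boot)
            frac_le = (1 + np.sum(boot <= 0)) / (nb + 1)
            frac_ge = (1 + np.sum(boot >= 0)) / (nb + 1)
            p = float(min(1.0, 2.0 * min(frac_le, frac_ge)))
        contrasts[lab] = (float(point), p)
    return InactivationResult(fits=fits, contrasts=contrasts)


def fractional_inhibition(v_inhibited: float, v_uninhibited: float) -> float:
    """Percent inhibition ``100 * (1 − v_i / v_u)``, clipped to [0, 100]."""
    if v_uninhibited == 0:
        raise ValueError("uninhibited rate must be non-zero")
    return float(np.clip(100.0 * (1.0 - v_inhibited / v_uninhibited), 0.0, 100.0))
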