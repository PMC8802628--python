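"""Enzyme-kinetics fitters: round trips, unit conversions, error contracts."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from thermotarget import (
    KineticTrace,
    fit_activation,
    fit_hill,
    fit_ic50,
    fit_inactivation,
    fractional_inhibition,
    simulate_kinetics,
    trace_to_rate,
)
from thermotarget.curves import hill as hill_model
from thermotarget.curves import log_logistic, log_logistic_desc


class TestTraceToRate:
    def _trace(self, slope_au_per_min, chemistry="aldolase_coupled", mass_mg=0.001):
        t = np.arange(0.0, 300.0, 15.0)
        a340 = 1.0 - slope_au_per_min / 60.0 * t
        return KineticTrace(
            times=t, a340=a340, assay_chemistry=chemistry,
            enzyme_mass_mg=mass_mg, well_volume_l=200e-6, path_length_cm=1.0,
        )

    def test_hand_unit_conversion_aldolase(self):
        """-0.0622 AU/min, eps 6220, 1 cm, 200 uL, 2 NADH/FBP, 1 ug enzyme
        works out to exactly 1 umol FBP per min per mg."""
        rate = trace_to_rate(self._trace(0.0622))
        assert rate == pytest.approx(1.0, rel=1e-12)

    def test_pk_ldh_stoichiometry_doubles_the_rate(self):
        aldolase = trace_to_rate(self._trace(0.0622))
        pk_ldh = trace_to_rate(self._trace(0.0622, chemistry="pk_ldh_coupled"))
        assert pk_ldh == pytest.approx(2 * aldolase)

    def test_flat_trace_gives_zero(self):
        trace = self._trace(0.0)
        assert trace_to_rate(trace) == pytest.approx(0.0, abs=1e-12)

    def test_window_restriction_and_minimum_points(self):
        trace = self._trace(0.0622)
        assert trace_to_rate(trace, fit_window=(0, 60)) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="4 points"):
            trace_to_rate(trace, fit_window=(0, 20))

    def test_substrate_exhaustion_signalled(self):
        t = np.arange(0.0, 600.0, 15.0)
        a340 = 0.2 + 0.8 * np.exp(-t / 60.0)  # saturating depletion
        trace = KineticTrace(
            times=t, a340=a340, assay_chemistry="aldolase_coupled", enzyme_mass_mg=0.001
        )
        with pytest.raises(RuntimeError, match="non-linear"):
            trace_to_rate(trace)

    def test_invalid_traces_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            KineticTrace([0, 0, 1], [1, 1, 1], "aldolase_coupled", 0.001)
        with pytest.raises(ValueError, match="non-negative"):
            KineticTrace([0, 1, 2], [1, -0.1, 1], "aldolase_coupled", 0.001)
        with pytest.raises(ValueError, match="chemistry"):
            KineticTrace([0, 1, 2], [1, 1, 1], "hexokinase", 0.001)


# Table-style ground truths exercised through the simulate -> fit loop:
# wild-type and effector-site-mutant F6P saturation parameters.
HILL_TRUTHS = [
    dict(vmax=13.28, k_half=1.97, h=3.16),
    dict(vmax=17.36, k_half=0.57, h=3.07),
]


class TestFitHill:
    @pytest.mark.parametrize("truth", HILL_TRUTHS)
    def test_noiseless_round_trip(self, truth):
        concs = np.geomspace(0.25, 8.0, 8)
        rates = hill_model(concs, truth["vmax"], truth["k_half"], truth["h"])
        fit = fit_hill(concs, rates)
        assert fit.vmax == pytest.approx(truth["vmax"], rel=1e-6)
        assert fit.k_half == pytest.approx(truth["k_half"], rel=1e-6)
        assert fit.hill_h == pytest.approx(truth["h"], rel=1e-6)

    def test_half_saturation_definition(self):
        fit_input = np.geomspace(0.25, 8.0, 8)
        rates = hill_model(fit_input, 10.0, 2.0, 3.0)
        fit = fit_hill(fit_input, rates)
        assert hill_model(fit.k_half, fit.vmax, fit.k_half, fit.hill_h) == (
            pytest.approx(fit.vmax / 2)
        )

    def test_noisy_recovery_within_fifteen_percent(self):
        df = simulate_kinetics(
            "hill", dict(vmax=13.28, k_half=1.97, h=3.16),
            dict(x=list(np.geomspace(0.25, 8, 8)), n_replicates=3, noise_cv=0.05),
            seed=202,
        )
        fit = fit_hill(df["conc"], df["response"])
        assert fit.k_half == pytest.approx(1.97, rel=0.15)
        assert fit.se["k_half"] > 0

    def test_hill_one_reduces_to_michaelis_menten(self):
        concs = np.geomspace(0.25, 8.0, 8)
        rates = hill_model(concs, 10.0, 2.0, 1.0)

        def mm(s, vmax, km):
            return vmax * s / (km + s)

        popt, _ = curve_fit(mm, concs, rates, p0=[9.0, 1.0])
        fit = fit_hill(concs, rates)
        assert fit.hill_h == pytest.approx(1.0, abs=1e-4)
        assert fit.k_half == pytest.approx(popt[1], rel=1e-4)

    def test_flat_rates_signalled(self):
        with pytest.raises(RuntimeError, match="curvature"):
            fit_hill(np.geomspace(0.25, 8, 8), np.ones(8))


class TestFitActivation:
    def test_noiseless_round_trip(self):
        concs = np.concatenate([[0.0], np.geomspace(1, 1000, 10)])
        rates = log_logistic(concs, 1.5, 10.0, 14.0, 1.0)
        fit = fit_activation(concs, rates)
        assert fit.ec50 == pytest.approx(14.0, rel=1e-6)
        assert fit.v_floor == pytest.approx(1.5, rel=1e-6)
        assert fit.v_ceiling == pytest.approx(10.0, rel=1e-6)
        assert fit.fractional_inhibition_at_zero == pytest.approx(0.85, rel=1e-6)

    def test_rescaling_rates_leaves_ec50_unchanged(self):
        concs = np.concatenate([[0.0], np.geomspace(1, 1000, 10)])
        rates = log_logistic(concs, 1.5, 10.0, 14.0, 1.0)
        a = fit_activation(concs, rates)
        b = fit_activation(concs, rates * 3.7)
        assert b.ec50 == pytest.approx(a.ec50, rel=1e-9)

    def test_zero_activator_only_is_undefined(self):
        with pytest.raises(ValueError, match="EC50 is undefined"):
            fit_activation([0.0, 0.0, 0.0], [1.5, 1.4, 1.6])


class TestFitIC50:
    def test_noiseless_round_trip_netosis_style(self):
        concs = np.concatenate([[0.0], np.geomspace(0.1, 1000, 8)])
        resp = log_logistic_desc(concs, 7.0, 75.0, 4.0, 1.0)
        fit = fit_ic50(concs, resp)
        assert fit.ic50 == pytest.approx(4.0, rel=1e-6)
        assert fit.floor == pytest.approx(7.0, rel=1e-4)
        assert fit.ceiling == pytest.approx(75.0, rel=1e-6)
        assert not fit.extrapolated

    def test_increasing_response_rejected(self):
        concs = np.geomspace(0.1, 1000, 8)
        resp = log_logistic(concs, 7.0, 75.0, 4.0, 1.0)  # ascending
        with pytest.raises(RuntimeError, match="increases"):
            fit_ic50(concs, resp)

    def test_ic50_outside_tested_range_flagged(self):
        concs = np.concatenate([[0.0], np.geomspace(100, 10000, 8)])
        resp = log_logistic_desc(concs, 7.0, 75.0, 4.0, 1.0)  # IC50 below range
        fit = fit_ic50(concs, resp)
        assert fit.extrapolated


class TestInactivation:
    def _two_condition_data(self, k_ctrl, k_lig, seed=30):
        t = list(np.arange(0.0, 31.0, 5.0))
        a = simulate_kinetics(
            "decay", dict(a0=1.0, k=k_ctrl),
            dict(x=t, n_replicates=3, noise_cv=0.05), seed=seed,
        )
        b = simulate_kinetics(
            "decay", dict(a0=1.0, k=k_lig),
            dict(x=t, n_replicates=3, noise_cv=0.05), seed=seed + 1,
        )
        times = list(a["time"]) + list(b["time"])
        act = list(a["response"]) + list(b["response"])
        conds = ["control"] * len(a) + ["ligand"] * len(b)
        return times, act, conds

    def test_protective_ligand_contrast_recovered_and_significant(self):
        times, act, conds = self._two_condition_data(0.10, 0.02)
        res = fit_inactivation(times, act, conds, n_boot=200, seed=1)
        contrast, p = res.contrasts["ligand"]
        assert contrast == pytest.approx(0.08, abs=0.02)
        assert p < 0.05
        assert res.fits["control"].k_inact == pytest.approx(0.10, rel=0.2)

    def test_non_protective_ligand_not_significant(self):
        times, act, conds = self._two_condition_data(0.10, 0.10)
        res = fit_inactivation(times, act, conds, n_boot=200, seed=2)
        contrast, p = res.contrasts["ligand"]
        assert abs(contrast) < 0.03
        assert p > 0.05

    def test_zero_rate_data_fit_flat(self):
        times = list(np.arange(0, 31, 5.0)) * 2
        act = [0.95] * 7 + [0.95] * 7
        conds = ["control"] * 7 + ["ligand"] * 7
        res = fit_inactivation(times, act, conds, n_boot=50, seed=3)
        assert res.fits["control"].k_inact == pytest.approx(0.0, abs=1e-4)
        assert res.contrasts["ligand"][0] == pytest.approx(0.0, abs=1e-4)

    def test_missing_control_condition(self):
        with pytest.raises(ValueError, match="control"):
            fit_inactivation([0, 1], [1, 0.9], ["a", "a"], control_condition="control")


@pytest.mark.parametrize(
    "vi, vu, expected",
    [(10.0, 10.0, 0.0), (0.0, 10.0, 100.0), (1.0, 10.0, 90.0), (-5.0, 10.0, 100.0)],
)
def test_fractional_inhibition(vi, vu, expected):
    assert fractional_inhibition(vi, vu) == pytest.approx(expected)


def test_fractional_inhibition_zero_reference():
    with pytest.raises(ValueError):
        fractional_inhibition(1.0, 0.0)
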