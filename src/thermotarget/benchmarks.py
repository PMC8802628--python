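"""Bundled parameter-recovery experiments on reference fixtures.

Each experiment plants a published-style ground truth in the synthetic
generator, runs the relevant stage of the package end to end, and
returns the recovered quantity. The kinetic fixtures mirror how such
values are produced at the bench: every "determination" is an
independent titration (replicate wells with proportional noise) fitted
on its own, and the reported value is the mean over determinations.

These routines power ``scripts/acceptance.py`` and the recovery tests;
they are also convenient smoke tests of a local installation.
"""

from __future__ import annotations

import numpy as np

from .kinetics import fit_activation, fit_hill, fit_ic50
from .melt import thermal_shift_table
from .psm import fdr_filter, normalize, qc_filter, summarize_to_protein
from .synthetic import SimConfig, make_ground_truth, simulate_kinetics, simulate_tpp

_SEED_MOD = 2**31 - 1


def _hill_case(vmax, k_half, h, n_det):
    return dict(
        model="hill",
        params=dict(vmax=vmax, k_half=k_half, h=h),
        x=list(np.geomspace(0.25, 8.0, 8)),  # mM F6P
        report="k_half",
        truth=k_half,
        n_determinations=n_det,
    )


def _activation_case(ec50, ceiling, inhibition, n_det, c_lo=1.0, c_hi=1000.0):
    return dict(
        model="activation",
        params=dict(floor=(1.0 - inhibition) * ceiling, ceiling=ceiling, ec50=ec50, h=1.0),
        x=[0.0] + list(np.geomspace(c_lo, c_hi, 10)),  # nM activator
        report="ec50",
        truth=ec50,
        n_determinations=n_det,
    )


def _dose_response_case(ic50, n_det, c_lo, c_hi):
    # floor/ceiling: spontaneous vs stimulus-induced NETosis fractions
    return dict(
        model="dose_response",
        params=dict(floor=7.0, ceiling=75.0, ic50=ic50, h=1.0),
        x=[0.0] + list(np.geomspace(c_lo, c_hi, 8)),  # nM inhibitor
        report="ic50",
        truth=ic50,
        n_determinations=n_det,
    )


#: Reference kinetic fixtures. Enzymatic ground truths are the published
#: characterization of PFK1 constructs (F6P saturation at pH 7.5 with
#: 225 uM ATP; activator titrations at 3.1 mM ATP for PFKL, 4.0 mM for
#: PFKM) and the cellular NETosis dose-response readouts; the number of
#: determinations matches the reported replication. Activation ceilings
#: are the Hill-predicted rate at the assay's F6P concentration, floors
#: set by the stated depth of ATP inhibition (>80% for PFKL, >90% for
#: PFKM constructs).
KINETIC_EXPERIMENTS = {
    # K_M,F6P of wild-type PFKL and of the triple effector-pocket mutant
    "km_f6p_pfkl_wildtype": _hill_case(13.28, 1.97, 3.16, n_det=7),
    "km_f6p_pfkl_3mut": _hill_case(17.36, 0.57, 3.07, n_det=6),
    # relief of ATP inhibition of wild-type PFKL (4 mM F6P -> ceiling ~12)
    "ec50_na11_pfkl": _activation_case(14.00, 12.0, 0.85, n_det=8),
    "ec50_ldc7559_pfkl": _activation_case(66.04, 12.0, 0.85, n_det=7),
    # NA-5 activation of the pocket-swap PFKM mutant (1 mM F6P -> ~3.9)
    "ec50_na5_pfkm_pocket": _activation_case(10.94, 3.9, 0.92, n_det=5),
    # cellular NETosis inhibition, one fit per donor
    "ic50_na11_netosis": _dose_response_case(4.0, n_det=3, c_lo=0.1, c_hi=1000.0),
    "ic50_palp1_netosis": _dose_response_case(271.0, n_det=3, c_lo=1.0, c_hi=10000.0),
}

_FITTERS = {"hill": fit_hill, "activation": fit_activation, "dose_response": fit_ic50}

_REPORT_ATTR = {"k_half": "k_half", "ec50": "ec50", "ic50": "ic50"}


def recover_kinetic_parameter(
    name: str, seed: int, noise_cv: float = 0.05, n_replicates: int = 3
) -> tuple[float, int]:
    """Simulate and refit one reference titration experiment.

    Returns ``(mean estimate over determinations, total data points)``.
    """
    case = KINETIC_EXPERIMENTS[name]
    fitter = _FITTERS[case["model"]]
    estimates = []
    n_points = 0
    for det in range(case["n_determinations"]):
        det_seed = int((seed * 1000 + det) % _SEED_MOD)
        df = simulate_kinetics(
            case["model"],
            case["params"],
            dict(x=case["x"], n_replicates=n_replicates, noise_cv=noise_cv),
            seed=det_seed,
        )
        if case["model"] == "hill":
            fit = fitter(df["conc"], df["response"])
        else:
            fit = fitter(df["conc"], df["response"])
        estimates.append(getattr(fit, _REPORT_ATTR[case["report"]]))
        n_points += len(df)
    return float(np.mean(estimates)), n_points


def recover_delta_tm(seed: int, n_proteins: int = 1000) -> tuple[float, int]:
    """Full TPP stage on the planted-target proteome; returns (ΔTm, n_proteins).

    One thermally shifted target (vehicle midpoint 55 °C, +4 °C under
    treatment) among ``n_proteins`` at default reporter noise; the PSM
    table passes the FDR and QC filters, per-temperature normalization
    and per-protein 4PL fitting before the target's ΔTm is read off.
    """
    config = SimConfig(seed=int(seed % _SEED_MOD), n_proteins=n_proteins, n_targets=1)
    truth = make_ground_truth(config)
    table, design = simulate_tpp(config, truth)
    table = qc_filter(fdr_filter(table))
    pq = normalize(summarize_to_protein(table), design, mode="tpp")
    shift = thermal_shift_table(pq, design)
    row = shift[shift["protein_id"] == truth[0].protein_id]
    if row.empty:
        raise RuntimeError("planted target lost during filtering")
    return float(row["delta_tm"].iloc[0]), n_proteins
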