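"""Synthetic PSM tables and kinetic assay data with known ground truth.

The generator emulates the statistical structure of the three
chemoproteomic arms of a dual target-deconvolution experiment:

* TPP — 16-channel design, 2 conditions x 8 temperatures (37-65 °C),
  per-channel reporter intensities following a 4PL melting curve;
* PISA — 10-channel design, 2 conditions x 5 replicates, each replicate
  a physical pool over 6 temperatures in the 44-58 °C window, so the
  expected intensity is the mean of the 4PL soluble fraction over the
  pooled temperatures;
* PAL pull-down — vehicle / probe / inactive-probe / probe+competitor
  conditions with replicates, condition means set by a planted
  enrichment and competition efficiency.

Reporter noise is multiplicative log-normal (mean 1, coefficient of
variation from config) — TMT intensity error is approximately
proportional to signal. A protein's total intensity is split across its
PSMs with Dirichlet shares to mimic heterogeneous peptide response
factors. Decoy PSMs with a lower score distribution are interleaved so
the target-decoy FDR filter downstream has something to estimate.

Everything is a pure function of (config, truth, seed): regeneration
with the same inputs is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import exp_decay, hill, log_logistic, log_logistic_desc, soluble_fraction

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Channel column prefix used throughout the PSM table dialect.
CHANNEL_PREFIX = "channel_"

PAL_CONDITIONS = ("vehicle", "probe", "inactive_probe", "probe_plus_competitor")


@dataclass
class QCFieldParams:
    """Distributions for the per-PSM quality-control fields."""

    isolation_beta: tuple[float, float] = (8.0, 2.0)
    peptide_length_range: tuple[int, int] = (6, 30)
    target_score: tuple[float, float] = (3.0, 0.5)  # mean, sd
    decoy_score: tuple[float, float] = (1.0, 0.5)


@dataclass
class GroundTruthProtein:
    """Planted truth for one protein across all three arms."""

    protein_id: str
    tm_vehicle: float  # °C, 4PL midpoint under vehicle
    delta_tm: float = 0.0  # °C, treated − vehicle midpoint (0 for non-targets)
    base_abundance: float = 1e6  # arbitrary intensity units
    n_psms: int = 4
    pal_enrichment: float = 1.0  # probe / vehicle fold (1 = non-binder)
    competition_efficiency: float = 0.0  # fraction of probe labeling lost
    inactive_probe_enrichment: float = 1.0  # ~1 for true targets
    melt_scale: float = 2.0  # °C, 4PL slope parameter
    melt_floor: float = 0.05  # non-melting plateau as fraction of base

    def __post_init__(self):
        if self.n_psms < 1:
            raise ValueError(f"{self.protein_id}: n_psms must be >= 1")
        if not 0.0 <= self.competition_efficiency <= 1.0:
            raise ValueError(f"{self.protein_id}: competition_efficiency not in [0,1]")
        if self.melt_floor < 0.02:
            raise ValueError(f"{self.protein_id}: melt_floor below the 2% floor")

    def tm(self, condition: str) -> float:
        return self.tm_vehicle + (self.delta_tm if condition == "treated" else 0.0)


def _default_tpp_temperatures() -> list[float]:
    return list(np.linspace(37.0, 65.0, 8))


def _default_pisa_temperatures() -> list[float]:
    return list(np.linspace(44.0, 58.0, 6))


@dataclass
class SimConfig:
    """All knobs of the simulator; ``seed`` fully determines output."""

    seed: int = 0
    n_proteins: int = 1000
    n_targets: int = 1
    tpp_temperatures: list[float] = field(default_factory=_default_tpp_temperatures)
    pisa_temperatures: list[float] = field(default_factory=_default_pisa_temperatures)
    pisa_replicates: int = 5
    pal_replicates_per_condition: int = 3
    reporter_noise_cv: float = 0.1
    decoy_fraction: float = 0.02
    qc_field_distributions: QCFieldParams = field(default_factory=QCFieldParams)

    def __post_init__(self):
        for name in ("tpp_temperatures", "pisa_temperatures"):
            temps = np.asarray(getattr(self, name), dtype=float)
            if len(temps) < 2 or not np.all(np.diff(temps) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        for name in ("reporter_noise_cv", "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not in [0,1]")
        if self.n_targets > self.n_proteins:
            raise ValueError("n_targets exceeds n_proteins")


def make_ground_truth(
    config: SimConfig,
    target_tm_vehicle: float = 55.0,
    target_delta_tm: float = 4.0,
    target_pal_enrichment: float = 8.0,
    target_competition_efficiency: float = 0.9,
    target_inactive_probe_enrichment: float = 1.0,
) -> list[GroundTruthProtein]:
    """Build a proteome with ``config.n_targets`` planted dual-evidence targets.

    The default planted target mirrors the package's reference fixture:
    a 4 °C thermal shift from a 55 °C vehicle midpoint, 8-fold probe
    enrichment, 90% competition and no inactive-probe labeling. Targets
    occupy the first ``n_targets`` protein ids; the manifest (the
    returned list itself) is the ground truth for recovery tests.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    n = config.n_proteins
    tms = np.clip(rng.normal(50.0, 4.0, size=n), 40.0, 60.0)
    bases = rng.lognormal(mean=np.log(1e6), sigma=0.7, size=n)
    n_psms = 1 + rng.poisson(3.0, size=n)
    scales = rng.uniform(1.0, 2.5, size=n)
    floors = rng.uniform(0.02, 0.08, size=n)
    truth = []
    for i in range(n):
        is_target = i < config.n_targets
        truth.append(
            GroundTruthProtein(
                protein_id=f"PROT{i + 1:05d}",
                tm_vehicle=target_tm_vehicle if is_target else float(tms[i]),
                delta_tm=target_delta_tm if is_target else 0.0,
                base_abundance=2e6 if is_target else float(bases[i]),
                n_psms=8 if is_target else int(n_psms[i]),
                pal_enrichment=target_pal_enrichment if is_target else 1.0,
                competition_efficiency=(
                    target_competition_efficiency if is_target else 0.0
                ),
                inactive_probe_enrichment=(
                    target_inactive_probe_enrichment if is_target else 1.0
                ),
                melt_scale=1.0 if is_target else float(scales[i]),
                melt_floor=0.02 if is_target else float(floors[i]),
            )
        )
    return truth


def _noise_factors(rng, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-normal factors with the given CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _random_peptides(rng, lengths) -> list[str]:
    return ["".join(rng.choice(_AMINO_ACIDS, size=int(k))) for k in lengths]


def _assemble_table(rows: list[dict], n_channels: int) -> pd.DataFrame:
    cols = [
        "psm_id",
        "protein_id",
        "peptide",
        "peptide_length",
        "decoy",
        "score",
        "isolation_specificity",
        "total_intensity",
    ] + [f"{CHANNEL_PREFIX}{i + 1:03d}" for i in range(n_channels)]
    return pd.DataFrame(rows, columns=cols)


def _simulate_arm(config: SimConfig, truth, condition_fraction, n_channels, stream):
    """Shared PSM-table machinery for the three proteomic arms.

    ``condition_fraction(protein) -> ndarray of length n_channels`` gives
    the expected relative abundance per channel (the arm-specific part);
    everything else — Dirichlet PSM shares, log-normal reporter noise,
    QC fields, decoy rows — is common.
    """
    rng = np.random.default_rng([int(config.seed), stream])
    qc = config.qc_field_distributions
    lo, hi = qc.peptide_length_range
    rows: list[dict] = []
    psm_counter = 0
    for prot in truth:
        shares = rng.dirichlet(np.full(prot.n_psms, 2.0))
        fractions = condition_fraction(prot)  # length n_channels
        lengths = rng.integers(lo, hi + 1, size=prot.n_psms)
        peptides = _random_peptides(rng, lengths)
        iso = rng.beta(*qc.isolation_beta, size=prot.n_psms)
        scores = rng.normal(*qc.target_score, size=prot.n_psms)
        noise = _noise_factors(rng, config.reporter_noise_cv, (prot.n_psms, n_channels))
        intens = prot.base_abundance * shares[:, None] * fractions[None, :] * noise
        for j in range(prot.n_psms):
            psm_counter += 1
            row = {
                "psm_id": f"PSM{stream}{psm_counter:07d}",
                "protein_id": prot.protein_id,
                "peptide": peptides[j],
                "peptide_length": int(lengths[j]),
                "decoy": False,
                "score": float(scores[j]),
                "isolation_specificity": float(iso[j]),
                "total_intensity": float(intens[j].sum()),
            }
            for c in range(n_channels):
                row[f"{CHANNEL_PREFIX}{c + 1:03d}"] = float(intens[j, c])
            rows.append(row)

    # Decoys: decoy_fraction of ALL emitted rows, generic intensity structure.
    n_target_rows = len(rows)
    if config.decoy_fraction > 0 and n_target_rows:
        n_decoys = int(
            round(config.decoy_fraction * n_target_rows / (1 - config.decoy_fraction))
        )
        lengths = rng.integers(lo, hi + 1, size=n_decoys)
        peptides = _random_peptides(rng, lengths)
        iso = rng.beta(*qc.isolation_beta, size=n_decoys)
        scores = rng.normal(*qc.decoy_score, size=n_decoys)
        bases = rng.lognormal(mean=np.log(2e5), sigma=0.7, size=n_decoys)
        noise = _noise_factors(rng, config.reporter_noise_cv, (n_decoys, n_channels))
        for j in range(n_decoys):
            psm_counter += 1
            intens = bases[j] / n_channels * noise[j]
            row = {
                "psm_id": f"PSM{stream}{psm_counter:07d}",
                "protein_id": f"DECOY{j + 1:05d}",
                "peptide": peptides[j],
                "peptide_length": int(lengths[j]),
                "decoy": True,
                "score": float(scores[j]),
                "isolation_specificity": float(iso[j]),
                "total_intensity": float(intens.sum()),
            }
            for c in range(n_channels):
                row[f"{CHANNEL_PREFIX}{c + 1:03d}"] = float(intens[c])
            rows.append(row)
    return _assemble_table(rows, n_channels)


def simulate_tpp(config: SimConfig, truth: list[GroundTruthProtein]):
    """Simulate the full-melting-curve arm.

    Returns ``(psm_table, design)`` where design maps channel name to
    ``{"condition", "temperature"}``. Vehicle channels come first in
    temperature order, then treated.
    """
    temps = np.asarray(config.tpp_temperatures, dtype=float)
    n_channels = 2 * len(temps)
    design = {}
    conditions = []
    for i, cond in enumerate(("vehicle", "treated")):
        for j, t in enumerate(temps):
            ch = f"{CHANNEL_PREFIX}{i * len(temps) + j + 1:03d}"
            design[ch] = {"condition": cond, "temperature": float(t)}
            conditions.append(cond)

    def fractions(prot: GroundTruthProtein) -> np.ndarray:
        return np.concatenate(
            [
                soluble_fraction(temps, prot.tm(cond), prot.melt_scale, prot.melt_floor)
                for cond in ("vehicle", "treated")
            ]
        )

    table = _simulate_arm(config, truth, fractions, n_channels, stream=1)
    return table, design


def pooled_fraction(prot: GroundTruthProtein, temps, condition: str) -> float:
    """Expected PISA pooled soluble fraction: mean 4PL over the pooled temps."""
    temps = np.asarray(temps, dtype=float)
    return float(
        np.mean(soluble_fraction(temps, prot.tm(condition), prot.melt_scale, prot.melt_floor))
    )


def simulate_pisa(config: SimConfig, truth: list[GroundTruthProtein]):
    """Simulate the pooled-temperature (PISA) arm: 2 x pisa_replicates channels."""
    n_rep = config.pisa_replicates
    n_channels = 2 * n_rep
    design = {}
    for i, cond in enumerate(("vehicle", "treated")):
        for r in range(n_rep):
            ch = f"{CHANNEL_PREFIX}{i * n_rep + r + 1:03d}"
            design[ch] = {"condition": cond, "replicate": r + 1}

    def fractions(prot: GroundTruthProtein) -> np.ndarray:
        per_cond = [
            pooled_fraction(prot, config.pisa_temperatures, cond)
            for cond in ("vehicle", "treated")
        ]
        return np.repeat(per_cond, n_rep)

    table = _simulate_arm(config, truth, fractions, n_channels, stream=2)
    return table, design


def pal_condition_means(prot: GroundTruthProtein) -> dict[str, float]:
    """Expected relative abundance per pull-down condition."""
    e, c = prot.pal_enrichment, prot.competition_efficiency
    return {
        "vehicle": 1.0,
        "probe": e,
        "inactive_probe": prot.inactive_probe_enrichment,
        "probe_plus_competitor": 1.0 + (e - 1.0) * (1.0 - c),
    }


def simulate_pal(config: SimConfig, truth: list[GroundTruthProtein]):
    """Simulate the photoaffinity pull-down arm (4 conditions x replicates)."""
    n_rep = config.pal_replicates_per_condition
    n_channels = len(PAL_CONDITIONS) * n_rep
    design = {}
    for i, cond in enumerate(PAL_CONDITIONS):
        for r in range(n_rep):
            ch = f"{CHANNEL_PREFIX}{i * n_rep + r + 1:03d}"
            design[ch] = {"condition": cond, "replicate": r + 1}

    def fractions(prot: GroundTruthProtein) -> np.ndarray:
        means = pal_condition_means(prot)
        return np.repeat([means[c] for c in PAL_CONDITIONS], n_rep)

    table = _simulate_arm(config, truth, fractions, n_channels, stream=3)
    return table, design


_KINETIC_MODELS = {
    "hill": (hill, ("vmax", "k_half", "h"), "conc"),
    "activation": (log_logistic, ("floor", "ceiling", "ec50", "h"), "conc"),
    "dose_response": (log_logistic_desc, ("floor", "ceiling", "ic50", "h"), "conc"),
    "decay": (exp_decay, ("a0", "k"), "time"),
}


def simulate_kinetics(model: str, params: dict, design: dict, seed: int) -> pd.DataFrame:
    """Generative twin of the kinetics fitters.

    Parameters
    ----------
    model
        One of ``hill`` (F6P saturation), ``activation`` (ascending
        log-logistic relief of ATP inhibition), ``dose_response``
        (descending log-logistic, e.g. % NETosis vs inhibitor) or
        ``decay`` (first-order thermal inactivation).
    params
        Model parameters; keys per model:
        hill: vmax, k_half, h — activation: floor, ceiling, ec50, h —
        dose_response: floor, ceiling, ic50, h — decay: a0, k.
    design
        ``{"x": [...], "n_replicates": int, "noise_cv": float}`` where x
        is concentration (hill: mM; activation/dose_response: nM) or
        time (decay: min).

    Responses are ``model(x) * (1 + N(0, noise_cv))``, seed-deterministic.
    """
    if model not in _KINETIC_MODELS:
        raise ValueError(f"unknown kinetic model {model!r}")
    fn, names, xname = _KINETIC_MODELS[model]
    missing = [k for k in names if k not in params]
    if missing:
        raise ValueError(f"model {model!r} missing parameters {missing}")
    x = np.asarray(design["x"], dtype=float)
    n_rep = int(design.get("n_replicates", 1))
    cv = float(design.get("noise_cv", 0.0))
    if model == "decay":
        mean = fn(x, params["a0"], params["k"])
    elif model == "hill":
        mean = fn(x, params["vmax"], params["k_half"], params["h"])
    elif model == "activation":
        mean = fn(x, params["floor"], params["ceiling"], params["ec50"], params["h"])
    else:
        mean = fn(x, params["floor"], params["ceiling"], params["ic50"], params["h"])
    rng = np.random.default_rng([int(seed), 4])
    rows = []
    for r in range(n_rep):
        noise = rng.normal(0.0, cv, size=len(x)) if cv > 0 else np.zeros(len(x))
        resp = mean * (1.0 + noise)
        for xi, yi in zip(x, resp):
            rows.append({xname: float(xi), "replicate": r + 1, "response": float(yi)})
    return pd.DataFrame(rows, columns=[xname, "replicate", "response"])
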