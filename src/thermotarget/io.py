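"""On-disk formats, run configuration and the end-to-end pipeline.

Tables travel as TSV in the dialect emitted by the simulator
(``psm_id, protein_id, peptide, peptide_length, decoy, score,
isolation_specificity, total_intensity, channel_001...``); channel
designs and manifests are JSON; run configuration round-trips through
YAML with unknown keys rejected. All randomness flows from
``RunConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .integrate import IntegrationConfig, call_targets
from .melt import thermal_shift_table
from .pisa import pisa_differential
from .psm import (
    ProteinQuantTable,
    fdr_filter,
    normalize,
    qc_filter,
    summarize_to_protein,
)
from .pulldown import pulldown_differential
from .synthetic import (
    CHANNEL_PREFIX,
    SimConfig,
    make_ground_truth,
    simulate_pal,
    simulate_pisa,
    simulate_tpp,
)

logger = logging.getLogger("thermotarget")

REQUIRED_COLUMNS = (
    "psm_id",
    "protein_id",
    "peptide",
    "peptide_length",
    "decoy",
    "score",
    "isolation_specificity",
    "total_intensity",
)

ALL_STAGES = ("tpp", "pisa", "pal", "integrate")


def read_psm_table(path) -> pd.DataFrame:
    """Read a PSM TSV, validating the header and intensity sign."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    channels = [c for c in table.columns if c.startswith(CHANNEL_PREFIX)]
    if not channels:
        raise ValueError(f"{path}: no {CHANNEL_PREFIX}* columns found")
    if len(table):
        table["decoy"] = table["decoy"].astype(bool)
        vals = table[channels].to_numpy(dtype=float)
        bad = np.nonzero((vals < 0).any(axis=1))[0]
        if len(bad):
            raise ValueError(
                f"{path}: negative reporter intensity at row index {int(bad[0])}"
            )
    return table


def write_psm_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_design(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_design(design: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(design, fh, indent=1, sort_keys=True)


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    seed: int = 0
    n_proteins: int = 1000
    n_targets: int = 1
    reporter_noise_cv: float = 0.1
    decoy_fraction: float = 0.02
    fdr_level: float = 0.02
    min_total_intensity: float = 30_000.0
    min_isolation_specificity: float = 0.7
    min_peptide_length: int = 7
    target_tm_vehicle: float = 55.0
    target_delta_tm: float = 4.0
    target_pal_enrichment: float = 8.0
    target_competition_efficiency: float = 0.9
    stages: tuple = ALL_STAGES
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown RunConfig key(s): {sorted(unknown)}")
        if "integration" in raw and isinstance(raw["integration"], dict):
            iknown = {f.name for f in dataclasses.fields(IntegrationConfig)}
            iunknown = set(raw["integration"]) - iknown
            if iunknown:
                raise ValueError(f"unknown integration key(s): {sorted(iunknown)}")
            raw["integration"] = IntegrationConfig(**raw["integration"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        blob = json.dumps(data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sim_config(config: RunConfig) -> SimConfig:
    return SimConfig(
        seed=config.seed,
        n_proteins=config.n_proteins,
        n_targets=config.n_targets,
        reporter_noise_cv=config.reporter_noise_cv,
        decoy_fraction=config.decoy_fraction,
    )


def process_psm_table(table: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """FDR + QC filtering with per-stage row accounting in the log."""
    n0 = len(table)
    table = fdr_filter(table, fdr_level=config.fdr_level)
    n1 = len(table)
    table = qc_filter(
        table,
        min_total_intensity=config.min_total_intensity,
        min_isolation_specificity=config.min_isolation_specificity,
        min_peptide_length=config.min_peptide_length,
    )
    logger.info("PSM filters: %d rows -> %d after FDR -> %d after QC", n0, n1, len(table))
    return table


def _summarize(table: pd.DataFrame, design: dict, mode: str) -> ProteinQuantTable:
    pq = summarize_to_protein(table)
    return normalize(pq, design, mode=mode)


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Simulate, process and integrate all requested stages.

    Returns a results bundle (dict of DataFrames plus the truth
    manifest). When ``out_dir`` is given every artifact is written
    alongside a manifest carrying the package version, seed and a
    config hash; identical config implies identical outputs.
    """
    stages = tuple(config.stages)
    bad = set(stages) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stage(s): {sorted(bad)}")
    sim = _sim_config(config)
    truth = make_ground_truth(
        sim,
        target_tm_vehicle=config.target_tm_vehicle,
        target_delta_tm=config.target_delta_tm,
        target_pal_enrichment=config.target_pal_enrichment,
        target_competition_efficiency=config.target_competition_efficiency,
    )
    results: dict = {
        "truth": truth,
        "target_ids": [p.protein_id for p in truth if p.delta_tm != 0 or p.pal_enrichment != 1],
    }

    current = None
    try:
        if "tpp" in stages:
            current = "tpp"
            table, design = simulate_tpp(sim, truth)
            table = process_psm_table(table, config)
            pq = _summarize(table, design, mode="tpp")
            results["shift_table"] = thermal_shift_table(pq, design)
        if "pisa" in stages:
            current = "pisa"
            table, design = simulate_pisa(sim, truth)
            table = process_psm_table(table, config)
            pq = _summarize(table, design, mode="global")
            results["pisa_results"] = pisa_differential(pq, design)
        if "pal" in stages:
            current = "pal"
            table, design = simulate_pal(sim, truth)
            table = process_psm_table(table, config)
            pq = _summarize(table, design, mode="global")
            results["pulldown_results"] = pulldown_differential(pq, design)
        if "integrate" in stages:
            current = "integrate"
            needed = {"shift_table", "pisa_results", "pulldown_results"}
            if not needed <= set(results):
                raise ValueError(
                    "integrate stage requires tpp, pisa and pal stages"
                )
            results["target_calls"] = call_targets(
                results["shift_table"],
                results["pisa_results"],
                results["pulldown_results"],
                config.integration,
            )
    except Exception as err:
        if out_dir is not None:
            _write_bundle(results, config, Path(out_dir), failed_stage=current)
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err

    if out_dir is not None:
        _write_bundle(results, config, Path(out_dir), failed_stage=None)
    return results


def _write_bundle(results: dict, config: RunConfig, out_dir: Path, failed_stage):
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("shift_table", "pisa_results", "pulldown_results", "target_calls"):
        if name in results:
            path = out_dir / f"{name}.tsv"
            results[name].to_csv(path, sep="\t", index=False)
            written.append(path.name)
    truth_path = out_dir / "truth_manifest.json"
    with open(truth_path, "w") as fh:
        json.dump(
            [dataclasses.asdict(p) for p in results.get("truth", [])], fh, indent=1
        )
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": list(config.stages),
        "thresholds": config.integration.as_dict(),
        "artifacts": written + [truth_path.name],
        "failed_stage": failed_stage,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
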