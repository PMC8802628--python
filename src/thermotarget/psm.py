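"""PSM-level quality filtering and protein-level summarization.

The filtering contract follows standard TMT practice for thermal
profiling data: PSMs are kept only when total reporter intensity exceeds
30,000, isolation specificity exceeds 0.7 and the peptide is at least 7
residues long; identification confidence is controlled by a classic
target-decoy q-value threshold at 2% FDR. Surviving PSMs are log2
transformed and summarized per protein and channel by the median, then
channel medians are aligned (per temperature for the melting-curve
design, globally otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CHANNEL_PREFIX

_QC_COLUMNS = ("total_intensity", "isolation_specificity", "peptide_length")
_FDR_COLUMNS = ("decoy", "score")


def channel_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith(CHANNEL_PREFIX)]


def _require_columns(table: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"PSM table is missing required column(s): {missing}")


def fdr_filter(table: pd.DataFrame, fdr_level: float = 0.02) -> pd.DataFrame:
    """Retain target PSMs above a target-decoy score threshold.

    The threshold is the smallest score ``s`` such that
    ``#{decoys with score >= s} / #{targets with score >= s} <= fdr_level``;
    decoy rows are then removed.

    Raises
    ------
    ValueError
        If the table carries no decoy rows (the threshold is undefined)
        or no target rows.
    """
    _require_columns(table, _FDR_COLUMNS)
    decoy = table["decoy"].astype(bool)
    if not decoy.any():
        raise ValueError("no decoy PSMs present: FDR threshold is undefined")
    if decoy.all():
        raise ValueError("all PSMs are decoys: FDR threshold is undefined")
    scores = table["score"].to_numpy(dtype=float)
    order = np.argsort(scores)  # ascending candidate thresholds
    sorted_scores = scores[order]
    sorted_decoy = decoy.to_numpy()[order]
    n = len(scores)
    # Counting from the top: cum decoys/targets with score >= s.
    decoys_above = np.cumsum(sorted_decoy[::-1])[::-1]
    targets_above = np.arange(n, 0, -1) - decoys_above
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(targets_above > 0, decoys_above / targets_above, np.inf)
    ok = np.nonzero(fdr <= fdr_level)[0]
    if len(ok) == 0:
        # No threshold controls FDR; return an empty table with the schema.
        return table.iloc[0:0].copy()
    threshold = sorted_scores[ok[0]]
    keep = (scores >= threshold) & ~decoy.to_numpy()
    return table.loc[keep].copy()


def qc_filter(
    table: pd.DataFrame,
    min_total_intensity: float = 30_000.0,
    min_isolation_specificity: float = 0.7,
    min_peptide_length: int = 7,
) -> pd.DataFrame:
    """Apply the reporter-intensity / isolation-specificity / length gates.

    A row survives iff ``total_intensity > min_total_intensity`` AND
    ``isolation_specificity > min_isolation_specificity`` AND
    ``peptide_length >= min_peptide_length`` (inequality strictness is
    part of the contract).
    """
    _require_columns(table, _QC_COLUMNS)
    keep = (
        (table["total_intensity"] > min_total_intensity)
        & (table["isolation_specificity"] > min_isolation_specificity)
        & (table["peptide_length"] >= min_peptide_length)
    )
    return table.loc[keep].copy()


@dataclass
class ProteinQuantTable:
    """Protein x channel matrix of log2 abundance plus PSM accounting."""

    log2_abundance: pd.DataFrame  # index protein_id, columns channel_*
    n_psms: pd.Series  # PSMs contributing per protein
    n_dropped_proteins: int = 0  # proteins lost to all-zero channels

    def copy(self) -> "ProteinQuantTable":
        return ProteinQuantTable(
            self.log2_abundance.copy(), self.n_psms.copy(), self.n_dropped_proteins
        )


def summarize_to_protein(table: pd.DataFrame) -> ProteinQuantTable:
    """Median log2 reporter intensity per protein per channel.

    Zero (or negative) intensities become missing cells rather than
    -inf; proteins whose channels are all missing are dropped and
    counted. Decoy rows, if any survive upstream, are excluded.
    """
    _require_columns(table, ("protein_id",))
    channels = channel_columns(table)
    if not channels:
        raise ValueError("PSM table has no channel_* columns")
    work = table
    if "decoy" in table.columns and table["decoy"].astype(bool).any():
        work = table.loc[~table["decoy"].astype(bool)]
    values = work[channels].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.where(values > 0, np.log2(np.where(values > 0, values, 1.0)), np.nan)
    log2df = pd.DataFrame(log2, columns=channels, index=work.index)
    log2df["protein_id"] = work["protein_id"].to_numpy()
    grouped = log2df.groupby("protein_id", sort=True)
    medians = grouped[channels].median()
    n_psms = grouped.size().rename("n_psms")
    all_missing = medians.isna().all(axis=1)
    dropped = int(all_missing.sum())
    medians = medians.loc[~all_missing]
    n_psms = n_psms.loc[medians.index]
    return ProteinQuantTable(medians, n_psms, n_dropped_proteins=dropped)


def _temperature_pairs(design: dict) -> dict[float, dict[str, list[str]]]:
    """Group channels by temperature then condition (TPP designs)."""
    by_temp: dict[float, dict[str, list[str]]] = {}
    for ch, meta in design.items():
        t = float(meta["temperature"])
        by_temp.setdefault(t, {}).setdefault(meta["condition"], []).append(ch)
    return by_temp


def normalize(
    pq: ProteinQuantTable, design: dict, mode: str = "global"
) -> ProteinQuantTable:
    """Align channel medians to remove systematic labeling variation.

    ``mode="tpp"``: for each temperature, the treated channels are
    shifted so their cross-protein median matches the vehicle median at
    that temperature (condition medians coincide per temperature).

    ``mode="global"``: every channel is shifted so its median equals the
    median of all channel medians.

    Both modes are idempotent.
    """
    out = pq.copy()
    df = out.log2_abundance
    if mode == "global":
        col_medians = df.median(axis=0)
        grand = float(col_medians.median())
        out.log2_abundance = df + (grand - col_medians)
    elif mode == "tpp":
        for _, groups in _temperature_pairs(design).items():
            if "vehicle" not in groups:
                continue
            ref = float(df[groups["vehicle"]].stack().median())
            for cond, chans in groups.items():
                if cond == "vehicle":
                    continue
                med = float(df[chans].stack().median())
                df[chans] = df[chans] + (ref - med)
        out.log2_abundance = df
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return out
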