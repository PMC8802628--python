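"""Quadrant-style integration of the thermal-shift and pull-down arms.

A protein is called a target only when both orthogonal lines of
evidence agree: a melting-temperature shift of at least
``min_delta_tm`` with acceptable curve quality, and a pull-down profile
that passes the competition call (probe-enriched, competed, not labeled
by the inactive probe). Because ΔTm (°C) and competition log2 fold
change have incommensurate units, the combined ranking score is the sum
of their per-arm z-scores across the quantified proteome, which makes
the ranking invariant to affine rescaling of either axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pulldown import competition_call


@dataclass
class IntegrationConfig:
    min_delta_tm: float = 2.0  # °C
    min_quality: float = 0.5
    min_probe_enrichment_log2: float = 1.0
    min_competition_log2: float = 1.0
    min_inactive_log2: float = 1.0
    alpha: float = 0.05

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _zscore(x: pd.Series) -> pd.Series:
    v = x.to_numpy(dtype=float)
    ok = np.isfinite(v)
    if ok.sum() < 2:
        return pd.Series(np.zeros(len(x)), index=x.index)
    mu, sd = v[ok].mean(), v[ok].std(ddof=0)
    if sd == 0:
        return pd.Series(np.zeros(len(x)), index=x.index)
    z = (v - mu) / sd
    z[~ok] = np.nan
    return pd.Series(z, index=x.index)


def call_targets(
    shift_table: pd.DataFrame,
    pisa_results: pd.DataFrame,
    pulldown_results: pd.DataFrame,
    config: IntegrationConfig | None = None,
) -> pd.DataFrame:
    """Rank proteins by combined dual-arm evidence and call targets.

    Returns one row per protein seen in any arm, sorted by
    ``combined_rank_score`` descending. ``called`` is True iff the
    protein is quantified in all arms, its ΔTm and quality score pass
    the thermal thresholds, and the pull-down competition call is True.
    Proteins covered by only some arms get ``coverage_flag`` and are
    never called.
    """
    config = config or IntegrationConfig()
    if shift_table.empty and pisa_results.empty and pulldown_results.empty:
        return pd.DataFrame(
            columns=[
                "protein_id", "delta_tm", "quality_score", "pisa_log2_fc",
                "pisa_p", "log2_probe_vs_competition", "p_probe_vs_competition",
                "combined_rank_score", "called", "coverage_flag",
            ]
        )
    shift = shift_table[
        ["protein_id", "delta_tm", "quality_score"]
    ].copy() if not shift_table.empty else pd.DataFrame(
        columns=["protein_id", "delta_tm", "quality_score"]
    )
    pisa = pisa_results[["protein_id", "log2_fc", "p_value"]].rename(
        columns={"log2_fc": "pisa_log2_fc", "p_value": "pisa_p"}
    ) if not pisa_results.empty else pd.DataFrame(
        columns=["protein_id", "pisa_log2_fc", "pisa_p"]
    )
    pal_cols = [
        "protein_id",
        "log2_probe_vs_vehicle", "p_probe_vs_vehicle",
        "log2_probe_vs_competition", "p_probe_vs_competition",
        "log2_probe_vs_inactive",
    ]
    pal = pulldown_results[pal_cols].copy() if not pulldown_results.empty else (
        pd.DataFrame(columns=pal_cols)
    )

    merged = shift.merge(pisa, on="protein_id", how="outer").merge(
        pal, on="protein_id", how="outer"
    )
    in_tpp = merged["protein_id"].isin(shift["protein_id"])
    in_pal = merged["protein_id"].isin(pal["protein_id"])
    in_pisa = merged["protein_id"].isin(pisa["protein_id"])
    coverage = np.where(
        in_tpp & in_pal & in_pisa,
        "",
        "partial_coverage",
    )
    merged["coverage_flag"] = coverage

    if not pulldown_results.empty:
        comp = competition_call(
            pulldown_results,
            min_probe_enrichment_log2=config.min_probe_enrichment_log2,
            min_competition_log2=config.min_competition_log2,
            min_inactive_log2=config.min_inactive_log2,
            alpha=config.alpha,
        )
        comp_map = merged["protein_id"].map(comp)
        merged["competition_called"] = (
            comp_map.where(comp_map.notna(), False).astype(bool)
        )
    else:
        merged["competition_called"] = False

    merged["called"] = (
        (merged["coverage_flag"] == "")
        & (merged["delta_tm"] >= config.min_delta_tm)
        & (merged["quality_score"] >= config.min_quality)
        & merged["competition_called"]
    )

    z_tm = _zscore(merged["delta_tm"])
    z_comp = _zscore(merged["log2_probe_vs_competition"])
    merged["combined_rank_score"] = (
        z_tm.fillna(0.0) + z_comp.fillna(0.0)
    )
    merged = merged.sort_values(
        "combined_rank_score", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    return merged
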