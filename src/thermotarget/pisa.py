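"""Differential soluble-abundance statistics for the pooled (PISA) design.

Each replicate channel is a physical pool over the 44-58 °C ladder, so
one log2 abundance per replicate approximates the area under the
protein's melting curve. Treated-vs-vehicle differences are tested per
protein with a Student's t test (equal-variance by default, Welch or
paired by option) on log2 protein abundances; fold changes are mean
differences on the log2 scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .psm import ProteinQuantTable


def _group_channels(design: dict, condition: str) -> list[str]:
    chans = [(meta.get("replicate", 0), ch) for ch, meta in design.items()
             if meta["condition"] == condition]
    return [ch for _, ch in sorted(chans)]


def pisa_differential(
    pq: ProteinQuantTable,
    design: dict,
    paired: bool = False,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-protein log2 fold change (treated − vehicle) and two-sided p value.

    Proteins quantified in both groups get one record each. With fewer
    than 2 replicates observed in either group the record is emitted
    with an undefined p value and a ``low_replicates`` flag. ``paired``
    pairs replicates by their design index (requires equal counts).
    """
    v_chans = _group_channels(design, "vehicle")
    t_chans = _group_channels(design, "treated")
    records = []
    for pid, row in pq.log2_abundance.iterrows():
        v = row[v_chans].to_numpy(dtype=float)
        t = row[t_chans].to_numpy(dtype=float)
        if paired:
            ok = np.isfinite(v) & np.isfinite(t)
            v, t = v[ok], t[ok]
        else:
            v, t = v[np.isfinite(v)], t[np.isfinite(t)]
        if len(v) == 0 or len(t) == 0:
            continue
        log2_fc = float(t.mean() - v.mean())
        n_v, n_t = len(v), len(t)
        flag = ""
        if n_v < 2 or n_t < 2:
            p = np.nan
            flag = "low_replicates"
        elif paired:
            if np.allclose(t - v, (t - v)[0]):
                p = 1.0 if np.allclose(t, v) else np.nan
            else:
                p = float(stats.ttest_rel(t, v).pvalue)
        else:
            if np.allclose(v, v[0]) and np.allclose(t, t[0]) and np.isclose(v[0], t[0]):
                p = 1.0  # identical constant groups
            else:
                p = float(stats.ttest_ind(t, v, equal_var=equal_var).pvalue)
        records.append(
            {
                "protein_id": pid,
                "log2_fc": log2_fc,
                "p_value": p,
                "n_vehicle": n_v,
                "n_treated": n_t,
                "flag": flag,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["protein_id", "log2_fc", "p_value", "n_vehicle", "n_treated", "flag"],
    )


def tpp_pisa_concordance(
    shift_table: pd.DataFrame,
    pisa_results: pd.DataFrame,
    min_quality: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Join the two thermal-stability readouts and rank-correlate them.

    Inner join on ``protein_id``; Spearman correlation of ΔTm vs PISA
    log2 fold change over proteins whose melting-curve quality score is
    at least ``min_quality`` (NaN when fewer than 3 such proteins).
    """
    joined = shift_table.merge(pisa_results, on="protein_id", how="inner")
    sel = joined[
        (joined["quality_score"] >= min_quality)
        & joined["delta_tm"].notna()
        & joined["log2_fc"].notna()
    ]
    if len(sel) < 3:
        return joined, float("nan")
    rho = stats.spearmanr(sel["delta_tm"], sel["log2_fc"]).statistic
    return joined, float(rho)
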