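"""Enrichment and competition statistics for the photoaffinity pull-down arm.

The design declares four conditions: vehicle, active probe, inactive
(control) probe, and probe co-incubated with excess parent compound.
A genuine high-affinity target is enriched by the active probe over
vehicle, lost under competition, and not labeled by the inactive probe.
All three pairwise contrasts are mean log2-abundance differences with
two-sided Student's t tests across replicates; "absent in the negative
controls" is operationalized as a log2-ratio threshold rather than
literal absence, since reporter intensities are rarely exactly zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .psm import ProteinQuantTable
from .synthetic import PAL_CONDITIONS

CONTRASTS = {
    "probe_vs_vehicle": ("probe", "vehicle"),
    "probe_vs_competition": ("probe", "probe_plus_competitor"),
    "probe_vs_inactive": ("probe", "inactive_probe"),
}


def _condition_channels(design: dict) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {c: [] for c in PAL_CONDITIONS}
    for ch, meta in design.items():
        cond = meta["condition"]
        if cond not in groups:
            raise ValueError(f"unknown pull-down condition {cond!r}")
        groups[cond].append(ch)
    return groups


def pulldown_differential(pq: ProteinQuantTable, design: dict) -> pd.DataFrame:
    """All three pairwise contrasts per protein.

    Returns one row per protein with per-condition mean log2 abundance,
    the three log2 ratios (differences of condition means) and their t
    test p values. Contrasts with fewer than 2 replicates on either side
    are flagged and carry NaN p values.
    """
    groups = _condition_channels(design)
    records = []
    for pid, row in pq.log2_abundance.iterrows():
        obs = {
            cond: row[chans].to_numpy(dtype=float)[
                np.isfinite(row[chans].to_numpy(dtype=float))
            ]
            for cond, chans in groups.items()
        }
        rec: dict = {"protein_id": pid}
        flags = []
        for cond in PAL_CONDITIONS:
            rec[f"mean_{cond}"] = float(obs[cond].mean()) if len(obs[cond]) else np.nan
        for name, (a, b) in CONTRASTS.items():
            xa, xb = obs[a], obs[b]
            if len(xa) == 0 or len(xb) == 0:
                rec[f"log2_{name}"] = np.nan
                rec[f"p_{name}"] = np.nan
                flags.append(f"missing:{name}")
                continue
            rec[f"log2_{name}"] = float(xa.mean() - xb.mean())
            if len(xa) < 2 or len(xb) < 2:
                rec[f"p_{name}"] = np.nan
                flags.append(f"low_replicates:{name}")
            elif np.allclose(xa, xa[0]) and np.allclose(xb, xb[0]):
                rec[f"p_{name}"] = 1.0 if np.isclose(xa[0], xb[0]) else np.nan
            else:
                rec[f"p_{name}"] = float(stats.ttest_ind(xa, xb, equal_var=True).pvalue)
        rec["flag"] = ";".join(flags)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def competition_call(
    results: pd.DataFrame,
    min_probe_enrichment_log2: float = 1.0,
    min_competition_log2: float = 1.0,
    min_inactive_log2: float = 1.0,
    alpha: float = 0.05,
) -> pd.Series:
    """Boolean specific-binder call per protein.

    Called iff probe-vs-vehicle enrichment and probe-vs-competition loss
    both exceed their log2 thresholds with significant t tests, and the
    active probe exceeds the inactive probe by ``min_inactive_log2``
    (the "absent in negative control" criterion).
    """
    if results.empty:
        return pd.Series(dtype=bool, name="called")
    called = (
        (results["log2_probe_vs_vehicle"] >= min_probe_enrichment_log2)
        & (results["p_probe_vs_vehicle"] < alpha)
        & (results["log2_probe_vs_competition"] >= min_competition_log2)
        & (results["p_probe_vs_competition"] < alpha)
        & (results["log2_probe_vs_inactive"] >= min_inactive_log2)
    )
    called = called.fillna(False).astype(bool)
    called.index = results["protein_id"].to_numpy()
    return called.rename("called")
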