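"""PSM filtering, summarization and normalization contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermotarget import fdr_filter, normalize, qc_filter, summarize_to_protein
from thermotarget.synthetic import SimConfig, make_ground_truth, simulate_tpp


def _psm_rows(rows):
    """Build a minimal PSM table from (total, iso, length, decoy, score) tuples."""
    recs = []
    for i, (total, iso, length, decoy, score) in enumerate(rows):
        recs.append(
            {
                "psm_id": f"P{i}",
                "protein_id": f"PROT{i:03d}",
                "peptide": "A" * length,
                "peptide_length": length,
                "decoy": decoy,
                "score": score,
                "isolation_specificity": iso,
                "total_intensity": total,
                "channel_001": total / 2,
                "channel_002": total / 2,
            }
        )
    return pd.DataFrame(recs)


QC_FIXTURE = [
    # (total_intensity, isolation_specificity, peptide_length) -> survives?
    (40_000, 0.8, 9, True),
    (40_000, 0.8, 7, True),
    (25_000, 0.9, 12, False),  # intensity not strictly above 30,000
    (40_000, 0.7, 12, False),  # isolation specificity not strictly above 0.7
    (40_000, 0.8, 6, False),  # peptide shorter than 7 residues
]


class TestQCFilter:
    def test_hand_fixture_thresholds_are_exact(self):
        table = _psm_rows([(t, i, l, False, 3.0) for t, i, l, _ in QC_FIXTURE])
        out = qc_filter(table)
        survivors = {f"P{j}" for j, (_, _, _, keep) in enumerate(QC_FIXTURE) if keep}
        assert set(out["psm_id"]) == survivors

    def test_row_permutation_invariance(self):
        table = _psm_rows([(t, i, l, False, 3.0) for t, i, l, _ in QC_FIXTURE])
        shuffled = table.sample(frac=1.0, random_state=7)
        out_a = qc_filter(table).sort_values("psm_id").reset_index(drop=True)
        out_b = qc_filter(shuffled).sort_values("psm_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(out_a, out_b)

    def test_empty_and_all_passing(self):
        table = _psm_rows([(40_000, 0.8, 9, False, 3.0)] * 5)
        assert len(qc_filter(table)) == 5
        assert len(qc_filter(table.iloc[0:0])) == 0

    def test_missing_field_rejects_table(self):
        table = _psm_rows([(40_000, 0.8, 9, False, 3.0)]).drop(
            columns=["isolation_specificity"]
        )
        with pytest.raises(ValueError, match="isolation_specificity"):
            qc_filter(table)


class TestFDRFilter:
    def test_targets_above_all_decoys_retained(self):
        """98 targets above 2 decoys at 2% FDR: 2/98 > 0.02 just above the
        lowest decoy, 1/98 <= 0.02 above the second, so all targets stay."""
        rows = [(50_000, 0.9, 10, False, 5.0 + i / 100) for i in range(98)]
        rows += [(50_000, 0.9, 10, True, 1.0), (50_000, 0.9, 10, True, 2.0)]
        out = fdr_filter(_psm_rows(rows), fdr_level=0.02)
        assert len(out) == 98
        assert not out["decoy"].any()

    def test_fdr_level_one_keeps_all_targets(self):
        rows = [(50_000, 0.9, 10, False, float(i)) for i in range(10)]
        rows += [(50_000, 0.9, 10, True, 100.0)]  # decoy above everything
        out = fdr_filter(_psm_rows(rows), fdr_level=1.0)
        assert len(out) == 10

    def test_no_decoys_or_all_decoys_error(self):
        with pytest.raises(ValueError, match="no decoy"):
            fdr_filter(_psm_rows([(1, 0.9, 9, False, 1.0)]))
        with pytest.raises(ValueError, match="all PSMs are decoys"):
            fdr_filter(_psm_rows([(1, 0.9, 9, True, 1.0)]))

    def test_filter_order_independence(self):
        from thermotarget.synthetic import QCFieldParams

        config = SimConfig(
            seed=5,
            n_proteins=30,
            decoy_fraction=0.1,
            qc_field_distributions=QCFieldParams(
                target_score=(5.0, 0.3), decoy_score=(1.0, 0.3)
            ),
        )
        table, _ = simulate_tpp(config, make_ground_truth(config))
        a = qc_filter(fdr_filter(table)).sort_values("psm_id").reset_index(drop=True)
        b = fdr_filter(qc_filter(table)).sort_values("psm_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestSummarize:
    def test_median_of_log2(self):
        table = _psm_rows([(40_000, 0.8, 9, False, 3.0)] * 3)
        table["protein_id"] = "PROTX"
        table["channel_001"] = [4.0, 8.0, 16.0]
        table["channel_002"] = [4.0, 8.0, 16.0]
        pq = summarize_to_protein(table)
        assert pq.log2_abundance.loc["PROTX", "channel_001"] == pytest.approx(3.0)
        assert pq.n_psms["PROTX"] == 3

    def test_single_psm_identity(self):
        table = _psm_rows([(40_000, 0.8, 9, False, 3.0)])
        pq = summarize_to_protein(table)
        assert pq.log2_abundance.iloc[0, 0] == pytest.approx(np.log2(20_000))

    def test_zero_intensity_becomes_missing_not_minus_inf(self):
        table = _psm_rows([(40_000, 0.8, 9, False, 3.0)])
        table["channel_001"] = 0.0
        pq = summarize_to_protein(table)
        assert np.isnan(pq.log2_abundance.iloc[0, 0])
        assert np.isfinite(pq.log2_abundance.iloc[0, 1])

    def test_row_order_invariance(self):
        config = SimConfig(seed=9, n_proteins=25)
        table, _ = simulate_tpp(config, make_ground_truth(config))
        pq_a = summarize_to_protein(table)
        pq_b = summarize_to_protein(table.sample(frac=1.0, random_state=3))
        pd.testing.assert_frame_equal(pq_a.log2_abundance, pq_b.log2_abundance)


class TestNormalize:
    @pytest.fixture
    def tpp_pq_design(self, small_config, small_truth):
        table, design = simulate_tpp(small_config, small_truth)
        return summarize_to_protein(table), design

    @pytest.mark.parametrize("mode", ["global", "tpp"])
    def test_idempotent(self, tpp_pq_design, mode):
        pq, design = tpp_pq_design
        once = normalize(pq, design, mode=mode)
        twice = normalize(once, design, mode=mode)
        pd.testing.assert_frame_equal(
            once.log2_abundance, twice.log2_abundance, rtol=1e-12
        )

    def test_constructed_offset_recovered(self, tpp_pq_design):
        pq, design = tpp_pq_design
        baseline = normalize(pq, design, mode="global")
        shifted = baseline.copy()
        shifted.log2_abundance["channel_003"] += 1.0
        renorm = normalize(shifted, design, mode="global")
        pd.testing.assert_frame_equal(
            renorm.log2_abundance, baseline.log2_abundance, rtol=1e-9
        )

    def test_tpp_mode_aligns_condition_medians_per_temperature(self, tpp_pq_design):
        pq, design = tpp_pq_design
        out = normalize(pq, design, mode="tpp")
        by_temp = {}
        for ch, meta in design.items():
            by_temp.setdefault(meta["temperature"], {})[meta["condition"]] = ch
        for temp, conds in by_temp.items():
            med_v = out.log2_abundance[conds["vehicle"]].median()
            med_t = out.log2_abundance[conds["treated"]].median()
            assert med_v == pytest.approx(med_t, abs=1e-9)

    def test_unknown_mode(self, tpp_pq_design):
        pq, design = tpp_pq_design
        with pytest.raises(ValueError, match="mode"):
            normalize(pq, design, mode="quantile")


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    totals=st.lists(
        st.floats(min_value=1.0, max_value=1e6, allow_nan=False), min_size=1, max_size=20
    ),
    iso=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
)
def test_qc_filter_is_a_pointwise_predicate(totals, iso):
    """Survival of a row never depends on the other rows."""
    rows = [(t, iso, 10, False, 3.0) for t in totals]
    table = _psm_rows(rows)
    out = qc_filter(table)
    expected = {
        f"P{i}" for i, t in enumerate(totals) if t > 30_000 and iso > 0.7
    }
    assert set(out["psm_id"]) == expected
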