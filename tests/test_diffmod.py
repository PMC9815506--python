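import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epidrs import io_tables
from epidrs.diffmod import (
    base_composition,
    coverage_filter,
    diffmod_scan,
    fisher_exact_2x2,
    log2fc_mod,
    pool_counts,
    transcript_mod_ratio,
)
from epidrs.io_tables import ModCallTable, ValidationError

from .oracles import fisher_oracle


def make_table(rows, condition_map=None):
    condition_map = condition_map or {"C1": "control", "C2": "control",
                                      "N1": "treated", "N2": "treated"}
    df = pd.DataFrame(rows, columns=io_tables.MODCALL_COLUMNS)
    return ModCallTable(df, condition_map, condition_order=("control", "treated"))


class TestPooling:
    def test_replicates_summed(self):
        table = make_table(
            [
                ("tx1", 0, "A", "C1", 20, 2),
                ("tx1", 0, "A", "C2", 30, 3),
                ("tx1", 0, "A", "N1", 25, 10),
                ("tx1", 0, "A", "N2", 25, 12),
            ]
        )
        pooled = pool_counts(table)
        row = pooled.iloc[0]
        assert (row["N_c"], row["m_c"]) == (50, 5)
        assert (row["N_t"], row["m_t"]) == (50, 22)

    def test_absent_condition_pooled_as_zero(self):
        table = make_table([("tx1", 0, "A", "C1", 20, 2)])
        pooled = pool_counts(table)
        assert pooled.iloc[0]["N_t"] == 0
        assert pooled.iloc[0]["m_t"] == 0

    def test_single_replicate_identity(self):
        table = make_table(
            [("tx1", 0, "A", "C1", 20, 2), ("tx1", 0, "A", "N1", 33, 7)],
            condition_map={"C1": "control", "N1": "treated"},
        )
        row = pool_counts(table).iloc[0]
        assert (row["N_c"], row["m_c"], row["N_t"], row["m_t"]) == (20, 2, 33, 7)

    def test_pooling_preserves_totals(self, small_bundle):
        pooled = pool_counts(small_bundle.modcalls)
        assert pooled["N_c"].sum() + pooled["N_t"].sum() == \
            small_bundle.modcalls.df["coverage"].sum()
        assert pooled["m_c"].sum() + pooled["m_t"].sum() == \
            small_bundle.modcalls.df["modified_count"].sum()


class TestCoverageFilter:
    @staticmethod
    def _pooled(rows):
        df = pd.DataFrame(rows, columns=["transcript_id", "position", "ref_base",
                                         "m_c", "N_c", "m_t", "N_t"])
        return df

    def test_one_low_condition_removed(self):
        pooled = self._pooled([("tx1", 0, "A", 5, 49, 20, 200)])
        assert len(coverage_filter(pooled, 50)) == 0

    def test_boundary_inclusive(self):
        pooled = self._pooled([("tx1", 0, "A", 5, 50, 20, 50)])
        assert len(coverage_filter(pooled, 50)) == 1

    def test_empty_input(self):
        pooled = self._pooled([])
        assert len(coverage_filter(pooled, 50)) == 0

    def test_min_cov_must_be_positive(self):
        with pytest.raises(ValidationError):
            coverage_filter(self._pooled([]), 0)


class TestFisher:
    def test_identical_columns_p_one(self):
        assert fisher_exact_2x2(10, 90, 10, 90) == 1.0

    def test_extreme_table_matches_enumeration(self):
        # all-or-nothing table with margins (10, 10, 10, 10)
        assert fisher_exact_2x2(0, 10, 10, 0) == pytest.approx(
            fisher_oracle(0, 10, 10, 0), abs=1e-12
        )

    def test_mixed_table_matches_enumeration(self):
        assert fisher_exact_2x2(5, 45, 25, 25) == pytest.approx(
            fisher_oracle(5, 45, 25, 25), abs=1e-9
        )

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(-1, 5, 5, 5)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(0, 0, 0, 0)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 40), st.integers(0, 40),
           st.integers(0, 40), st.integers(0, 40))
    def test_agrees_with_enumeration_oracle(self, m_c, u_c, m_t, u_t):
        if m_c + u_c + m_t + u_t == 0:
            return
        p = fisher_exact_2x2(m_c, u_c, m_t, u_t)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(fisher_oracle(m_c, u_c, m_t, u_t), abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 200), st.integers(0, 200),
           st.integers(0, 200), st.integers(0, 200))
    def test_agrees_with_scipy(self, m_c, u_c, m_t, u_t):
        from scipy.stats import fisher_exact

        if m_c + u_c + m_t + u_t == 0:
            return
        p_ref = fisher_exact([[m_c, m_t], [u_c, u_t]]).pvalue
        assert fisher_exact_2x2(m_c, u_c, m_t, u_t) == pytest.approx(
            p_ref, rel=1e-7, abs=1e-12
        )


class TestLog2FC:
    def test_closed_form_with_pseudocount(self):
        # (25 + .5)/(50 + 1) over (5 + .5)/(50 + 1) = 25.5/5.5
        assert log2fc_mod(5, 50, 25, 50) == pytest.approx(
            np.log2(25.5 / 5.5), abs=1e-12
        )
        assert log2fc_mod(5, 50, 25, 50) == pytest.approx(2.213, abs=5e-4)

    def test_zero_at_equality(self):
        assert log2fc_mod(7, 30, 7, 30) == 0.0

    def test_zero_depth_both_sides_rejected(self):
        with pytest.raises(ValidationError):
            log2fc_mod(0, 0, 0, 0)

    @settings(max_examples=100, deadline=None)
    @given(data=st.data())
    def test_antisymmetric_under_swap(self, data):
        N_c = data.draw(st.integers(1, 1000))
        N_t = data.draw(st.integers(1, 1000))
        m_c = data.draw(st.integers(0, N_c))
        m_t = data.draw(st.integers(0, N_t))
        assert log2fc_mod(m_c, N_c, m_t, N_t) == pytest.approx(
            -log2fc_mod(m_t, N_t, m_c, N_c), abs=1e-12
        )

    def test_finite_at_extremes(self):
        assert np.isfinite(log2fc_mod(0, 100, 100, 100))
        assert np.isfinite(log2fc_mod(100, 100, 0, 100))


class TestScan:
    def test_significant_over_call(self):
        # 10/100 vs 30/100: p ~ 6e-4, log2fc ~ 1.52 -> over
        table = make_table(
            [("tx1", 0, "A", "C1", 100, 10), ("tx1", 0, "A", "N1", 100, 30)],
            condition_map={"C1": "control", "N1": "treated"},
        )
        results = diffmod_scan(table)
        assert results.iloc[0]["status"] == "over"
        assert results.iloc[0]["p_value"] < 0.05
        assert results.iloc[0]["log2fc"] > 0.5

    def test_alpha_gate_blocks_large_lfc(self):
        # big fold change but tiny counts -> p above alpha -> ns
        table = make_table(
            [("tx1", 0, "A", "C1", 60, 0), ("tx1", 0, "A", "N1", 60, 3)],
            condition_map={"C1": "control", "N1": "treated"},
        )
        results = diffmod_scan(table)
        assert results.iloc[0]["p_value"] > 0.05
        assert abs(results.iloc[0]["log2fc"]) > 0.5
        assert results.iloc[0]["status"] == "ns"

    def test_lfc_gate_blocks_small_effect(self):
        # large counts, significant p, small fold change -> ns
        table = make_table(
            [("tx1", 0, "A", "C1", 4000, 1000), ("tx1", 0, "A", "N1", 4000, 1160)],
            condition_map={"C1": "control", "N1": "treated"},
        )
        results = diffmod_scan(table)
        assert results.iloc[0]["p_value"] < 0.05
        assert abs(results.iloc[0]["log2fc"]) < 0.5
        assert results.iloc[0]["status"] == "ns"

    def test_status_invariant(self, small_bundle):
        results = diffmod_scan(small_bundle.modcalls, min_cov=10)
        alpha, tau = 0.05, 0.5
        over = (results["p_value"] < alpha) & (results["log2fc"] > tau)
        under = (results["p_value"] < alpha) & (results["log2fc"] < -tau)
        assert ((results["status"] == "over") == over).all()
        assert ((results["status"] == "under") == under).all()
        # sign(log2fc) = sign(f_t - f_c)
        assert (np.sign(results["log2fc"]) ==
                np.sign(results["f_t"] - results["f_c"])).all()

    def test_invariant_to_sample_relabeling(self, small_bundle):
        table = small_bundle.modcalls
        df = table.df.copy()
        swap = {"control_1": "control_2", "control_2": "control_1"}
        df["sample_id"] = df["sample_id"].replace(swap)
        df = df.sample(frac=1.0, random_state=0)  # also shuffle row order
        relabeled = ModCallTable(df, table.condition_map,
                                 condition_order=table.conditions)
        a = diffmod_scan(table, min_cov=10).reset_index(drop=True)
        b = diffmod_scan(relabeled, min_cov=10).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_bh_adjustment_gates_on_q(self):
        rows = []
        # one strong effect among many nulls
        for i in range(40):
            rows.append((f"tx{i}", 0, "A", "C1", 100, 10))
            rows.append((f"tx{i}", 0, "A", "N1", 100, 30 if i == 0 else 10))
        table = make_table(rows, condition_map={"C1": "control", "N1": "treated"})
        raw = diffmod_scan(table)
        bh = diffmod_scan(table, adjust="bh")
        assert (bh["q_value"] >= bh["p_value"] - 1e-12).all()
        assert set(bh.columns) == set(raw.columns)

    def test_bad_adjust_rejected(self, small_bundle):
        with pytest.raises(ValidationError):
            diffmod_scan(small_bundle.modcalls, adjust="bonferroni")


class TestBaseComposition:
    def test_counting(self):
        comp = base_composition(["A", "A", "G", "U"])
        assert comp == {"A": 50.0, "C": 0.0, "G": 25.0, "U": 25.0}

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            base_composition([])

    def test_all_a(self):
        comp = base_composition(["A", "A"])
        assert comp["A"] == 100.0

    def test_sums_to_hundred(self, small_bundle):
        comp = base_composition(small_bundle.modcalls.df["ref_base"])
        assert sum(comp.values()) == pytest.approx(100.0, abs=1e-9)


class TestTranscriptModRatio:
    @staticmethod
    def _pooled(rows):
        df = pd.DataFrame(rows, columns=["transcript_id", "position", "ref_base",
                                         "m_c", "N_c", "m_t", "N_t"])
        df.attrs["conditions"] = ("control", "treated")
        return df

    def test_weighted_pooling(self):
        pooled = self._pooled(
            [("tx1", 0, "A", 5, 50, 0, 50), ("tx1", 1, "A", 15, 50, 0, 50)]
        )
        assert transcript_mod_ratio(pooled, "control")["tx1"] == pytest.approx(0.2)

    def test_boundary_fully_modified(self):
        pooled = self._pooled([("tx1", 0, "A", 50, 50, 0, 50)])
        assert transcript_mod_ratio(pooled, "control")["tx1"] == 1.0

    def test_boundary_unmodified(self):
        pooled = self._pooled([("tx1", 0, "A", 0, 50, 0, 50)])
        assert transcript_mod_ratio(pooled, "control")["tx1"] == 0.0

    def test_zero_coverage_transcript_omitted(self):
        pooled = self._pooled([("tx1", 0, "A", 0, 0, 5, 50)])
        assert "tx1" not in transcript_mod_ratio(pooled, "control").index
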