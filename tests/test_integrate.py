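import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

from epidrs.io_tables import AbundanceMatrix, ValidationError
from epidrs.integrate import (
    correlation_suite,
    cpm,
    expression_filter,
    log_abundance_by_condition,
    multiomics_overlap,
    pearson_with_p,
    read_significance_table,
)


def matrix(data, kind="counts"):
    return AbundanceMatrix(pd.DataFrame(data), kind=kind)


class TestCPM:
    def test_definition(self):
        mat = matrix({"S": [10, 90]})
        out = cpm(mat)
        assert out.values["S"].tolist() == [1e5, 9e5]
        assert out.kind == "cpm"

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        mat = matrix({f"S{i}": rng.integers(0, 1000, 50) + 1 for i in range(4)})
        out = cpm(mat)
        assert np.allclose(out.values.sum(axis=0), 1e6, atol=1e-6)

    def test_all_zero_row_stays_zero(self):
        out = cpm(matrix({"S": [0, 10]}))
        assert out.values["S"].iloc[0] == 0.0

    def test_zero_library_rejected(self):
        with pytest.raises(ValidationError, match="zero library"):
            cpm(matrix({"S": [0, 0]}))


class TestExpressionFilter:
    def test_boundary_inclusive(self):
        mat = matrix({f"S{i}": [v] for i, v in
                      enumerate([2.0, 2.0, 0, 0, 0, 0])}, kind="cpm")
        assert len(expression_filter(mat).values) == 1

    def test_single_qualifying_sample_dropped(self):
        mat = matrix({f"S{i}": [v] for i, v in
                      enumerate([5.0, 0, 0, 0, 0, 0])}, kind="cpm")
        assert len(expression_filter(mat).values) == 0

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(1)
        mat = matrix({f"S{i}": rng.uniform(0, 10, 20) for i in range(3)},
                     kind="cpm")
        out = expression_filter(mat, min_cpm=0)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_requires_cpm_kind(self):
        with pytest.raises(ValidationError):
            expression_filter(matrix({"S": [1]}, kind="counts"))

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0, 10), st.floats(0, 10))
    def test_monotone_in_threshold(self, t1, t2):
        lo, hi = sorted((t1, t2))
        rng = np.random.default_rng(42)
        mat = matrix({f"S{i}": rng.uniform(0, 10, 30) for i in range(4)},
                     kind="cpm")
        kept_hi = set(expression_filter(mat, min_cpm=hi).values.index)
        kept_lo = set(expression_filter(mat, min_cpm=lo).values.index)
        assert kept_hi <= kept_lo


class TestPearson:
    def test_perfect_linearity(self):
        res = pearson_with_p([1, 2, 3], [2, 4, 6])
        assert res.r == 1.0
        assert res.p_value == 0.0

    def test_perfect_anti_linearity(self):
        assert pearson_with_p([1, 2, 3], [3, 2, 1]).r == -1.0

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=50)
            y = 0.3 * x + rng.normal(size=50)
            res = pearson_with_p(x, y)
            ref = pearsonr(x, y)
            assert res.r == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)
            assert res.n == 50

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            pearson_with_p([1, 1, 1], [1, 2, 3])

    def test_nan_pairwise_removal(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, np.nan]
        res = pearson_with_p(x, y)
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError, match="n >= 3"):
            pearson_with_p([1, 2], [3, 4])

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(-10, 10), b=st.floats(0.1, 10),
        flip=st.booleans(), seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, a, b, flip, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = pearson_with_p(x, y).r
        scale = -b if flip else b
        transformed = pearson_with_p(a + scale * x, y).r
        expected = -base if flip else base
        assert transformed == pytest.approx(expected, abs=1e-9)


class TestOverlap:
    def test_worked_example(self):
        rep = multiomics_overlap({1, 2, 3}, {2, 3}, {3})
        assert rep.ab_only == 1
        assert rep.ac_only == 0
        assert rep.bc_only == 0
        assert rep.abc == 1
        assert rep.total_at_least_two == 2

    def test_disjoint_sets(self):
        rep = multiomics_overlap({1}, {2}, {3})
        assert rep.total_at_least_two == 0

    def test_identical_sets(self):
        rep = multiomics_overlap({1, 2}, {1, 2}, {1, 2})
        assert rep.abc == 2
        assert rep.ab_only == rep.ac_only == rep.bc_only == 0

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
        c=st.sets(st.integers(0, 30)),
    )
    def test_inclusion_exclusion(self, a, b, c):
        rep = multiomics_overlap(a, b, c)
        assert rep.total == len(a | b | c)
        assert (rep.ab_only + rep.abc) == len(a & b)
        assert (rep.ac_only + rep.abc) == len(a & c)
        assert (rep.bc_only + rep.abc) == len(b & c)
        assert rep.total_at_least_two == (
            rep.ab_only + rep.ac_only + rep.bc_only + rep.abc
        )


class TestSuite:
    @staticmethod
    def _layers(n=200, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"tx{i}" for i in range(n)])
        def series(vals):
            return pd.Series(vals, index=idx)
        x = rng.normal(size=n)
        layers = {}
        for cond in ("control", "treated"):
            layers.setdefault("mod", {})[cond] = series(0.05 + 0.01 * x)
            layers.setdefault("m6a", {})[cond] = series(0.05 + 0.01 * x)
            layers.setdefault("ab", {})[cond] = series(-x + rng.normal(size=n))
            layers.setdefault("pa", {})[cond] = series(91 + x + rng.normal(size=n))
        return layers

    def test_expected_pairs_present(self):
        L = self._layers()
        results = correlation_suite(L["mod"], L["m6a"], L["ab"], L["pa"])
        pairs = {(r.pair, r.condition) for r in results}
        assert (("mod_ratio", "log_abundance"), "control") in pairs
        assert (("polya_mean", "m6a_ratio"), "treated") in pairs
        # protein pairs absent without a protein layer
        assert not any("log_protein" in r.pair for r in results)

    def test_protein_requires_id_map(self):
        L = self._layers()
        with pytest.raises(ValidationError, match="id_map"):
            correlation_suite(L["mod"], L["m6a"], L["ab"], L["pa"],
                              log_protein={"control": L["ab"]["control"]})

    def test_permuted_ids_decorrelate(self):
        L = self._layers(n=500, seed=3)
        permuted = L["ab"]["control"].copy()
        rng = np.random.default_rng(9)
        permuted.index = permuted.index[rng.permutation(len(permuted))]
        res = correlation_suite(
            L["mod"], L["m6a"], {"control": permuted}, L["pa"]
        )
        for r in res:
            if r.pair[1] == "log_abundance":
                assert abs(r.r) < 0.15

    def test_too_few_common_features_skipped(self):
        L = self._layers(n=2)
        assert correlation_suite(L["mod"], L["m6a"], L["ab"], L["pa"]) == []


class TestSignificanceTable:
    def test_reads_flagged_ids(self, tmp_path):
        path = tmp_path / "sig.tsv"
        path.write_text(
            "feature_id\tp_or_fdr\tlogFC\tsignificant\n"
            "tx1\t0.01\t1.2\t1\ntx2\t0.5\t0.1\t0\n"
        )
        assert read_significance_table(path) == {"tx1"}


def test_log_abundance_by_condition():
    mat = matrix({"C1": [100, 0], "C2": [100, 0], "N1": [50, 50]})
    out = log_abundance_by_condition(
        cpm(mat), {"C1": "control", "C2": "control", "N1": "treated"}
    )
    assert out["control"].iloc[0] == pytest.approx(np.log2(1e6 + 1))
    assert out["treated"].iloc[0] == pytest.approx(np.log2(5e5 + 1))
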