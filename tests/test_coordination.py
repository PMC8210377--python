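import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txcoord.coordination import (
    CoordinationAnalysis,
    PcTable,
    compute_coexpression,
    drop_degenerate,
    pairwise_pc,
    pc_index,
    summarize_pc,
)
from txcoord.io import ExpressionMatrix, SampleMetadata, filter_expressed, log_cpm

from conftest import pearson_scalar


def expr_from(rows: dict[str, list[float]], units="log2cpm") -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df, units=units)


def random_coex(rng, n_genes, n_samples=9, group="G"):
    vals = rng.normal(size=(n_genes, n_samples))
    df = pd.DataFrame(vals, index=[f"g{i:02d}" for i in range(n_genes)],
                      columns=[f"s{i}" for i in range(n_samples)])
    return compute_coexpression(ExpressionMatrix(df, units="log2cpm"), group=group)


def pc_oracle(RA, RB, exclude_self=True):
    """Scalar double-loop Pc oracle, independent of the vectorized path."""
    G = RA.shape[0]
    out = []
    for g in range(G):
        cols = [j for j in range(G) if (j != g or not exclude_self)]
        a = [RA[g, j] for j in cols]
        b = [RB[g, j] for j in cols]
        out.append(pearson_scalar(a, b))
    return np.array(out)


class TestComputeCoexpression:
    def test_perfect_linear_pairs(self):
        expr = expr_from({"g1": [1, 2, 3, 4], "g2": [2, 4, 6, 8], "g3": [4, 3, 2, 1]})
        coex = compute_coexpression(expr, group="C")
        i = {g: k for k, g in enumerate(coex.gene_ids)}
        assert coex.R[i["g1"], i["g2"]] == pytest.approx(1.0, abs=1e-12)
        assert coex.R[i["g1"], i["g3"]] == pytest.approx(-1.0, abs=1e-12)
        assert np.all(np.diag(coex.R) == 1.0)

    def test_hand_computed_pearson(self):
        # cov 4.0, each sum of squared deviations 5.0 -> 4 / sqrt(25) = 0.8
        expr = expr_from({"g1": [1, 2, 3, 4], "g4": [1, 3, 2, 4]})
        coex = compute_coexpression(expr)
        assert coex.R[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_gene_listed_in_error(self):
        expr = expr_from({"flat": [5, 5, 5, 5], "g": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="flat"):
            compute_coexpression(expr)

    def test_fewer_than_three_samples_rejected(self):
        expr = expr_from({"g1": [1, 2], "g2": [2, 1]})
        with pytest.raises(ValueError, match=">= 3"):
            compute_coexpression(expr)

    def test_matches_scalar_pearson_oracle(self, rng):
        vals = rng.normal(size=(6, 7))
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(7)])
        coex = compute_coexpression(ExpressionMatrix(df, units="log2cpm"))
        for i in range(6):
            for j in range(6):
                expected = pearson_scalar(list(vals[i]), list(vals[j]))
                assert coex.R[i, j] == pytest.approx(expected, abs=1e-12)


class TestPcIndex:
    def test_self_comparison_is_exactly_one(self, rng):
        coex = random_coex(rng, 10)
        table = pc_index(coex, coex)
        assert np.all(table.pc == 1.0)
        assert table.n_profile == 9

    def test_sign_flipped_gene_gives_minus_one(self, rng):
        vals = rng.normal(size=(8, 9))
        ids = [f"g{i}" for i in range(8)]
        cols = [f"s{i}" for i in range(9)]
        a = compute_coexpression(
            ExpressionMatrix(pd.DataFrame(vals, index=ids, columns=cols), "log2cpm"), "A")
        flipped = vals.copy()
        flipped[3] = -flipped[3]
        b = compute_coexpression(
            ExpressionMatrix(pd.DataFrame(flipped, index=ids, columns=cols), "log2cpm"), "B")
        table = pc_index(a, b)
        assert table.pc[3] == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("exclude_self", [True, False])
    def test_matches_double_loop_oracle_20_genes(self, rng, exclude_self):
        a = random_coex(rng, 20, group="A")
        b = random_coex(rng, 20, group="B")
        table = pc_index(a, b, exclude_self=exclude_self)
        expected = pc_oracle(a.R, b.R, exclude_self=exclude_self)
        assert np.allclose(table.pc, expected, atol=1e-10)

    def test_symmetric_in_arguments(self, rng):
        a = random_coex(rng, 12, group="A")
        b = random_coex(rng, 12, group="B")
        assert np.array_equal(pc_index(a, b).pc, pc_index(b, a).pc)

    def test_computed_on_gene_intersection(self, rng):
        a = random_coex(rng, 10, group="A")
        b = random_coex(rng, 10, group="B")
        b_sub_ids = b.gene_ids[2:]
        keep = np.arange(2, 10)
        from txcoord.coordination import CoexpressionMatrix
        b_sub = CoexpressionMatrix(b_sub_ids, b.R[np.ix_(keep, keep)], "B", b.n_samples)
        table = pc_index(a, b_sub)
        assert table.gene_ids == a.gene_ids[2:]
        assert table.n_profile == 7

    def test_tiny_intersection_rejected(self, rng):
        a = random_coex(rng, 4, group="A")
        from txcoord.coordination import CoexpressionMatrix
        b = CoexpressionMatrix(["g00", "g01", "x", "y"], random_coex(rng, 4).R, "B", 9)
        with pytest.raises(ValueError, match="common"):
            pc_index(a, b)

    def test_permuting_gene_order_permutes_pc_consistently(self, rng):
        a = random_coex(rng, 9, group="A")
        b = random_coex(rng, 9, group="B")
        base = pc_index(a, b)
        perm = rng.permutation(9)
        from txcoord.coordination import CoexpressionMatrix
        ap = CoexpressionMatrix([a.gene_ids[i] for i in perm], a.R[np.ix_(perm, perm)],
                                "A", a.n_samples)
        bp = CoexpressionMatrix([b.gene_ids[i] for i in perm], b.R[np.ix_(perm, perm)],
                                "B", b.n_samples)
        permuted = pc_index(ap, bp)
        base_map = dict(zip(base.gene_ids, base.pc))
        for g, v in zip(permuted.gene_ids, permuted.pc):
            assert v == pytest.approx(base_map[g], abs=1e-12)


class TestDropDegenerate:
    def test_constant_in_one_group_removed(self):
        df = pd.DataFrame(
            {"a1": [1, 5], "a2": [2, 5], "a3": [3, 5], "b1": [1, 1], "b2": [2, 2], "b3": [3, 4]},
            index=["ok", "flat_in_A_and_B?"], dtype=float)
        # second gene: constant in group A (5,5,5) -> must go for any A-involving analysis
        expr = ExpressionMatrix(df, units="log2cpm")
        meta = SampleMetadata(pd.Series(["A"] * 3 + ["B"] * 3, index=df.columns))
        out = drop_degenerate(expr, meta, ["A", "B"])
        assert out.gene_ids == ["ok"]

    def test_identity_when_nothing_constant(self, counts_expr, two_group_meta):
        noisy = ExpressionMatrix(counts_expr.data + np.random.default_rng(7).uniform(
            0.01, 0.99, counts_expr.data.shape), units="log2cpm")
        out = drop_degenerate(noisy, two_group_meta, ["A", "B"])
        assert out.gene_ids == noisy.gene_ids

    def test_matches_per_group_variance_check(self, rng, two_group_meta, counts_expr):
        data = counts_expr.data.copy().astype(float)
        planted = list(data.index[rng.choice(50, size=6, replace=False)])
        for k, g in enumerate(planted):
            cols = data.columns[:6] if k % 2 else data.columns[6:]
            data.loc[g, cols] = 42.0
        expr = ExpressionMatrix(data, units="log2cpm")
        out = drop_degenerate(expr, two_group_meta, ["A", "B"])
        expected = []
        for g in data.index:
            ok = True
            for grp in ("A", "B"):
                v = data.loc[g, two_group_meta.samples(grp)].to_numpy()
                if np.var(v) == 0:
                    ok = False
            if ok:
                expected.append(g)
        assert out.gene_ids == expected
        assert set(planted).isdisjoint(out.gene_ids)


class TestPairwisePc:
    def test_same_group_twice_gives_unit_pc(self, counts_expr, two_group_meta):
        table = pairwise_pc(counts_expr, two_group_meta, "A", "A")
        assert np.all(table.pc[table.defined] == 1.0)

    def test_equals_manual_stage_chaining(self, counts_expr, two_group_meta):
        expr8 = ExpressionMatrix(counts_expr.data.iloc[:8], units="raw_counts")
        table = pairwise_pc(expr8, two_group_meta, "A", "B", min_mean_count=1)
        work = filter_expressed(expr8, two_group_meta, ["A", "B"], min_mean_count=1)
        work = log_cpm(work, pseudocount=1)
        work = drop_degenerate(work, two_group_meta, ["A", "B"])
        ca = compute_coexpression(work.subset_samples(two_group_meta.samples("A")), "A")
        cb = compute_coexpression(work.subset_samples(two_group_meta.samples("B")), "B")
        expected = pc_index(ca, cb)
        assert table.gene_ids == expected.gene_ids
        assert np.allclose(table.pc, expected.pc, atol=1e-12, equal_nan=True)

    @pytest.mark.parametrize("block_size", [3, 7, 64])
    def test_block_size_does_not_change_results(self, counts_expr, two_group_meta, block_size):
        ref = pairwise_pc(counts_expr, two_group_meta, "A", "B", block_size=10_000)
        blk = pairwise_pc(counts_expr, two_group_meta, "A", "B", block_size=block_size)
        assert blk.gene_ids == ref.gene_ids
        assert np.allclose(blk.pc, ref.pc, atol=1e-12, equal_nan=True)

    def test_null_simulation_concentrates_pc_at_positive_values(self):
        from txcoord.simulate import SimConfig, generate_dataset
        cfg = SimConfig(n_genes=200, n_modules=10, module_sizes=[20] * 10,
                        groups={"A": 30, "B": 30}, rewired_modules={}, seed=11)
        expr, meta, _ = generate_dataset(cfg)
        table = pairwise_pc(expr, meta, "A", "B")
        assert float(np.mean(table.pc[table.defined])) > 0.5


class TestSummarizePc:
    def test_direct_arithmetic(self):
        t = PcTable(["a", "b", "c"], np.array([0.1, 0.2, 0.3]), ("A", "B"), 2)
        s = summarize_pc(t)
        assert s["mean"] == pytest.approx(0.2)
        assert s["median"] == pytest.approx(0.2)
        assert s["n"] == 3

    def test_symmetric_values_average_to_zero(self):
        t = PcTable(["a", "b"], np.array([-1.0, 1.0]), ("A", "B"), 1)
        assert summarize_pc(t)["mean"] == 0.0

    def test_matches_independent_summary(self, rng):
        vals = rng.uniform(-1, 1, 40)
        t = PcTable([f"g{i}" for i in range(40)], vals, ("A", "B"), 39)
        s = summarize_pc(t)
        assert s["mean"] == pytest.approx(float(np.mean(vals)), abs=1e-12)
        assert s["median"] == pytest.approx(float(np.median(vals)), abs=1e-12)
        assert s["sd"] == pytest.approx(float(np.std(vals, ddof=1)), abs=1e-12)

    def test_undefined_values_excluded_and_counted(self):
        t = PcTable(["a", "b", "c"], np.array([0.5, np.nan, 0.7]), ("A", "B"), 2)
        s = summarize_pc(t)
        assert s["n"] == 2 and s["n_undefined"] == 1

    def test_empty_rejected(self):
        t = PcTable(["a"], np.array([np.nan]), ("A", "B"), 3)
        with pytest.raises(ValueError, match="no defined"):
            summarize_pc(t)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_genes=st.integers(5, 12))
def test_pc_values_always_within_unit_interval(seed, n_genes):
    rng = np.random.default_rng(seed)
    a = random_coex(rng, n_genes, group="A")
    b = random_coex(rng, n_genes, group="B")
    table = pc_index(a, b)
    assert np.all(np.abs(table.pc[table.defined]) <= 1.0)


class TestCoordinationAnalysisEstimator:
    def test_fit_matches_functional_pipeline(self, counts_expr, two_group_meta):
        X = counts_expr.data.T  # samples x genes, sklearn orientation
        y = two_group_meta.groups.loc[X.index].to_numpy()
        est = CoordinationAnalysis().fit(X, y)
        assert est.groups_ == ["A", "B"]
        table = est.pc_tables_[("A", "B")]
        expected = pairwise_pc(counts_expr, two_group_meta, "A", "B")
        assert table.gene_ids == expected.gene_ids
        assert np.allclose(table.pc, expected.pc, atol=1e-12, equal_nan=True)
        assert est.n_features_in_ == 50

    def test_get_set_params_round_trip(self):
        est = CoordinationAnalysis(min_mean_count=3.0)
        params = est.get_params()
        assert params["min_mean_count"] == 3.0
        est.set_params(exclude_self=False, block_size=128)
        assert est.exclude_self is False and est.block_size == 128

    def test_three_groups_yield_three_comparisons(self):
        from txcoord.simulate import SimConfig, generate_dataset
        cfg = SimConfig(n_genes=60, n_modules=3, module_sizes=[10] * 3,
                        groups={"C": 5, "S": 5, "NS": 5}, rewired_modules={}, seed=3)
        expr, meta, _ = generate_dataset(cfg)
        est = CoordinationAnalysis().fit(expr.data.T, meta.groups.to_numpy())
        assert est.comparisons_ == [("C", "S"), ("C", "NS"), ("S", "NS")]
        frame = est.pc_frame()
        assert set(frame["comparison"]) == {"C_vs_S", "C_vs_NS", "S_vs_NS"}
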