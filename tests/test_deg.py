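import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wheatstress import (
    SimulationConfig,
    benjamini_yekutieli,
    call_degs,
    deg_test,
    degs_in_intervals,
    filter_low_expression,
    fold_change,
    generate_expression,
    venn_overlap,
)
from wheatstress.io import ExpressionMatrix, GenomicIntervalSet


def welch_oracle(x, y):
    """Textbook Welch t-test on log2(x+1): statistic, Satterthwaite df, p."""
    x = np.log2(np.asarray(x, dtype=float) + 1)
    y = np.log2(np.asarray(y, dtype=float) + 1)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def by_oracle(p):
    """Brute-force step-up: adjusted(i) = min over j>=rank(i) of p(j)m H(m)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    harmonic = sum(1.0 / j for j in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adjusted_sorted = np.empty(m)
    for i in range(m):
        adjusted_sorted[i] = min(
            min(1.0, sorted_p[j] * m * harmonic / (j + 1)) for j in range(i, m)
        )
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def _small_matrix(gene_rows, conditions):
    """Build a matrix from {gene: {(variety, treatment): [reps]}}."""
    libraries, design_rows = [], []
    for v, t in conditions:
        n = len(next(iter(gene_rows.values()))[(v, t)])
        for r in range(1, n + 1):
            libraries.append(f"{v}_{t}_R{r}")
            design_rows.append((v, t, r))
    values = {}
    for lib, (v, t, r) in zip(libraries, design_rows):
        values[lib] = [gene_rows[g][(v, t)][r - 1] for g in gene_rows]
    design = pd.DataFrame(
        design_rows, columns=["variety", "treatment", "replicate"],
        index=pd.Index(libraries, name="library"),
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=list(gene_rows)),
        design=design,
        normalized=True,
    )


class TestExpressionFloor:
    def test_gene_below_floor_everywhere_removed(self):
        expr = _small_matrix(
            {"low": {("A", "control"): [0.3, 0.3], ("A", "s"): [0.3, 0.3]},
             "high": {("A", "control"): [5.0, 5.0], ("A", "s"): [5.0, 5.0]}},
            [("A", "control"), ("A", "s")],
        )
        assert filter_low_expression(expr, floor=0.5) == ["high"]

    def test_one_condition_above_floor_retains(self):
        expr = _small_matrix(
            {"g": {("A", "control"): [0.0, 0.0], ("A", "s"): [0.6, 0.6]}},
            [("A", "control"), ("A", "s")],
        )
        assert filter_low_expression(expr, floor=0.5) == ["g"]
        # the strict reading removes it: the mean must clear the floor everywhere
        assert filter_low_expression(expr, floor=0.5, require_all=True) == []

    def test_zero_floor_keeps_everything(self, study):
        _, expr, _ = study
        assert filter_low_expression(expr, floor=0.0) == expr.genes


class TestFoldChange:
    def test_doubling_without_pseudocount(self):
        expr = _small_matrix(
            {"g": {("A", "control"): [5.0, 5.0], ("A", "s"): [10.0, 10.0]}},
            [("A", "control"), ("A", "s")],
        )
        assert fold_change(expr, "g", "A", "s", pseudocount=0.0) == pytest.approx(2.0)

    def test_identical_means_give_unity(self):
        expr = _small_matrix(
            {"g": {("A", "control"): [7.0, 9.0], ("A", "s"): [8.0, 8.0]}},
            [("A", "control"), ("A", "s")],
        )
        assert fold_change(expr, "g", "A", "s") == pytest.approx(1.0)

    def test_planted_fc_recovered_without_noise(self, noiseless_study):
        _, expr, truth = noiseless_study
        for (gene, v, t), fc in list(truth.planted_fc.items())[:20]:
            got = fold_change(expr, gene, v, t, pseudocount=0.0)
            assert got == pytest.approx(fc, rel=1e-12)

    def test_missing_control_group_rejected(self):
        expr = _small_matrix(
            {"g": {("A", "control"): [1.0, 1.0], ("A", "s"): [1.0, 1.0]}},
            [("A", "control"), ("A", "s")],
        )
        with pytest.raises(ValueError, match="control"):
            fold_change(expr, "g", "B", "s")


class TestWelch:
    def test_identical_groups_give_p_one(self):
        assert deg_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_matches_independent_welch_oracle(self):
        c, s = [1.0, 1.1, 0.9], [5.0, 5.2, 4.8]
        assert deg_test(c, s) == pytest.approx(welch_oracle(c, s), abs=1e-10)

    @given(
        st.lists(st.floats(0, 100), min_size=3, max_size=6),
        st.lists(st.floats(0, 100), min_size=3, max_size=6),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_oracle_agreement_property(self, c, s):
        if np.var(np.log2(np.asarray(c) + 1), ddof=1) == 0 and np.var(
            np.log2(np.asarray(s) + 1), ddof=1
        ) == 0:
            return
        assert deg_test(c, s) == pytest.approx(welch_oracle(c, s), abs=1e-10)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            deg_test([1.0], [2.0, 3.0])

    def test_constant_groups_resolved_by_mean(self):
        assert deg_test([2, 2, 2], [2, 2, 2]) == 1.0
        assert deg_test([2, 2, 2], [9, 9, 9]) == 0.0


class TestBenjaminiYekutieli:
    def test_single_test_unchanged(self):
        adjusted, rejected = benjamini_yekutieli([0.04], q=0.05)
        assert adjusted[0] == pytest.approx(0.04)
        assert rejected[0]

    def test_all_ones_stay_ones(self):
        adjusted, rejected = benjamini_yekutieli([1.0] * 5)
        assert (adjusted == 1.0).all() and not rejected.any()

    def test_four_value_worked_example(self):
        # hand enumeration with H(4) = 25/12
        adjusted, _ = benjamini_yekutieli([0.01, 0.02, 0.04, 0.05])
        np.testing.assert_allclose(
            adjusted, [1 / 12, 1 / 12, 0.125 * 25 / 30, 0.05 * 25 / 12], atol=1e-12
        )
        np.testing.assert_allclose(
            np.round(adjusted, 4), [0.0833, 0.0833, 0.1042, 0.1042]
        )

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            benjamini_yekutieli([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_matches_brute_force_and_statsmodels(self, p, _seed):
        from statsmodels.stats.multitest import multipletests

        adjusted, rejected = benjamini_yekutieli(p, q=0.05)
        np.testing.assert_allclose(adjusted, by_oracle(p), atol=1e-12)
        reject_sm, adj_sm, _, _ = multipletests(p, alpha=0.05, method="fdr_by")
        np.testing.assert_allclose(adjusted, adj_sm, atol=1e-10)
        assert (rejected == reject_sm).all()

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_monotone_and_dominated_by_bh(self, p):
        from statsmodels.stats.multitest import multipletests

        adjusted, rejected = benjamini_yekutieli(p, q=0.05)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adjusted[order]) >= -1e-12).all()
        reject_bh, _, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert not (rejected & ~reject_bh).any()  # BY rejections are a BH subset


class TestCallDegs:
    def test_planted_degs_all_recovered_at_low_noise(self):
        config = SimulationConfig(
            n_genes=800, deg_fraction=0.1, fc_range=(5.0, 9.0), noise_cv=0.05, seed=17
        )
        expr, truth = generate_expression(config)
        table = call_degs(expr)
        called = set(table.loc[table["significant"], "gene"])
        assert set(truth.deg_genes) <= called

    def test_direction_matches_planted_truth(self):
        config = SimulationConfig(
            n_genes=400, deg_fraction=0.1, fc_range=(5.0, 9.0), noise_cv=0.05, seed=19
        )
        expr, truth = generate_expression(config)
        table = call_degs(expr).set_index(["gene", "variety", "treatment"])
        sig = table[table["significant"]]
        for key, row in sig.iterrows():
            if key in truth.deg_flags:
                assert row["direction"] == truth.deg_flags[key]

    def test_floor_above_all_expression_empties_table(self, study):
        _, expr, _ = study
        table = call_degs(expr, floor=float(expr.values.max().max()) * 2)
        assert len(table) == 0

    def test_significant_rows_pass_fold_change_gate(self, study):
        _, expr, _ = study
        table = call_degs(expr)
        sig = table[table["significant"]]
        assert ((sig["fold_change"] > 2) | (sig["fold_change"] < 0.5)).all()
        tested = table[table["p_value"].notna()]
        assert (tested["p_adjusted"] >= tested["p_value"] - 1e-12).all()

    def test_invariant_under_library_permutation(self, study):
        _, expr, _ = study
        rng = np.random.default_rng(7)
        perm = rng.permutation(expr.libraries)
        shuffled = ExpressionMatrix(
            values=expr.values[perm], design=expr.design.loc[perm], normalized=True
        )
        a = call_degs(expr).sort_values(["gene", "variety", "treatment"]).reset_index(drop=True)
        b = call_degs(shuffled).sort_values(["gene", "variety", "treatment"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_null_data_rarely_calls_genes(self):
        config = SimulationConfig(n_genes=2000, deg_fraction=0.0, noise_cv=0.1, seed=29)
        expr, _ = generate_expression(config)
        table = call_degs(expr, q=0.05)
        frac = table.loc[table["significant"], "gene"].nunique() / config.n_genes
        assert frac <= 0.05


class TestVenn:
    def test_equal_sets(self):
        ov = venn_overlap({"a", "b"}, {"a", "b"})
        assert ov.percentage == 100.0

    def test_disjoint_sets(self):
        ov = venn_overlap({"a"}, {"b"})
        assert ov.percentage == 0.0

    def test_both_empty_percentage_null(self):
        assert venn_overlap(set(), set()).percentage is None

    def test_union_identity(self):
        ov = venn_overlap(set(range(100)), set(range(60, 130)))
        assert ov.union == ov.size_a + ov.size_b - ov.intersection

    def test_wd_overlap_matches_reported_percentage(self):
        # 31 shared of a 397-gene union reports as 7.8%
        a = set(range(125))
        b = set(range(94, 397))
        ov = venn_overlap(a, b)
        assert (ov.intersection, ov.union) == (31, 397)
        assert ov.percentage == 7.8


class TestIntervals:
    @staticmethod
    def _deg_table(genes):
        return pd.DataFrame(
            {"gene": genes, "variety": "A", "treatment": "s",
             "mean_control": 1.0, "mean_stress": 3.0, "fold_change": 3.0,
             "p_value": 0.01, "p_adjusted": 0.02, "direction": "up",
             "significant": True}
        )

    def test_empty_region_set_gives_empty_subset(self):
        table = self._deg_table(["g1"])
        pos = pd.DataFrame({"chrom": ["2A"], "start": [0], "end": [10]}, index=["g1"])
        out = degs_in_intervals(table, GenomicIntervalSet(), pos)
        assert len(out) == 0

    def test_whole_chromosome_region_returns_all(self):
        genes = [f"g{i}" for i in range(5)]
        table = self._deg_table(genes)
        pos = pd.DataFrame(
            {"chrom": "2A", "start": np.arange(5) * 100, "end": np.arange(5) * 100 + 50},
            index=genes,
        )
        regions = GenomicIntervalSet(
            intervals=pd.DataFrame({"chrom": ["2A"], "start": [0], "end": [10_000]})
        )
        assert len(degs_in_intervals(table, regions, pos)) == 5

    def test_midpoint_selection_picks_covered_genes_only(self):
        genes = [f"g{i}" for i in range(10)]
        table = self._deg_table(genes)
        pos = pd.DataFrame(
            {"chrom": "2A", "start": np.arange(10) * 100,
             "end": np.arange(10) * 100 + 100},
            index=genes,
        )
        # midpoints 50, 150, ..., 950; region [0, 300) covers the first 3
        regions = GenomicIntervalSet(
            intervals=pd.DataFrame({"chrom": ["2A"], "start": [0], "end": [300]})
        )
        out = degs_in_intervals(table, regions, pos)
        assert list(out["gene"]) == ["g0", "g1", "g2"]

    def test_gene_without_position_skipped_with_warning(self):
        table = self._deg_table(["g1", "orphan"])
        pos = pd.DataFrame({"chrom": ["2A"], "start": [0], "end": [100]}, index=["g1"])
        regions = GenomicIntervalSet(
            intervals=pd.DataFrame({"chrom": ["2A"], "start": [0], "end": [100]})
        )
        with pytest.warns(UserWarning, match="skipped"):
            out = degs_in_intervals(table, regions, pos)
        assert list(out["gene"]) == ["g1"]
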