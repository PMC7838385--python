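"""Gene selection, correlations, NNSD-based threshold choice, network
construction, and the degree-distribution power-law fit."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from conftest import make_annotation, make_design
from fmena.datatypes import PipelineError, SignalMatrix
from fmena.rmt import (
    CorrelationMatrix,
    ThresholdScanError,
    build_network,
    nnsd_test,
    pearson_matrix,
    powerlaw_r2,
    select_common_genes,
    select_threshold,
    threshold_similarity,
    unfold_eigenvalues,
)
from fmena.synthetic import generate_correlated_blocks


def _goe(n, rng):
    a = rng.standard_normal((n, n))
    return (a + a.T) / np.sqrt(2 * n)


def _block_goe(n_blocks, block_size, rng):
    return scipy.linalg.block_diag(*[_goe(block_size, rng) for _ in range(n_blocks)])


class TestSelectCommonGenes:
    def test_prevalent_focal_gene_kept_offcategory_excluded(self):
        design = make_design(2, 4)
        probes = ["g1", "g2"]
        annot = make_annotation(probes, categories=["stress response", "virulence"])
        values = pd.DataFrame(1.0, index=probes, columns=design.samples)
        m = SignalMatrix(values, transformed=True, normalized=True)
        kept = select_common_genes(m, design, annot, "low")
        assert list(kept) == ["g1"]

    def test_prevalence_fraction_enumeration(self):
        design = make_design(2, 4)
        low = design.samples_in_group("low")
        probes = [f"g{i}" for i in range(10)]
        annot = make_annotation(probes, categories=["carbon cycling"] * 10)
        values = pd.DataFrame(0.0, index=probes, columns=design.samples)
        for i, p in enumerate(probes):  # probe i detected in i low samples (max 4)
            values.loc[p, low[: min(i, 4)]] = 1.0
        m = SignalMatrix(values, transformed=True, normalized=True)
        kept = select_common_genes(m, design, annot, "low", min_prevalence_fraction=0.5)
        expected = [p for i, p in enumerate(probes) if min(i, 4) >= 2]
        assert list(kept) == expected

    def test_empty_selection_raises_advice(self):
        design = make_design(2, 4)
        annot = make_annotation(["g1"], categories=["virulence"])
        values = pd.DataFrame(1.0, index=["g1"], columns=design.samples)
        m = SignalMatrix(values, transformed=True, normalized=True)
        with pytest.raises(PipelineError, match="prevalence"):
            select_common_genes(m, design, annot, "low")


class TestPearsonMatrix:
    def test_duplicate_gene_r_one_negated_r_minus_one(self):
        rng = np.random.default_rng(0)
        base = rng.random(8)
        values = pd.DataFrame(
            [base, base, 1.0 - base], index=["a", "b", "c"], columns=[f"s{i}" for i in range(8)]
        )
        corr = pearson_matrix(values)
        assert corr.r[0, 1] == pytest.approx(1.0)
        assert corr.r[0, 2] == pytest.approx(-1.0)

    def test_matches_definitional_formula(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.random((3, 6)), index=["a", "b", "c"])
        corr = pearson_matrix(values)
        x = values.to_numpy()
        for i in range(3):
            for j in range(3):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert corr.r[i, j] == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_rejected(self):
        values = pd.DataFrame(np.random.default_rng(2).random((3, 3)))
        with pytest.raises(PipelineError):
            pearson_matrix(values)

    def test_zero_variance_genes_dropped(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            [[1.0] * 6, rng.random(6), rng.random(6)], index=["flat", "ok1", "ok2"]
        )
        corr = pearson_matrix(values)
        assert corr.genes == ["ok1", "ok2"]


class TestNNSD:
    def test_goe_verdict_over_seeds(self):
        verdicts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            verdicts.append(nnsd_test(_goe(200, rng), st=0.0).verdict)
        assert verdicts.count("goe") >= 19

    def test_block_diagonal_poisson_verdict_over_seeds(self):
        verdicts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            verdicts.append(nnsd_test(_block_goe(12, 20, rng), st=0.0).verdict)
        assert verdicts.count("poisson") >= 19

    def test_unfolded_mean_spacing_near_one(self):
        for seed in (0, 1):
            rng = np.random.default_rng(seed)
            res = nnsd_test(_goe(200, rng), st=0.0)
            assert abs(res.mean_spacing - 1.0) <= 0.05
            res_b = nnsd_test(_block_goe(12, 20, rng), st=0.0)
            assert abs(res_b.mean_spacing - 1.0) <= 0.05

    def test_tiny_matrix_rejected_when_not_allowed(self):
        with pytest.raises(PipelineError):
            nnsd_test(np.eye(2), st=0.5, allow_small=False)

    def test_diagonal_matrix_is_degenerate_poisson(self):
        res = nnsd_test(np.eye(60), st=0.5)
        assert res.verdict == "poisson"
        assert res.degenerate

    def test_unfolding_methods_agree_on_goe(self):
        rng = np.random.default_rng(1)
        eigs = np.sort(np.linalg.eigvalsh(_goe(300, rng)))
        for method in ("local", "ecdf", "spline"):
            sp = unfold_eigenvalues(eigs, method=method)
            assert abs(sp.mean() - 1.0) < 0.05


class TestSelectThreshold:
    def test_planted_blocks_select_at_or_below_planted_correlation(self):
        blocks = generate_correlated_blocks(120, 8, 0.98, 50, seed=1)
        corr = pearson_matrix(blocks.values)
        scan = select_threshold(corr)
        assert scan.selected_st <= 0.98

    def test_identity_matrix_selects_grid_minimum(self):
        corr = CorrelationMatrix(np.eye(80), [f"g{i}" for i in range(80)], 24)
        scan = select_threshold(corr)
        assert scan.selected_st == pytest.approx(0.30)

    def test_structureless_goe_correlation_raises(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((200, 200))
        m = np.clip(0.08 * (a + a.T) / np.sqrt(2), -1, 1)
        np.fill_diagonal(m, 1.0)
        corr = CorrelationMatrix(m, [f"g{i}" for i in range(200)], 24)
        with pytest.raises(ThresholdScanError):
            select_threshold(corr)

    def test_scan_summary_records_grid(self):
        blocks = generate_correlated_blocks(120, 8, 0.95, 100, seed=0)
        scan = select_threshold(pearson_matrix(blocks.values))
        summary = scan.summary()
        assert (summary["st"].to_numpy() == scan.grid).all()
        assert summary["verdict"].isin(["poisson", "goe", "ambiguous"]).all()


class TestBuildNetwork:
    def _toy_corr(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.99
        r[0, 2] = r[2, 0] = 0.10
        r[1, 2] = r[2, 1] = -0.99
        return CorrelationMatrix(r, ["a", "b", "c"], 10)

    def test_signed_edges_and_counts(self):
        net = build_network(self._toy_corr(), 0.9)
        assert net.n == 3 and net.L == 2
        assert net.pct_positive == pytest.approx(50.0)
        assert net.pct_negative == pytest.approx(50.0)
        assert net.graph.edges[("a", "b")]["sign"] == 1
        assert net.graph.edges[("b", "c")]["sign"] == -1

    def test_threshold_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            build_network(self._toy_corr(), 1.0 + 1e-9)

    def test_isolated_genes_dropped_and_empty_warning(self):
        net = build_network(self._toy_corr(), 0.999)
        assert net.n == 0
        assert net.empty_warning

    def test_edges_monotone_nonincreasing_in_threshold(self):
        blocks = generate_correlated_blocks(60, 4, 0.9, 30, seed=5)
        corr = pearson_matrix(blocks.values)
        previous = None
        for st in (0.3, 0.5, 0.7, 0.9):
            edges = set(map(frozenset, build_network(corr, st).graph.edges))
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_planted_blocks_edges_mostly_intra_block(self):
        blocks = generate_correlated_blocks(60, 3, 0.95, 50, seed=6)
        corr = pearson_matrix(blocks.values)
        net = build_network(corr, 0.7)
        intra = sum(
            1 for u, v in net.graph.edges if blocks.block_of[u] == blocks.block_of[v]
        )
        assert intra / net.L >= 0.9


class TestPowerlawR2:
    def test_exact_power_law_r2_one(self):
        # degree frequencies (1 x8, 2 x4, 4 x2, 8 x1): a perfect log-log line
        import networkx as nx
        from fmena.rmt import GeneNetwork

        degree_sequence = [8] + [4] * 2 + [2] * 4 + [1] * 8
        g = nx.havel_hakimi_graph(degree_sequence)
        assert sorted(d for _, d in g.degree()) == sorted(degree_sequence)
        net = GeneNetwork(g, st=0.5)
        assert powerlaw_r2(net) == pytest.approx(1.0, abs=1e-9)

    def test_r2_on_generated_tree_matches_manual_ols(self):
        import networkx as nx
        from fmena.rmt import GeneNetwork

        g = nx.balanced_tree(2, 4)
        net = GeneNetwork(g, st=0.5)
        r2 = powerlaw_r2(net)
        degs = np.array([d for _, d in g.degree()])
        ks, freqs = np.unique(degs, return_counts=True)
        x, y = np.log10(ks), np.log10(freqs)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - slope * x - intercept
        expected = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 == pytest.approx(expected, abs=1e-12)

    def test_regular_graph_undefined(self):
        import networkx as nx
        from fmena.rmt import GeneNetwork

        net = GeneNetwork(nx.cycle_graph(6), st=0.5)
        assert powerlaw_r2(net) is None


def test_threshold_similarity_strict_keep_rule():
    r = np.array([[1.0, 0.5, -0.7], [0.5, 1.0, 0.2], [-0.7, 0.2, 1.0]])
    s = threshold_similarity(r, 0.5)
    assert s[0, 1] == 0.5  # |r| equal to st is kept
    assert s[0, 2] == 0.7  # absolute value
    assert s[1, 2] == 0.0
    assert np.diag(s).tolist() == [1.0, 1.0, 1.0]
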