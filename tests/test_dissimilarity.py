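"""Distance metrics and the three permutation tests, against brute-force
enumeration, closed-form limits, and an independent library."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway

from fmena.dissimilarity import (
    DissimilarityMatrix,
    anosim,
    contrast_table,
    distance_matrix,
    mrpp,
    permanova,
)


def _dm(values, metric="euclidean"):
    return DissimilarityMatrix(np.asarray(values, float), [str(i) for i in range(len(values))], metric)


class TestDistances:
    def test_identical_profiles_zero_under_all_metrics(self):
        prof = pd.DataFrame([[1.0, 2.0, 3.0]] * 2, index=["a", "b"])
        for metric in ("euclidean", "bray", "horn"):
            D = distance_matrix(prof, metric)
            assert D.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_bray_horn_one(self):
        prof = pd.DataFrame([[1.0, 2.0, 0.0, 0.0], [0.0, 0.0, 3.0, 4.0]])
        assert distance_matrix(prof, "bray").values[0, 1] == pytest.approx(1.0)
        assert distance_matrix(prof, "horn").values[0, 1] == pytest.approx(1.0)

    def test_euclidean_3_4_5(self):
        prof = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]])
        assert distance_matrix(prof, "euclidean").values[0, 1] == pytest.approx(5.0)

    def test_morisita_horn_formula(self):
        x = np.array([2.0, 1.0, 0.0])
        y = np.array([1.0, 1.0, 2.0])
        X, Y = x.sum(), y.sum()
        expected = 1 - 2 * (x * y).sum() / (((x**2).sum() / X**2 + (y**2).sum() / Y**2) * X * Y)
        prof = pd.DataFrame([x, y])
        assert distance_matrix(prof, "horn").values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_sample_rejected_for_abundance_metrics(self):
        prof = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]])
        for metric in ("bray", "horn"):
            with pytest.raises(ValueError):
                distance_matrix(prof, metric)

    def test_matches_skbio_bray(self):
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(0)
        prof = pd.DataFrame(rng.random((5, 8)), index=[f"s{i}" for i in range(5)])
        ours = distance_matrix(prof, "bray").values
        theirs = beta_diversity("braycurtis", prof.to_numpy(), ids=prof.index).data
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestPermanova:
    def test_exhaustive_enumeration_2v2(self):
        rng = np.random.default_rng(3)
        prof = pd.DataFrame(rng.random((4, 5)))
        D = distance_matrix(prof, "euclidean")
        groups = np.array(["a", "a", "b", "b"])
        res = permanova(D, groups, exact=True)
        # brute force over all distinct labelings
        from fmena.dissimilarity import _permanova_F

        stats = [
            _permanova_F(D.values**2, np.array(g))
            for g in sorted(set(itertools.permutations(groups)))
        ]
        expected_p = np.mean([s >= res.statistic - 1e-12 for s in stats])
        assert res.n_permutations == 6
        assert res.p == pytest.approx(expected_p)

    def test_equals_classical_anova_f_on_1d_euclidean(self):
        rng = np.random.default_rng(1)
        y = rng.random(9)
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        D = distance_matrix(pd.DataFrame(y), "euclidean")
        res = permanova(D, groups, n_perm=9, seed=0)
        expected = f_oneway(y[:3], y[3:6], y[6:]).statistic
        assert res.statistic == pytest.approx(expected, abs=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        prof = pd.DataFrame(rng.random((6, 4)))
        groups = np.array(["a", "b", "a", "b", "a", "b"])
        D = distance_matrix(prof, "euclidean")
        f1 = permanova(D, groups, n_perm=9, seed=0).statistic
        order = rng.permutation(6)
        D2 = DissimilarityMatrix(D.values[np.ix_(order, order)], [str(i) for i in order], "euclidean")
        f2 = permanova(D2, groups[order], n_perm=9, seed=0).statistic
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(5)
        prof = pd.DataFrame(rng.random((8, 6)), index=[f"s{i}" for i in range(8)])
        groups = ["a"] * 4 + ["b"] * 4
        D = distance_matrix(prof, "bray")
        ours = permanova(D, np.array(groups), n_perm=99, seed=0)
        theirs = sk_permanova(SkDM(D.values, ids=D.ids), grouping=groups, permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"], abs=1e-9)

    def test_single_sample_group_rejected(self):
        D = _dm([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError):
            permanova(D, np.array(["a", "b", "b"]))

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        groups = np.array(["a"] * 6 + ["b"] * 6)
        hits = 0
        n_sim = 1000
        for i in range(n_sim):
            prof = pd.DataFrame(rng.standard_normal((12, 10)))
            D = distance_matrix(prof, "euclidean")
            hits += permanova(D, groups, n_perm=99, seed=i).p <= 0.05
        assert abs(hits / n_sim - 0.05) <= 0.02


class TestAnosim:
    def test_complete_separation_R_one(self):
        prof = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [10.0, 10.0], [10.1, 10.0], [10.0, 10.1]]
        )
        D = distance_matrix(prof, "euclidean")
        res = anosim(D, np.array(["a"] * 3 + ["b"] * 3), n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_all_distances_equal_R_zero(self):
        n = 4
        d = np.ones((n, n)) - np.eye(n)
        res = anosim(_dm(d), np.array(["a", "a", "b", "b"]), n_perm=9, seed=0)
        assert res.statistic == pytest.approx(0.0)

    def test_expectation_zero_over_exhaustive_permutations(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(rng.random((6, 5)))
        D = distance_matrix(prof, "euclidean")
        from fmena.dissimilarity import _anosim_R
        from scipy.spatial.distance import squareform
        from scipy.stats import rankdata

        ranks = squareform(rankdata(D.condensed()), checks=False)
        labels = ["a", "a", "a", "b", "b", "b"]
        stats = [_anosim_R(ranks, np.array(p)) for p in set(itertools.permutations(labels))]
        assert np.mean(stats) == pytest.approx(0.0, abs=1e-12)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(6)
        prof = pd.DataFrame(rng.random((8, 6)), index=[f"s{i}" for i in range(8)])
        groups = ["a"] * 4 + ["b"] * 4
        D = distance_matrix(prof, "euclidean")
        ours = anosim(D, np.array(groups), n_perm=99, seed=0)
        theirs = sk_anosim(SkDM(D.values, ids=D.ids), grouping=groups, permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"], abs=1e-9)


class TestMrpp:
    def test_identical_pairs_delta_zero(self):
        prof = pd.DataFrame([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0], [5.0, 5.0]])
        D = distance_matrix(prof, "euclidean")
        res = mrpp(D, np.array(["a", "a", "b", "b"]), n_perm=9, seed=0)
        assert res.statistic == pytest.approx(0.0)

    def test_single_group_delta_is_mean_pairwise_distance(self):
        rng = np.random.default_rng(8)
        prof = pd.DataFrame(rng.random((5, 3)))
        D = distance_matrix(prof, "euclidean")
        from fmena.dissimilarity import _mrpp_delta

        delta = _mrpp_delta(D.values, np.zeros(5))
        assert delta == pytest.approx(D.condensed().mean())

    def test_exhaustive_enumeration_2v2(self):
        rng = np.random.default_rng(9)
        prof = pd.DataFrame(rng.random((4, 5)))
        D = distance_matrix(prof, "euclidean")
        groups = np.array(["a", "a", "b", "b"])
        res = mrpp(D, groups, exact=True)
        from fmena.dissimilarity import _mrpp_delta

        stats = [
            _mrpp_delta(D.values, np.array(g))
            for g in sorted(set(itertools.permutations(groups)))
        ]
        expected_p = np.mean([s <= res.statistic + 1e-12 for s in stats])
        assert res.p == pytest.approx(expected_p)


def test_observed_statistic_included_in_null():
    """Add-observed convention: p is at least 1/(n_perm + 1)."""
    rng = np.random.default_rng(10)
    prof = pd.DataFrame(rng.standard_normal((8, 4)))
    groups = np.array(["a"] * 4 + ["b"] * 4)
    D = distance_matrix(prof, "euclidean")
    for test in (permanova, anosim, mrpp):
        res = test(D, groups, n_perm=99, seed=1)
        assert res.p >= 1.0 / 100


def test_all_tests_concordant_on_planted_group_effect():
    """A two-fold planted group effect is detected by every test under
    every metric, echoing the concordance of the published contrasts."""
    rng = np.random.default_rng(11)
    base = rng.random((12, 30)) + 0.5
    base[6:, :10] *= 2.0  # strong shift in a third of the features
    prof = pd.DataFrame(base)
    groups = np.array(["low"] * 6 + ["high"] * 6)
    table = contrast_table(prof, groups, n_perm=199, seed=2)
    for col in ("mrpp_p", "anosim_p", "adonis_p"):
        assert (table[col] < 0.05).all(), table
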