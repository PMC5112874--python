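"""UPGMA clustering, branch labeling, Fisher and rank-sum associations."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

import blpanel as bl
from blpanel.simulate import MARKER_GENE
from conftest import expr


def naive_upgma(d: np.ndarray):
    """Independent O(n^3) agglomerator: recomputes every inter-cluster mean
    distance from the original matrix at each step."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges, heights = [], []
    for step in range(n - 1):
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or h < best[0] or (h == best[0] and (a, b) < best[1]):
                best = (h, (a, b))
        h, (a, b) = best
        clusters[n + step] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b))
        heights.append(h)
    return merges, heights


def fisher_oracle(table) -> float:
    """Exact rational enumeration of the two-sided hypergeometric p."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    pmf = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
           for x in range(max(0, c1 - r2), min(r1, c1) + 1)}
    obs = pmf[a]
    cutoff = obs * (1 + Fraction(1, 10_000_000))
    return float(sum(p for p in pmf.values() if p <= cutoff))


class TestCorrelationDistance:
    def test_duplicate_samples_distance_zero(self, rng):
        x = rng.normal(size=(10, 3))
        x[:, 2] = x[:, 0]
        d = bl.correlation_distance(expr(x))
        assert d.iloc[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_samples_distance_two(self):
        x = np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]])
        d = bl.correlation_distance(expr(x))
        assert d.iloc[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        x = rng.normal(size=(30, 6))
        d = bl.correlation_distance(expr(x))
        ref = 1.0 - np.corrcoef(x.T)
        np.testing.assert_allclose(d.to_numpy(), ref, atol=1e-12)

    def test_insufficient_overlap_rejected_by_pair(self):
        x = np.array([[1.0, np.nan], [2.0, np.nan], [np.nan, 1.0], [np.nan, 2.0]])
        with pytest.raises(ValueError, match="s0.*s1"):
            bl.correlation_distance(expr(x))


class TestAverageLinkage:
    def test_hand_agglomeration(self):
        d = pd.DataFrame([[0, 1, 4], [1, 0, 5], [4, 5, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        tree = bl.average_linkage(d)
        assert tree.merges[0] == (0, 1)
        assert tree.heights[0] == pytest.approx(1.0)
        assert tree.heights[1] == pytest.approx(4.5)

    def test_identical_points_merge_at_zero(self, rng):
        x = rng.normal(size=(8, 4))
        x[:, 3] = x[:, 1]
        tree = bl.average_linkage(bl.correlation_distance(expr(x)))
        assert tree.heights[0] == pytest.approx(0.0, abs=1e-12)
        assert set(tree.merges[0]) == {1, 3}

    def test_matches_naive_oracle_on_random_matrices(self, rng):
        """Merge sequence and heights equal the independent O(n^3)
        agglomerator on 50 random distance matrices (n <= 20)."""
        for _ in range(50):
            n = int(rng.integers(4, 21))
            a = rng.random((n, n))
            d = (a + a.T) / 2
            np.fill_diagonal(d, 0.0)
            dm = pd.DataFrame(d, index=[f"s{i}" for i in range(n)],
                              columns=[f"s{i}" for i in range(n)])
            tree = bl.average_linkage(dm)
            merges, heights = naive_upgma(d)
            assert tree.merges == merges
            np.testing.assert_allclose(tree.heights, heights, atol=1e-12)

    def test_matches_scipy_average_linkage(self, rng):
        """Cross-check against scipy's UPGMA: identical merge heights and
        identical flat clusters at k = 2..4."""
        n = 15
        a = rng.random((n, n))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"s{i}" for i in range(n)]
        tree = bl.average_linkage(pd.DataFrame(d, index=labels, columns=labels))
        Z = linkage(squareform(d), method="average")
        np.testing.assert_allclose(sorted(tree.heights), sorted(Z[:, 2]),
                                   atol=1e-10)
        for k in (2, 3, 4):
            ours = bl.cut_and_label(tree, k).assignments
            theirs = pd.Series(fcluster(Z, k, criterion="maxclust"), index=labels)
            assert ours.groupby(theirs).nunique().max() == 1
            assert theirs.groupby(ours).nunique().max() == 1

    def test_heights_monotone_nondecreasing(self, rng):
        a = rng.random((12, 12))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = bl.average_linkage(pd.DataFrame(d))
        assert all(h2 >= h1 - 1e-12
                   for h1, h2 in zip(tree.heights, tree.heights[1:]))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            bl.average_linkage(pd.DataFrame([[0.0]]))

    def test_newick_export_parses(self, rng):
        x = rng.normal(size=(10, 5))
        tree = bl.average_linkage(bl.correlation_distance(expr(x)))
        nwk = tree.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 4


class TestCutAndLabel:
    def test_separable_groups_recovered(self, strong_cohort):
        z = bl.standardize_genes(strong_cohort.expression)
        tree = bl.average_linkage(bl.correlation_distance(z))
        call = bl.cut_and_label(tree, 2)
        truth = strong_cohort.labels
        tab = pd.crosstab(call.assignments, truth)
        # each cluster is (almost) pure in one subtype
        assert (tab.max(axis=1) / tab.sum(axis=1)).min() >= 0.9

    def test_k_equals_n_singletons(self, rng):
        x = rng.normal(size=(10, 6))
        tree = bl.average_linkage(bl.correlation_distance(expr(x)))
        call = bl.cut_and_label(tree, 6)
        assert call.assignments.nunique() == 6

    def test_branch_label_by_mean_score(self, strong_cohort, reference_cohort):
        refs = bl.derive_reference_profiles(reference_cohort.expression,
                                            reference_cohort.labels)
        scores = bl.score_cohort(strong_cohort.expression, refs)
        z = bl.standardize_genes(strong_cohort.expression)
        tree = bl.average_linkage(bl.correlation_distance(z))
        call = bl.cut_and_label(tree, 2, scores)
        hi = max(call.cluster_scores, key=lambda c: call.cluster_scores[c])
        assert call.branch_labels[hi] == bl.BASAL_LIKE

    def test_cluster_call_agrees_with_score_sign(self, strong_cohort,
                                                 reference_cohort):
        """The two-branch label agrees with the sign-based B/L call for at
        least 90% of samples on a strong-signal cohort."""
        refs = bl.derive_reference_profiles(reference_cohort.expression,
                                            reference_cohort.labels)
        scores = bl.score_cohort(strong_cohort.expression, refs)
        z = bl.standardize_genes(strong_cohort.expression)
        tree = bl.average_linkage(bl.correlation_distance(z))
        call = bl.cut_and_label(tree, 2, scores)
        branch = call.assignments.map(call.branch_labels)
        sign_call = scores["call"].reindex(branch.index)
        assert (branch == sign_call).mean() >= 0.90

    def test_bad_k_rejected(self, rng):
        tree = bl.average_linkage(bl.correlation_distance(
            expr(rng.normal(size=(8, 4)))))
        with pytest.raises(ValueError, match="k"):
            bl.cut_and_label(tree, 1)


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert bl.fisher_exact([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    def test_diagonal_table_enumerated_p(self):
        # two extreme tables, each with probability 1/C(10,5)
        res = bl.fisher_exact([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / comb(10, 5), abs=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        """Agrees with exact rational enumeration to 1e-10 on random tables
        with margins <= 30."""
        for _ in range(100):
            t = rng.integers(0, 16, size=(2, 2))
            assert bl.fisher_exact(t).p_value == pytest.approx(
                fisher_oracle(t), abs=1e-10)

    def test_monotone_in_association_strength(self):
        """Moving mass toward the diagonal at fixed margins never increases
        the two-sided p."""
        ps = [bl.fisher_exact([[10 + k, 10 - k], [10 - k, 10 + k]]).p_value
              for k in range(0, 11)]
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_zero_cell_odds_ratio_continuity_corrected(self):
        res = bl.fisher_exact([[5, 0], [2, 3]])
        assert res.odds_ratio == pytest.approx((5.5 * 3.5) / (0.5 * 2.5))

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            bl.fisher_exact([[1, -1], [1, 1]])
        with pytest.raises(ValueError):
            bl.fisher_exact([[1.5, 1], [1, 1]])


class TestCompareClusterScores:
    @staticmethod
    def call_for(samples, groups):
        return bl.ClusterCall(
            assignments=pd.Series(groups, index=samples),
            cluster_scores={}, branch_labels={})

    def test_identical_distributions_p_near_one(self):
        samples = [f"s{i}" for i in range(20)]
        scores = pd.Series(list(range(10)) * 2, index=samples, dtype=float)
        call = self.call_for(samples, [1] * 10 + [2] * 10)
        _, p = bl.compare_cluster_scores(scores, call)
        assert p > 0.9

    def test_complete_separation_minimal_exact_p(self):
        """Fully separated score ranges at n = 10 + 10 attain the minimum
        two-sided exact rank-sum p of 2 / C(20, 10)."""
        samples = [f"s{i}" for i in range(20)]
        scores = pd.Series(np.r_[np.arange(10), 100 + np.arange(10)],
                           index=samples, dtype=float)
        call = self.call_for(samples, [1] * 10 + [2] * 10)
        _, p = bl.compare_cluster_scores(scores, call)
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_label_swap_symmetric_p(self, rng):
        samples = [f"s{i}" for i in range(16)]
        scores = pd.Series(rng.normal(size=16), index=samples)
        g = [1] * 8 + [2] * 8
        _, p1 = bl.compare_cluster_scores(scores, self.call_for(samples, g))
        _, p2 = bl.compare_cluster_scores(
            scores, self.call_for(samples, [3 - x for x in g]))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_welch_variant(self, rng):
        samples = [f"s{i}" for i in range(16)]
        scores = pd.Series(rng.normal(size=16) + np.r_[np.zeros(8), np.ones(8) * 3],
                           index=samples)
        _, p = bl.compare_cluster_scores(scores, self.call_for(samples, [1] * 8 + [2] * 8),
                                         test="welch")
        assert p < 0.01

    def test_small_cluster_rejected(self):
        samples = ["a", "b", "c"]
        scores = pd.Series([1.0, 2.0, 3.0], index=samples)
        with pytest.raises(ValueError, match="fewer than 2"):
            bl.compare_cluster_scores(scores, self.call_for(samples, [1, 2, 2]))


class TestMutationEnrichment:
    def test_contingency_counts(self, strong_cohort):
        z = bl.standardize_genes(strong_cohort.expression)
        tree = bl.average_linkage(bl.correlation_distance(z))
        call = bl.cut_and_label(tree, 2)
        tab = bl.mutation_contingency(call, strong_cohort.mutations, MARKER_GENE)
        assert tab.sum() == len(strong_cohort.samples)

    def test_enrichment_detected_on_default_frequencies(self, strong_cohort):
        """With ~80% luminal vs ~15% basal marker mutation, the cluster
        association is overwhelmingly significant."""
        z = bl.standardize_genes(strong_cohort.expression)
        tree = bl.average_linkage(bl.correlation_distance(z))
        call = bl.cut_and_label(tree, 2)
        res = bl.fisher_exact(
            bl.mutation_contingency(call, strong_cohort.mutations, MARKER_GENE))
        assert res.p_value < 1e-6
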