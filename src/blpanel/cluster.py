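"""Hierarchical clustering (UPGMA on 1 - Pearson) and cluster associations.

Samples are clustered with average linkage over the 1 - Pearson
correlation distance between their expression vectors.  Cutting the tree
at two clusters and labeling the branch with the higher mean B/L score
"basal-like" reproduces the two-branch basal/luminal reading of a
clustergram.  Associations between cluster membership and binary sample
attributes (e.g. FGFR3 mutation) are tested with Fisher's exact test;
score differences between branches with a two-sided exact rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ExpressionMatrix
from .scoring import BASAL_LIKE, LUMINAL_LIKE, MIN_OVERLAP, pearson_correlation

logger = logging.getLogger("blpanel")


def correlation_distance(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Sample x sample distance d(i,j) = 1 - Pearson(sample_i, sample_j).

    Pairwise-complete over jointly observed genes; any pair with fewer
    than the minimum overlap (or zero variance) is rejected by name, since
    the agglomeration needs a fully finite matrix.
    """
    x = matrix.values
    samples = matrix.samples
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = pearson_correlation(x[:, i], x[:, j])
            if np.isnan(r):
                raise ValueError(
                    f"samples {samples[i]!r} and {samples[j]!r} share fewer than "
                    f"{MIN_OVERLAP} informative genes; distance undefined"
                )
            d[i, j] = d[j, i] = 1.0 - r
    return pd.DataFrame(d, index=samples, columns=samples)


@dataclass
class Dendrogram:
    """Agglomeration record: leaves 0..n-1, internal node i is id n+i."""

    labels: list[str]
    merges: list[tuple[int, int]]  # node ids merged at each step
    heights: list[float]  # 1 - Pearson distance units

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def members(self, upto: int | None = None) -> dict[int, list[int]]:
        """Leaf sets of the clusters present after the first ``upto`` merges."""
        upto = len(self.merges) if upto is None else upto
        clusters = {i: [i] for i in range(self.n_leaves)}
        for step in range(upto):
            a, b = self.merges[step]
            clusters[self.n_leaves + step] = clusters.pop(a) + clusters.pop(b)
        return clusters

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf ordering implied by the merge sequence."""
        order = self.members()
        (root,) = order.values()
        return root

    def to_newick(self) -> str:
        node = {i: f"{self.labels[i]}" for i in range(self.n_leaves)}
        height = {i: 0.0 for i in range(self.n_leaves)}
        for step, (a, b) in enumerate(self.merges):
            h = self.heights[step]
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            nid = self.n_leaves + step
            node[nid] = f"({node.pop(a)}:{la:g},{node.pop(b)}:{lb:g})"
            height[nid] = h
        (root,) = node.values()
        return root + ";"


def average_linkage(distances: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration of a finite symmetric zero-diagonal distance matrix.

    Inter-cluster distance is the unweighted mean over all cross-pairs of
    the original distances.  Ties are broken toward the lexicographically
    smallest (id, id) pair among the minimal distances, so the merge
    sequence is deterministic across platforms.
    """
    d0 = distances.to_numpy(dtype=float)
    n = d0.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if not np.isfinite(d0).all():
        raise ValueError("distance matrix must be finite")
    if not np.allclose(d0, d0.T) or not np.allclose(np.diag(d0), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    active: dict[int, list[int]] = {i: [i] for i in range(n)}  # id -> leaf members
    dist: dict[tuple[int, int], float] = {
        (i, j): d0[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges, heights = [], []
    for step in range(n - 1):
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        new = n + step
        sa, sb = active.pop(a), active.pop(b)
        for k in list(active):
            na, nb = len(sa), len(sb)
            da = dist.pop((min(a, k), max(a, k)))
            db = dist.pop((min(b, k), max(b, k)))
            dist[(k, new)] = (na * da + nb * db) / (na + nb)
        del dist[(a, b)]
        active[new] = sa + sb
        merges.append((a, b))
        heights.append(h)
    return Dendrogram(labels=list(distances.index), merges=merges, heights=heights)


@dataclass
class ClusterCall:
    """Flat clustering of samples with optional basal/luminal branch labels."""

    assignments: pd.Series  # sample -> cluster index 1..k
    cluster_scores: dict[int, float]  # cluster -> mean B/L score
    branch_labels: dict[int, str]  # cluster -> basal-like/luminal-like (k=2 only)

    @property
    def k(self) -> int:
        return int(self.assignments.max())


def cut_and_label(
    tree: Dendrogram, k: int, scores: pd.DataFrame | None = None
) -> ClusterCall:
    """Cut the dendrogram into k clusters; label branches by mean B/L score.

    The cut keeps the first n-k merges.  Cluster indices 1..k follow first
    appearance in sample order.  With k=2 and per-sample scores available,
    the cluster with the higher mean score is labeled basal-like, the
    other luminal-like; for k>2 only indices are returned.
    """
    n = tree.n_leaves
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    clusters = tree.members(upto=n - k)
    leaf_to_cluster = {}
    for cid, leaves in clusters.items():
        for leaf in leaves:
            leaf_to_cluster[leaf] = cid
    index_of: dict[int, int] = {}
    assign = []
    for leaf in range(n):
        cid = leaf_to_cluster[leaf]
        if cid not in index_of:
            index_of[cid] = len(index_of) + 1
        assign.append(index_of[cid])
    assignments = pd.Series(assign, index=tree.labels)

    cluster_scores: dict[int, float] = {}
    branch_labels: dict[int, str] = {}
    if scores is not None:
        s = scores["score"] if isinstance(scores, pd.DataFrame) else scores
        for c in range(1, k + 1):
            members = assignments.index[assignments == c]
            cluster_scores[c] = float(s.reindex(members).mean())
        if k == 2:
            hi = max(cluster_scores, key=lambda c: cluster_scores[c])
            lo = 3 - hi
            branch_labels[hi] = BASAL_LIKE
            branch_labels[lo] = LUMINAL_LIKE
    return ClusterCall(assignments, cluster_scores, branch_labels)


@dataclass
class FisherResult:
    table: np.ndarray  # 2x2 counts
    p_value: float
    odds_ratio: float


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The two-sided p sums hypergeometric probabilities of all tables with
    the same margins whose probability does not exceed the observed
    table's (probability-mass criterion).  The odds ratio is the
    cross-product ratio, with a 0.5 continuity correction applied to every
    cell when any cell is zero.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return FisherResult(table=t, p_value=float(p), odds_ratio=float((a * d) / (b * c)))


def mutation_contingency(
    call: ClusterCall, mutations: pd.Series | pd.DataFrame, gene: str | None = None
) -> np.ndarray:
    """2x2 counts of mutant/wild-type by cluster (k=2) for one gene."""
    if isinstance(mutations, pd.DataFrame):
        if gene is None:
            gene = mutations.columns[0]
        mut = mutations[gene]
    else:
        mut = mutations
    if call.k != 2:
        raise ValueError("mutation contingency requires a 2-cluster call")
    counts = np.zeros((2, 2), dtype=int)
    for c in (1, 2):
        members = call.assignments.index[call.assignments == c]
        m = mut.reindex(members)
        counts[c - 1, 0] = int((m == "mutant").sum())
        counts[c - 1, 1] = int((m == "wild-type").sum())
    return counts


def compare_cluster_scores(
    scores: pd.DataFrame | pd.Series, call: ClusterCall, test: str = "ranksum"
) -> tuple[float, float]:
    """Two-sided comparison of per-sample B/L scores between two clusters.

    ``ranksum`` (default) is the exact Mann-Whitney rank-sum test;
    ``welch`` the unequal-variance t-test.  Returns (statistic, p).
    """
    if call.k != 2:
        raise ValueError("score comparison requires exactly 2 clusters")
    s = scores["score"] if isinstance(scores, pd.DataFrame) else scores
    groups = []
    for c in (1, 2):
        members = call.assignments.index[call.assignments == c]
        vals = s.reindex(members).dropna().to_numpy()
        if len(vals) < 2:
            raise ValueError(f"cluster {c} has fewer than 2 scored samples")
        groups.append(vals)
    if test == "ranksum":
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided",
                                 method="exact" if max(map(len, groups)) <= 25 else "auto")
    elif test == "welch":
        res = stats.ttest_ind(groups[0], groups[1], equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
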