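"""UPGMA agglomeration of the D2 matrix, Mojena cutoff, group extraction.

UPGMA merges, at every step, the pair of clusters whose average
inter-cluster dissimilarity is minimal; the fusion level alpha_m IS that
average (not halved), so on a proper dissimilarity the sequence of fusion
levels is non-decreasing.  The dendrogram's faithfulness is summarized by
the cophenetic correlation: the Pearson correlation between the original
G(G-1)/2 dissimilarities and the fusion level at which each pair first
joins.  Mojena's stopping rule cuts the tree at

    cutoff = mean(alpha) + k * sd(alpha)        (sample sd, G-1 levels)

with k = 1.25 by default (a widely used recommendation); groups are the
connected subtrees whose internal merges all sit strictly below the cutoff.

Agglomeration itself is delegated to scipy's average-linkage
implementation; heights are identical to the textbook O(G^3) algorithm
(tested against one), and merge order on exact ties follows scipy's
deterministic nearest-neighbor-chain convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .divergence import DistanceMatrix

__all__ = [
    "MergeTree",
    "GroupAssignment",
    "upgma",
    "cophenetic_correlation",
    "mojena_cutoff",
    "cut_tree",
    "to_newick",
]


@dataclass(frozen=True)
class MergeTree:
    """UPGMA merge sequence for G leaves.

    ``linkage`` is the (G-1) x 4 scipy linkage matrix: each row
    (a, b, alpha_m, size) merges clusters a and b (ids < G are leaves,
    id G+m is the cluster made by row m) at fusion level alpha_m.
    """

    leaves: tuple[str, ...]
    linkage: np.ndarray = field(repr=False)

    @property
    def fusion_levels(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def cophenetic_distances(self) -> np.ndarray:
        """Condensed vector of fusion levels at which each pair first joins."""
        return hierarchy.cophenet(self.linkage)

    def leaf_order(self) -> list[str]:
        """Leaf ordering for dendrogram plotting (no crossing branches)."""
        return [self.leaves[i] for i in hierarchy.leaves_list(self.linkage)]


@dataclass(frozen=True)
class GroupAssignment:
    """Genotype -> group id (1-based, numbered by first leaf appearance)."""

    cutoff: float
    groups: dict[str, int]

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, gid in self.groups.items():
            out.setdefault(gid, []).append(g)
        return out


def upgma(d2: DistanceMatrix) -> MergeTree:
    """Average-linkage agglomeration of a symmetric dissimilarity matrix."""
    mat = np.asarray(d2.d2, dtype=float)
    G = mat.shape[0]
    if G < 2:
        raise ValueError("need at least 2 genotypes to cluster")
    if mat.shape != (G, G) or not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if (mat < 0).any():
        raise ValueError("dissimilarities must be non-negative")
    condensed = squareform(mat, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return MergeTree(tuple(d2.genotypes), Z)


def cophenetic_correlation(tree: MergeTree, d2: DistanceMatrix) -> float:
    """Pearson correlation between original and cophenetic dissimilarities."""
    if tuple(d2.genotypes) != tree.leaves:
        raise ValueError("tree and matrix have different leaves")
    if len(tree.leaves) < 3:
        raise ValueError("cophenetic correlation needs at least 3 leaves")
    orig = d2.condensed()
    coph = tree.cophenetic_distances()
    return float(pearsonr(orig, coph).statistic)


def mojena_cutoff(tree: MergeTree, k: float = 1.25) -> float:
    """Mojena stopping rule: mean(alpha) + k * sample sd(alpha)."""
    if k < 0:
        raise ValueError(f"Mojena multiplier must be >= 0, got {k}")
    levels = tree.fusion_levels
    sd = levels.std(ddof=1) if len(levels) > 1 else 0.0
    return float(levels.mean() + k * sd)


def cut_tree(tree: MergeTree, cutoff: float) -> GroupAssignment:
    """Sever all merges with fusion level >= cutoff; groups are the remains.

    cutoff below every fusion level -> all singletons; above every level ->
    one group.  Group ids are numbered by first appearance in leaf order.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    G = len(tree.leaves)
    parent = list(range(G))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cluster_root = list(range(G))  # representative leaf-set root per cluster id
    for m, (a, b, h, _size) in enumerate(tree.linkage):
        ra, rb = find(cluster_root[int(a)]), find(cluster_root[int(b)])
        if h < cutoff:
            parent[rb] = ra
        cluster_root.append(ra)
    first_seen: dict[int, int] = {}
    groups: dict[str, int] = {}
    for i, name in enumerate(tree.leaves):
        root = find(i)
        if root not in first_seen:
            first_seen[root] = len(first_seen) + 1
        groups[name] = first_seen[root]
    return GroupAssignment(float(cutoff), groups)


def to_newick(tree: MergeTree) -> str:
    """Newick export: leaves at height 0, branch length = parent level - child level."""
    G = len(tree.leaves)
    heights = np.concatenate([np.zeros(G), tree.linkage[:, 2]])
    labels = [_escape(name) for name in tree.leaves]

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - heights[node]
        if node < G:
            return f"{labels[node]}:{bl:.10g}"
        a, b = int(tree.linkage[node - G, 0]), int(tree.linkage[node - G, 1])
        h = heights[node]
        return f"({render(a, h)},{render(b, h)}):{bl:.10g}"

    root = G + len(tree.linkage) - 1
    a, b = int(tree.linkage[-1, 0]), int(tree.linkage[-1, 1])
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"


def _escape(name: str) -> str:
    if any(c in name for c in " ():,;'"):
        return "'" + name.replace("'", "''") + "'"
    return name
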