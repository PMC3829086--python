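"""LD-tree SNP weighting: r² graph, single-linkage tree, GSC weights.

Rather than pruning SNPs in linkage disequilibrium, the pathway score
down-weights them.  Pairwise LD (r², squared Pearson correlation of
genotype dosages) is computed between pathway SNPs within a genomic
window (default 1 Mb).  Similarity is turned into the distance
d = 1 - r², SNPs are clustered by single linkage, and the resulting
ultrametric dendrogram -- completed by a virtual root at height 1 -- is
fed to the Gerstein-Sonnhammer-Chothia (GSC) branch-length-distribution
algorithm.  Each leaf (SNP) receives a weight in (0, 1]:

* a SNP with no LD partner gets weight exactly 1;
* K mutually perfect copies (r² = 1) get weight 1/K each, so duplicating
  a SNP never changes the weighted score;
* for a two-SNP pathway the weight decreases monotonically from 1 at
  r² = 0 to 1/2 at r² = 1.

The rooting at height 1 with the residual root edge distributed by the
same GSC rule is what makes weighted and unweighted scores
commensurable: it enforces the three identities above.  Per-tree weight
normalization would break them.

The LD-weighted pathway score is the per-sample sum of minor-allele
counts multiplied by these weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .scoring import PathwayScoreVector

#: Default genomic window for pairwise LD computation, in bases.
DEFAULT_LD_WINDOW = 1_000_000


class LDError(ValueError):
    """Raised for out-of-contract LD computations."""


@dataclass
class LDGraph:
    """Sparse symmetric map of pairwise r² between same-chromosome SNPs.

    Only pairs on the same chromosome with position difference at most
    ``window`` are stored; absent pairs are treated downstream as r² = 0.
    Keys are canonical ``(min_id, max_id)`` tuples (lexicographic).
    """

    r2: dict[tuple[str, str], float] = field(default_factory=dict)
    window: int = DEFAULT_LD_WINDOW

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, value: float) -> None:
        if a == b:
            raise LDError("self-pairs are excluded from the LD graph")
        self.r2[self._key(a, b)] = float(value)

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        return self.r2.get(self._key(a, b), default)

    def __len__(self) -> int:
        return len(self.r2)


@dataclass
class LDTree:
    """Single-linkage dendrogram over pathway SNPs, rooted at height 1.

    Leaves are numbered ``0 .. n-1`` in the order of ``leaves``; merge
    ``i`` creates internal node ``n + i``.  Merge heights are
    non-decreasing in [0, 1] and the virtual root sits at height
    ``root_height`` (1.0), so every leaf-to-root path has total length 1.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]
    root_height: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if n == 0:
            raise LDError("tree must have at least one leaf")
        if len(self.merges) != n - 1:
            raise LDError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        heights = [h for _, _, h in self.merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise LDError("merge heights must be non-decreasing")
        if heights and (heights[0] < -1e-12 or heights[-1] > self.root_height + 1e-12):
            raise LDError("merge heights must lie in [0, root_height]")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_heights(self) -> np.ndarray:
        """Height of every node: 0 for leaves, merge height for internals."""
        h = np.zeros(2 * self.n_leaves - 1)
        for i, (_, _, height) in enumerate(self.merges):
            h[self.n_leaves + i] = height
        return h

    def to_newick(self) -> str:
        """Newick string with branch lengths (parent height - child height)."""
        n = self.n_leaves
        heights = self.node_heights()
        children: dict[int, tuple[int, int]] = {
            n + i: (a, b) for i, (a, b, _) in enumerate(self.merges)
        }

        def render(node: int, parent_h: float) -> str:
            length = parent_h - heights[node]
            if node < n:
                return f"{self.leaves[node]}:{length:.10g}"
            a, b = children[node]
            return (
                f"({render(a, heights[node])},{render(b, heights[node])})"
                f":{length:.10g}"
            )

        top = 2 * n - 2 if self.merges else 0
        return f"({render(top, self.root_height)});"


# ---------------------------------------------------------------------------
# Pairwise LD
# ---------------------------------------------------------------------------


def pairwise_r2(
    g: GenotypeMatrix,
    variant_subset: Sequence[str] | None = None,
    window: int = DEFAULT_LD_WINDOW,
) -> LDGraph:
    """Pairwise r² between subset SNPs within ``window`` bases.

    r² is the squared Pearson correlation of dosage vectors over
    pairwise-complete (both non-missing) samples.  Pairs on different
    chromosomes or further apart than ``window`` are not stored; pairs
    where either vector is constant (or fewer than two complete samples
    exist) are omitted and treated as r² = 0 downstream.
    """
    if window <= 0:
        raise LDError(f"window must be positive, got {window}")
    ids = list(variant_subset) if variant_subset is not None else g.variant_ids
    sub = g.subset_variants(ids)
    chrom = sub.variants["chrom"].to_numpy()
    pos = sub.variants["pos"].to_numpy()
    dose = sub.dosage.astype(float)
    obs = sub.dosage != MISSING

    graph = LDGraph(window=window)
    complete = bool(obs.all())
    if complete and sub.n_samples >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(dose, rowvar=False)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if chrom[i] != chrom[j] or abs(int(pos[i]) - int(pos[j])) > window:
                    continue
                r = corr[i, j]
                if np.isfinite(r):
                    graph.set(ids[i], ids[j], min(r * r, 1.0))
        return graph

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if chrom[i] != chrom[j] or abs(int(pos[i]) - int(pos[j])) > window:
                continue
            both = obs[:, i] & obs[:, j]
            if both.sum() < 2:
                continue
            x, y = dose[both, i], dose[both, j]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if np.isfinite(r):
                graph.set(ids[i], ids[j], min(r * r, 1.0))
    return graph


# ---------------------------------------------------------------------------
# Single-linkage clustering
# ---------------------------------------------------------------------------


def build_single_linkage_tree(
    ld: LDGraph,
    leaves: Sequence[str],
    genomic_keys: dict[str, tuple] | None = None,
) -> LDTree:
    """Agglomerate SNPs by single linkage on the distance d = 1 - r².

    Absent LD pairs (different chromosome, beyond the window, or simply
    unlinked) have distance 1, so a pathway always yields one tree whose
    final cluster attaches to the virtual root at height 1.  Ties in the
    minimum inter-cluster distance are broken by the lexicographic
    (chrom, pos, id) key of the clusters' representative (smallest-key)
    leaves, making the tree deterministic and independent of input
    order.
    """
    leaves = list(leaves)
    n = len(leaves)
    if n == 0:
        raise LDError("leaves must be non-empty")
    if genomic_keys is None:
        genomic_keys = {v: (v,) for v in leaves}

    # Leaf-pair distance matrix.
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - ld.get(leaves[i], leaves[j], 0.0)
            dist[i, j] = dist[j, i] = d

    # Active clusters: node id, representative genomic key.  Cluster
    # distances start as leaf distances and are min-combined on merge
    # (single linkage).
    node_of = list(range(n))
    rep = [genomic_keys[v] for v in leaves]
    active = list(range(n))
    cdist = dist.copy()

    merges: list[tuple[int, int, float]] = []
    next_node = n
    while len(active) > 1:
        act = np.array(active)
        sub = cdist[np.ix_(act, act)]
        iu = np.triu_indices(len(act), k=1)
        flat = sub[iu]
        dmin = flat.min()
        ties = np.nonzero(flat == dmin)[0]
        best = None
        for t in ties:
            i, j = int(act[iu[0][t]]), int(act[iu[1][t]])
            lo, hi = sorted((rep[i], rep[j]))
            cand = (lo, hi, i, j)
            if best is None or cand < best:
                best = cand
        _, _, i, j = best
        d = float(dmin)
        merges.append((node_of[i], node_of[j], max(d, 0.0)))
        # Fold j into i: single-linkage min rule, smallest representative.
        cdist[i, :] = np.minimum(cdist[i, :], cdist[j, :])
        cdist[:, i] = cdist[i, :]
        rep[i] = min(rep[i], rep[j])
        node_of[i] = next_node
        next_node += 1
        active.remove(j)

    # Single-linkage heights are non-decreasing by construction up to
    # floating noise; clamp monotonically for the ultrametric contract.
    fixed: list[tuple[int, int, float]] = []
    prev = 0.0
    for a, b, h in merges:
        h = min(max(h, prev), 1.0)
        fixed.append((a, b, h))
        prev = h
    return LDTree(leaves=leaves, merges=fixed)


# ---------------------------------------------------------------------------
# GSC leaf weights
# ---------------------------------------------------------------------------


def gsc_leaf_weights(tree: LDTree) -> pd.Series:
    """Gerstein-Sonnhammer-Chothia weights of the tree's leaves.

    Bottom-up branch-length distribution: each leaf starts with its
    pendant edge length; then every internal edge's length (parent height
    minus node height, processed in merge order) is shared among the
    node's descendant leaves proportionally to their accumulated weights,
    or equally when those weights are all zero (clusters of perfect
    duplicates).  The residual edge up to the virtual root at height 1 is
    distributed by the same rule, so leaf weights sum, per tree, to the
    total branch length and each lies in (0, 1].
    """
    n = tree.n_leaves
    weights = np.zeros(n)
    if n == 1:
        weights[0] = tree.root_height  # single pendant edge to the root
        return pd.Series(weights, index=tree.leaves, name="weight")

    heights = tree.node_heights()
    leafsets: list[set[int]] = [{i} for i in range(n)]

    def distribute(leaf_set: set[int], length: float) -> None:
        if length <= 0:
            return
        idx = sorted(leaf_set)
        total = weights[idx].sum()
        if total == 0:
            share = length / len(idx)
            for i in idx:
                weights[i] += share
        else:
            for i in idx:
                weights[i] += length * weights[i] / total

    for m, (a, b, h) in enumerate(tree.merges):
        distribute(leafsets[a], h - heights[a])
        distribute(leafsets[b], h - heights[b])
        leafsets.append(leafsets[a] | leafsets[b])
    top = 2 * n - 2
    distribute(leafsets[top], tree.root_height - heights[top])
    return pd.Series(weights, index=tree.leaves, name="weight")


def ld_weights(
    g: GenotypeMatrix,
    pathway_variants: Sequence[str],
    window: int = DEFAULT_LD_WINDOW,
) -> pd.Series:
    """Convenience wrapper: r² graph -> single-linkage tree -> GSC weights."""
    ld = pairwise_r2(g, pathway_variants, window=window)
    keys = {v: g.genomic_key(v) for v in pathway_variants}
    tree = build_single_linkage_tree(ld, pathway_variants, genomic_keys=keys)
    return gsc_leaf_weights(tree)


# ---------------------------------------------------------------------------
# Weighted score
# ---------------------------------------------------------------------------


def weighted_pathway_score(
    counts: pd.DataFrame,
    weights: pd.Series,
    pathway_name: str = "pathway",
) -> PathwayScoreVector:
    """LD-weighted pathway A#m: sum of minor-allele counts times weights."""
    ids = list(weights.index)
    unknown = [v for v in ids if v not in counts.columns]
    if unknown:
        raise LDError(f"variants without counts: {unknown[:5]}")
    scores = counts[ids].to_numpy() @ weights.to_numpy()
    return PathwayScoreVector(
        pathway_name=pathway_name,
        scores=pd.Series(scores, index=counts.index, name="score"),
        weighted=True,
        n_variants=len(ids),
    )


def write_weights_tsv(weights: pd.Series, path) -> None:
    """Export weights as TSV (variant_id, weight) for inspection."""
    weights.rename_axis("variant_id").rename("weight").to_csv(path, sep="\t")


def write_merges_tsv(tree: LDTree, path) -> None:
    """Export the merge list (child_a, child_b, height) for inspection."""
    pd.DataFrame(tree.merges, columns=["child_a", "child_b", "height"]).to_csv(
        path, sep="\t", index=False
    )
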