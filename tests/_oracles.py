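"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results from first principles with naive
algorithms and different data structures than the package, so agreement
is evidence of correctness rather than shared code.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Single-linkage agglomeration, recomputed from scratch each step
# ---------------------------------------------------------------------------


def single_linkage_oracle(dist: dict, leaves: list, keys: dict):
    """Naive single-linkage: nested-tuple tree plus merge heights.

    ``dist`` maps frozenset({a, b}) -> distance (default 1.0 when absent).
    Each step recomputes every inter-cluster distance as the minimum over
    all leaf pairs; ties are broken by the sorted pair of representative
    (minimum-key) leaves.  Nodes are ``leaf_name`` or
    ``(child_a, child_b, height)``.
    """

    def leaf_dist(a, b):
        return dist.get(frozenset((a, b)), 1.0)

    clusters = [(leaf, frozenset([leaf])) for leaf in leaves]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = min(
                    leaf_dist(a, b)
                    for a in clusters[i][1]
                    for b in clusters[j][1]
                )
                rep_i = min(keys[l] for l in clusters[i][1])
                rep_j = min(keys[l] for l in clusters[j][1])
                lo, hi = sorted((rep_i, rep_j))
                cand = (d, lo, hi, i, j)
                if best is None or cand < best:
                    best = cand
        d, _, _, i, j = best
        node = (clusters[i][0], clusters[j][0], d)
        members = clusters[i][1] | clusters[j][1]
        heights.append(d)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((node, members))
    return clusters[0][0], heights


def gsc_weights_oracle(tree, root_height: float = 1.0) -> dict:
    """Literal GSC recurrence on a nested-tuple tree.

    Post-order walk: every subtree returns its leaf weights (pendant and
    internal edges already distributed); each edge up to the parent is
    then shared proportionally to the accumulated weights, equally when
    they are all zero; finally the root edge is distributed the same way.
    """

    def height(node):
        return 0.0 if isinstance(node, str) else node[2]

    def distribute(weights: dict, length: float) -> dict:
        if length <= 0:
            return weights
        total = sum(weights.values())
        if total == 0:
            share = length / len(weights)
            return {leaf: w + share for leaf, w in weights.items()}
        return {leaf: w + length * w / total for leaf, w in weights.items()}

    def walk(node) -> dict:
        if isinstance(node, str):
            return {node: 0.0}
        a, b, h = node
        wa = distribute(walk(a), h - height(a))
        wb = distribute(walk(b), h - height(b))
        return {**wa, **wb}

    return distribute(walk(tree), root_height - height(tree))


# ---------------------------------------------------------------------------
# Dense PCA by eigendecomposition of the sample covariance
# ---------------------------------------------------------------------------


def pca_oracle(x: np.ndarray, k: int) -> np.ndarray:
    """Leading-k PC coordinates via a dense covariance eigendecomposition."""
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / xc.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    return xc @ evecs[:, order]


# ---------------------------------------------------------------------------
# OLS by normal equations
# ---------------------------------------------------------------------------


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients via an explicit normal-equations solve."""
    return np.linalg.solve(x.T @ x, x.T @ y)
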