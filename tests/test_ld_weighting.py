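"""Pairwise LD, single-linkage LD trees and GSC leaf weights."""

import numpy as np
import pandas as pd
import pytest

from pathburden.genotype_io import MISSING, GenotypeMatrix
from pathburden.ld_weighting import (
    LDError,
    LDGraph,
    build_single_linkage_tree,
    gsc_leaf_weights,
    ld_weights,
    pairwise_r2,
    weighted_pathway_score,
)
from pathburden.scoring import major_minor_alleles, minor_allele_count_matrix

from _oracles import gsc_weights_oracle, single_linkage_oracle


def _matrix(columns: dict, chrom=None, pos=None):
    ids = list(columns)
    dosage = np.column_stack([columns[v] for v in ids]).astype(np.int16)
    m = len(ids)
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(dosage.shape[0])],
        variants=pd.DataFrame(
            {
                "id": ids,
                "chrom": chrom or ["chr1"] * m,
                "pos": pos or list(range(100, 100 + m)),
                "ref": "A",
                "alt": "G",
            }
        ),
        dosage=dosage,
    )


def _graph(pairs: dict) -> LDGraph:
    ld = LDGraph()
    for (a, b), v in pairs.items():
        ld.set(a, b, v)
    return ld


class TestPairwiseR2:
    def test_identical_vectors_r2_one(self):
        g = _matrix({"a": [0, 1, 2, 1], "b": [0, 1, 2, 1]})
        ld = pairwise_r2(g)
        assert ld.get("a", "b") == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        # r = 2/sqrt(8) -> r² = 0.5
        g = _matrix({"x": [0, 1, 2, 1], "y": [0, 0, 2, 2]})
        assert pairwise_r2(g).get("x", "y") == pytest.approx(0.5, abs=1e-12)

    def test_window_and_chromosome_rules(self):
        g = _matrix(
            {"a": [0, 1, 2, 1], "b": [0, 1, 2, 1], "c": [0, 1, 2, 1]},
            chrom=["chr1", "chr1", "chr2"],
            pos=[100, 2_100_000, 100],
        )
        ld = pairwise_r2(g, window=1_000_000)
        assert len(ld) == 0  # 2 Mb apart and cross-chromosome both absent

    def test_constant_vector_omitted(self):
        g = _matrix({"a": [1, 1, 1, 1], "b": [0, 1, 2, 1]})
        assert len(pairwise_r2(g)) == 0

    def test_pairwise_complete_with_missing(self):
        g = _matrix(
            {"a": [0, 1, 2, 1, MISSING], "b": [0, 1, 2, MISSING, 2]}
        )
        # complete pairs: rows 0-2, identical there
        assert pairwise_r2(g).get("a", "b") == pytest.approx(1.0)

    def test_bad_window_rejected(self):
        g = _matrix({"a": [0, 1, 2]})
        with pytest.raises(LDError):
            pairwise_r2(g, window=0)


class TestSingleLinkageTree:
    def test_three_snp_merge_heights(self):
        ld = _graph({("A", "B"): 0.96, ("A", "C"): 0.2, ("B", "C"): 0.1})
        tree = build_single_linkage_tree(ld, ["A", "B", "C"])
        assert [m[2] for m in tree.merges] == pytest.approx([0.04, 0.8])
        assert tree.root_height == 1.0

    def test_single_leaf_pendant_to_root(self):
        tree = build_single_linkage_tree(LDGraph(), ["only"])
        assert tree.merges == []
        w = gsc_leaf_weights(tree)
        assert w["only"] == 1.0

    def test_absent_pair_merges_at_one(self):
        tree = build_single_linkage_tree(LDGraph(), ["A", "B"])
        assert tree.merges[0][2] == 1.0

    def test_newick_contains_leaves_and_lengths(self):
        ld = _graph({("A", "B"): 0.96, ("A", "C"): 0.2, ("B", "C"): 0.1})
        tree = build_single_linkage_tree(ld, ["A", "B", "C"])
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for leaf in "ABC":
            assert leaf in nwk
        assert ":0.04" in nwk  # pendant edges of the tight pair


class TestGscWeights:
    def test_unlinked_snps_weight_one(self):
        tree = build_single_linkage_tree(LDGraph(), list("ABCD"))
        assert np.allclose(gsc_leaf_weights(tree), 1.0, atol=1e-15)

    def test_perfect_pair_plus_singleton(self):
        tree = build_single_linkage_tree(_graph({("A", "B"): 1.0}), list("ABC"))
        w = gsc_leaf_weights(tree)
        assert w["A"] == pytest.approx(0.5, abs=1e-15)
        assert w["B"] == pytest.approx(0.5, abs=1e-15)
        assert w["C"] == pytest.approx(1.0, abs=1e-15)

    def test_half_linked_pair(self):
        tree = build_single_linkage_tree(_graph({("A", "B"): 0.5}), ["A", "B"])
        assert np.allclose(gsc_leaf_weights(tree), [0.75, 0.75], atol=1e-15)

    def test_k_perfect_duplicates_share_unit_weight(self):
        leaves = [f"v{i}" for i in range(6)]
        ld = _graph({(a, b): 1.0 for a in leaves for b in leaves if a < b})
        w = gsc_leaf_weights(build_single_linkage_tree(ld, leaves))
        assert np.allclose(w, 1 / 6, atol=1e-15)

    def test_two_snp_weight_monotone_in_r2(self):
        grid = np.linspace(0, 1, 21)
        weights = []
        for r2 in grid:
            ld = LDGraph()
            if r2 > 0:
                ld.set("A", "B", r2)
            w = gsc_leaf_weights(build_single_linkage_tree(ld, ["A", "B"]))
            assert np.allclose(w["A"], w["B"])
            weights.append(w["A"])
        assert weights[0] == pytest.approx(1.0)
        assert weights[-1] == pytest.approx(0.5)
        assert all(b <= a + 1e-12 for a, b in zip(weights, weights[1:]))

    def test_weights_invariant_to_leaf_input_order(self):
        rng = np.random.default_rng(2)
        leaves = [f"v{i}" for i in range(7)]
        ld = LDGraph()
        for i in range(7):
            for j in range(i + 1, 7):
                if rng.random() < 0.6:
                    ld.set(leaves[i], leaves[j], rng.random())
        keys = {v: ("chr1", i, v) for i, v in enumerate(leaves)}
        w1 = gsc_leaf_weights(build_single_linkage_tree(ld, leaves, keys))
        shuffled = list(leaves)
        rng.shuffle(shuffled)
        w2 = gsc_leaf_weights(build_single_linkage_tree(ld, shuffled, keys))
        assert np.allclose(w1.sort_index(), w2.sort_index(), atol=1e-12)

    def test_matches_bruteforce_oracle_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            leaves = [f"v{i}" for i in range(n)]
            keys = {v: ("chr1", i, v) for i, v in enumerate(leaves)}
            ld, dist = LDGraph(), {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.7:
                        r2 = float(rng.random())
                        ld.set(leaves[i], leaves[j], r2)
                        dist[frozenset((leaves[i], leaves[j]))] = 1 - r2
            tree = build_single_linkage_tree(ld, leaves, keys)
            w = gsc_leaf_weights(tree)
            nested, heights = single_linkage_oracle(dist, leaves, keys)
            assert np.allclose(
                [m[2] for m in tree.merges], heights, atol=1e-12
            )
            oracle_w = gsc_weights_oracle(nested)
            for leaf in leaves:
                assert w[leaf] == pytest.approx(oracle_w[leaf], abs=1e-12)


class TestWeightedScore:
    def test_arithmetic_and_reduction(self):
        counts = pd.DataFrame({"a": [1], "b": [2], "c": [0]}, index=["S0"])
        w = pd.Series([0.5, 0.5, 1.0], index=["a", "b", "c"])
        vec = weighted_pathway_score(counts, w)
        assert vec.weighted
        assert vec.scores["S0"] == pytest.approx(1.5)
        ones = pd.Series(1.0, index=["a", "b", "c"])
        assert weighted_pathway_score(counts, ones).scores["S0"] == 3

    def test_missing_weight_rejected(self):
        counts = pd.DataFrame({"a": [1]}, index=["S0"])
        with pytest.raises(LDError):
            weighted_pathway_score(counts, pd.Series([1.0], index=["zzz"]))

    def test_duplication_invariance_on_genotypes(self):
        """Adding a perfect-LD copy of every SNP leaves weighted scores put."""
        rng = np.random.default_rng(4)
        base = {f"v{i}": rng.integers(0, 3, size=40) for i in range(10)}
        g1 = _matrix(base, pos=list(range(1000, 1000 + 10)))
        dup = {}
        for i in range(10):
            dup[f"v{i}"] = base[f"v{i}"]
            dup[f"v{i}dup"] = base[f"v{i}"]
        g2 = _matrix(dup, pos=list(range(1000, 1000 + 20)))
        c1 = minor_allele_count_matrix(g1, major_minor_alleles(g1))
        c2 = minor_allele_count_matrix(g2, major_minor_alleles(g2))
        s1 = weighted_pathway_score(c1, ld_weights(g1, g1.variant_ids)).scores
        s2 = weighted_pathway_score(c2, ld_weights(g2, g2.variant_ids)).scores
        assert np.allclose(s1, s2, atol=1e-9)
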