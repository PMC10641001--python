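"""Distances, Neighbor-Joining, bootstrap supports, rooting, cluster calls."""

import math

import numpy as np
import pytest

from noduplex import (
    Alignment,
    DistanceMatrix,
    SaturationError,
    assign_clusters,
    bipartitions,
    bootstrap_support,
    collapse_low_support,
    gen_strain_library,
    neighbor_joining,
    pairwise_distance,
    root_with_outgroup,
)
from _oracles import best_topology_by_ls, edge_splits, ls_fit, random_additive_tree


def _aln(taxa_rows):
    taxa, rows = zip(*taxa_rows)
    return Alignment(taxa=list(taxa), rows=list(rows))


class TestPairwiseDistance:
    def test_identical_sequences_zero_for_all_models(self):
        aln = _aln([("a", "ACGT" * 25), ("b", "ACGT" * 25)])
        for model in ("p", "JC69", "K2P"):
            d = pairwise_distance(aln, model=model)
            assert d.matrix[0, 1] == 0.0

    def test_p_distance_counts_mismatches(self):
        base = "A" * 100
        other = "C" * 10 + "A" * 90
        d = pairwise_distance(_aln([("a", base), ("b", other)]), model="p")
        assert d.matrix[0, 1] == pytest.approx(0.10, abs=1e-15)

    def test_jc69_closed_form(self):
        base = "A" * 100
        other = "C" * 10 + "A" * 90
        d = pairwise_distance(_aln([("a", base), ("b", other)]), model="JC69")
        assert d.matrix[0, 1] == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), rel=1e-12)

    def test_jc_exceeds_p_distance(self):
        lib = gen_strain_library(seed=5, clade_divergence=0.2)
        aln = Alignment.from_library(lib)
        dp = pairwise_distance(aln, model="p").matrix
        dj = pairwise_distance(aln, model="JC69").matrix
        off = ~np.eye(len(aln.taxa), dtype=bool)
        assert (dj[off] >= dp[off]).all()
        assert (dj[off & (dp > 0)] > dp[off & (dp > 0)]).all()

    def test_k2p_transition_transversion(self):
        # 10 transitions (A->G), 10 transversions (A->C) over 100 sites
        a = "A" * 100
        b = "G" * 10 + "C" * 10 + "A" * 80
        d = pairwise_distance(_aln([("a", a), ("b", b)]), model="K2P").matrix[0, 1]
        P, Q = 0.10, 0.10
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert d == pytest.approx(expected, rel=1e-12)

    def test_saturation_names_pair(self):
        a = "A" * 100
        b = "C" * 80 + "A" * 20
        with pytest.raises(SaturationError, match="tax2"):
            pairwise_distance(_aln([("tax1", a), ("tax2", b)]), model="JC69")

    def test_pairwise_vs_complete_deletion(self):
        aln = _aln([("a", "ACGTACGTAC"), ("b", "ACGTACGTA-"), ("c", "NCGTACGTAC")])
        dp = pairwise_distance(aln, model="p", pairwise_deletion=True)
        assert dp.matrix[0, 1] == 0.0  # 9 comparable columns, none differ
        dc = pairwise_distance(aln, model="p", pairwise_deletion=False)
        assert dc.matrix[0, 1] == 0.0  # 8 columns survive complete deletion


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(taxa=["a", "b", "c"],
                           matrix=np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]]))
        tree = neighbor_joining(D)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        # three-point formulas: a=(3+4-5)/2=1, b=(3+5-4)/2=2, c=(4+5-3)/2=3
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_matrix_exact_recovery(self, n):
        """NJ recovers the generating topology and branch lengths to 1e-12
        on additive matrices (checked against exhaustive least-squares)."""
        rng = np.random.default_rng(100 + n)
        for _ in range(20):
            edges, lengths, D = random_additive_tree(n, rng)
            taxa = [f"t{i}" for i in range(n)]
            tree = neighbor_joining(DistanceMatrix(taxa=taxa, matrix=D))
            # oracle: exhaustive LS over all topologies
            o_edges, o_lengths, o_rss = best_topology_by_ls(n, D)
            assert o_rss < 1e-18
            true_splits = {
                frozenset(taxa[i] for i in s)
                for s in edge_splits(edges, n).values()
                if 1 < len(s) < n - 1
            }
            oracle_splits = {
                frozenset(taxa[i] for i in s)
                for s in edge_splits(o_edges, n).values()
                if 1 < len(s) < n - 1
            }
            assert bipartitions(tree) == true_splits == oracle_splits
            # branch lengths: compare pendant edges by taxon label
            nj_pendant = {lf.taxon.label: lf.edge.length
                          for lf in tree.leaf_node_iter()}
            o_splits_all = edge_splits(edges, n)
            for idx, (u, v) in enumerate(edges):
                leaf = v if v < n else (u if u < n else None)
                if leaf is not None:
                    assert nj_pendant[taxa[leaf]] == pytest.approx(
                        lengths[idx], abs=1e-12)
            # internal edges by bipartition
            nj_internal = {}
            for nd in tree.preorder_node_iter():
                if nd.parent_node is None or nd.is_leaf():
                    continue
                side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                comp = frozenset(taxa) - side
                if 1 < len(side) < n - 1:
                    canon = min(side, comp, key=lambda s: (len(s), tuple(sorted(s))))
                    nj_internal[canon] = nd.edge.length
            for idx, split in o_splits_all.items():
                if 1 < len(split) < n - 1:
                    key = frozenset(taxa[i] for i in split)
                    assert nj_internal[key] == pytest.approx(lengths[idx], abs=1e-12)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(taxa=["a", "b"], matrix=np.array([[0, 1.0], [2.0, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(taxa=["a", "b"], matrix=np.array([[0, -1.0], [-1.0, 0]]))

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = 6
            # perturbed (non-additive) matrices can push NJ lengths negative
            _, _, D = random_additive_tree(n, rng)
            noise = rng.normal(0, 0.05, size=D.shape)
            D2 = np.abs(D + noise + noise.T)
            np.fill_diagonal(D2, 0.0)
            D2 = (D2 + D2.T) / 2
            tree = neighbor_joining(DistanceMatrix(taxa=[f"t{i}" for i in range(n)],
                                                   matrix=D2))
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    assert edge.length >= 0.0


class TestBootstrap:
    def test_fixed_seed_reproducible(self, library):
        aln = Alignment.from_library(library)
        t1, i1 = bootstrap_support(aln, n_replicates=30, seed=5)
        t2, i2 = bootstrap_support(aln, n_replicates=30, seed=5)
        s1 = sorted(nd.support for nd in t1 if not nd.is_leaf() and hasattr(nd, "support"))
        s2 = sorted(nd.support for nd in t2 if not nd.is_leaf() and hasattr(nd, "support"))
        assert s1 == s2
        assert i1 == i2

    def test_two_clade_signal_saturates_support(self):
        rows = ["A" * 150 + "C" * 150] * 3 + ["G" * 150 + "T" * 150] * 3
        aln = Alignment(taxa=[f"x{i}" for i in range(6)], rows=rows)
        tree, info = bootstrap_support(aln, model="p", n_replicates=50, seed=1)
        clade = frozenset(["x0", "x1", "x2"])
        supports = {}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None or nd.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            supports[side] = nd.support
        assert any(
            s == 100.0 and (side == clade or side == frozenset(aln.taxa) - clade)
            for side, s in supports.items()
        )

    def test_taxon_order_permutation_invariant_supports(self, library):
        aln = Alignment.from_library(library)
        order = np.random.default_rng(3).permutation(len(aln.taxa))
        aln2 = Alignment(taxa=[aln.taxa[i] for i in order],
                         rows=[aln.rows[i] for i in order])

        def split_supports(tree):
            out = {}
            n = len(aln.taxa)
            full = frozenset(aln.taxa)
            for nd in tree.preorder_node_iter():
                if nd.parent_node is None or nd.is_leaf():
                    continue
                side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                if 1 < len(side) < n - 1:
                    canon = min(side, full - side,
                                key=lambda s: (len(s), tuple(sorted(s))))
                    out[canon] = nd.support
            return out

        t1, _ = bootstrap_support(aln, n_replicates=40, seed=9)
        t2, _ = bootstrap_support(aln2, n_replicates=40, seed=9)
        s1, s2 = split_supports(t1), split_supports(t2)
        assert set(s1) == set(s2)
        # per-replicate column draws are identical (same seed, same length),
        # so each shared bipartition receives the same support
        assert s1 == s2


class TestCollapseAndRoot:
    def _supported_tree(self):
        lib = gen_strain_library(seed=4, n_reference=4, n_indigenous=2,
                                 its_len=300, clade_divergence=0.12)
        aln = Alignment.from_library(lib)
        tree, _ = bootstrap_support(aln, n_replicates=25, seed=2)
        return lib, tree

    def test_threshold_zero_keeps_all_edges(self):
        _, tree = self._supported_tree()
        before = bipartitions(tree)
        after = bipartitions(collapse_low_support(tree, 0.0))
        assert before == after

    def test_collapse_below_threshold(self):
        _, tree = self._supported_tree()
        kept = {
            s: nd
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None and not nd.is_leaf()
            for s in [frozenset(lf.taxon.label for lf in nd.leaf_iter())]
        }
        collapsed = collapse_low_support(tree, 50.0)
        survivors = bipartitions(collapsed)
        n = len(list(tree.leaf_node_iter()))
        full = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        for side, nd in kept.items():
            if 1 < len(side) < n - 1:
                canon = min(side, full - side, key=lambda s: (len(s), tuple(sorted(s))))
                assert (canon in survivors) == (nd.support >= 50.0)

    def test_full_collapse_gives_star(self):
        _, tree = self._supported_tree()
        star = collapse_low_support(tree, 101.0)
        assert bipartitions(star) == set()
        assert {lf.taxon.label for lf in star.leaf_node_iter()} == {
            lf.taxon.label for lf in tree.leaf_node_iter()
        }

    def test_rooting_preserves_bipartitions_and_leaves(self, library):
        aln = Alignment.from_library(library)
        tree = neighbor_joining(pairwise_distance(aln))
        rooted = root_with_outgroup(tree, "OUTGROUP")
        assert rooted.is_rooted
        assert bipartitions(rooted) == bipartitions(tree)
        assert {lf.taxon.label for lf in rooted.leaf_node_iter()} == set(aln.taxa)
        root_children = rooted.seed_node.child_nodes()
        assert len(root_children) == 2
        sides = [{lf.taxon.label for lf in c.leaf_iter()} for c in root_children]
        assert {"OUTGROUP"} in sides

    def test_reference_clades_monophyletic_after_rooting(self, library):
        aln = Alignment.from_library(library)
        tree, _ = bootstrap_support(aln, n_replicates=20, seed=8)
        rooted = root_with_outgroup(tree, "OUTGROUP")
        splits = bipartitions(rooted)
        clade2 = frozenset(s.id for s in library.references if s.clade == "reference-2")
        indig = frozenset(s.id for s in library.indigenous)
        assert clade2 in splits
        assert indig in splits

    def test_missing_outgroup_label_errors(self, library):
        aln = Alignment.from_library(library)
        tree = neighbor_joining(pairwise_distance(aln))
        with pytest.raises(ValueError):
            root_with_outgroup(tree, "nope")


class TestClusterAssignment:
    def test_identical_isolate_assigned_at_zero_distance(self, library):
        g = library.by_tag("G")
        calls = assign_clusters({"iso1": g.its_seq}, library)
        assert calls[0].call == "G"
        assert calls[0].distance == 0.0

    def test_indigenous_isolate_called_novel(self, library):
        seq = library.indigenous[0].its_seq
        calls = assign_clusters({"iso1": seq}, library, novelty_cutoff=0.05)
        assert calls[0].call == "novel"
        assert calls[0].distance > 0.05

    def test_equidistant_tie_flagged_alphabetical(self):
        lib = gen_strain_library(seed=1, n_reference=2, n_indigenous=0,
                                 its_len=200, clade_divergence=0.0)
        # both references identical -> any isolate is equidistant
        calls = assign_clusters({"iso": lib.references[0].its_seq}, lib,
                                novelty_cutoff=0.5)
        assert calls[0].tie
        assert calls[0].nearest == "A"

    def test_length_mismatch_errors(self, library):
        with pytest.raises(ValueError, match="length"):
            assign_clusters({"iso": "ACGT" * 50}, library)
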