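"""Concatenation, p-distances, neighbor joining and RF distances."""

import itertools
import random

import dendropy
import numpy as np
import pandas as pd
import pytest

from mitokit.phylo import (
    GENE_SETS,
    LocusAlignment,
    concatenate_loci,
    nj_tree,
    p_distance_matrix,
    rf_distance,
)
from mitokit.simulate import evolve_alignment


def _random_additive(n, seed):
    """A random tree with strictly positive branch lengths and its exact
    patristic distance matrix."""
    rnd = random.Random(seed)
    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = dendropy.simulate.treesim.uniform_pure_birth_tree(tns, rng=rnd)
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = rnd.uniform(0.05, 1.0)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tns, key=lambda t: t.label)
    D = pd.DataFrame(
        [[pdm.patristic_distance(a, b) for b in taxa] for a in taxa],
        index=[t.label for t in taxa],
        columns=[t.label for t in taxa],
    )
    return tree, D


class TestConcatenate:
    def _loci(self, species=("s1", "s2"), lengths=(4, 6)):
        out = []
        for name, L in zip(("atp1", "cob"), lengths):
            out.append(
                LocusAlignment(name, {sp: "ACGT" * (L // 4) + "A" * (L % 4)
                                      for sp in species})
            )
        return out

    def test_lengths_and_boundaries(self):
        concat = concatenate_loci(self._loci(), gene_set=["atp1", "cob"])
        assert concat.length == 10
        assert concat.partitions == (("atp1", 1, 4), ("cob", 5, 10))

    def test_named_subset(self):
        loci = [
            LocusAlignment(n, {"a": "ACGT", "b": "ACGA"})
            for n in GENE_SETS["all21"]
        ]
        concat = concatenate_loci(loci, gene_set="ccm")
        assert concat.loci == ("ccmB", "ccmC", "ccmFC", "ccmFN")
        assert concat.length == 16

    def test_missing_species_rejected_by_name(self):
        loci = [
            LocusAlignment("atp1", {"a": "ACGT", "b": "ACGT"}),
            LocusAlignment("cob", {"a": "ACGT"}),
        ]
        with pytest.raises(ValueError, match="cob"):
            concatenate_loci(loci, gene_set=["atp1", "cob"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            LocusAlignment("atp1", {"a": "ACGT", "b": "ACG"})

    def test_split_round_trip(self):
        tree = "((A:1,B:1):1,(C:1,D:1):1);"
        loci = [
            evolve_alignment(tree, 60, 0.1, seed=i, name=n)
            for i, n in enumerate(("atp1", "cob", "cox1"))
        ]
        concat = concatenate_loci(loci, gene_set=["atp1", "cob", "cox1"])
        back = concat.split()
        for orig, rec in zip(loci, back):
            assert orig.sequences == rec.sequences


class TestPDistance:
    def test_hand_examples(self):
        a = LocusAlignment("x", {"s1": "ACGT", "s2": "ACGA"})
        d = p_distance_matrix(a)
        assert d.loc["s1", "s2"] == 0.25
        same = LocusAlignment("y", {"s1": "ACGT", "s2": "ACGT"})
        assert p_distance_matrix(same).loc["s1", "s2"] == 0.0

    def test_pairwise_deletion(self):
        a = LocusAlignment("x", {"s1": "AC-T", "s2": "ACGT"})
        assert p_distance_matrix(a).loc["s1", "s2"] == 0.0  # over 3 columns

    def test_no_comparable_columns_rejected(self):
        a = LocusAlignment("x", {"s1": "--AA", "s2": "GG--"})
        with pytest.raises(ValueError):
            p_distance_matrix(a)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame(
            [[0, 2, 3], [2, 0, 3], [3, 3, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        assert nj_tree(d) == "(a:1,b:1,c:2);"

    def test_ultrametric_four_taxa(self):
        # ((A,B),(C,D)) with heights 1 and 3
        d = pd.DataFrame(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        assert rf_distance(nj_tree(d), "((A,B),(C,D));") == 0

    def test_additive_matrices_recovered_exactly(self):
        """Topology and branch lengths both recovered from 30 random
        additive matrices, n in [4, 10]."""
        for seed in range(30):
            n = 4 + seed % 7
            tree, D = _random_additive(n, seed)
            nwk = nj_tree(D)
            assert rf_distance(nwk, tree.as_string(schema="newick")) == 0
            t2 = dendropy.Tree.get(
                data=nwk, schema="newick",
                taxon_namespace=tree.taxon_namespace,
            )
            pdm = t2.phylogenetic_distance_matrix()
            for a in tree.taxon_namespace:
                for b in tree.taxon_namespace:
                    assert abs(
                        pdm.patristic_distance(a, b) - D.loc[a.label, b.label]
                    ) < 1e-8

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame(
            [[0, 1, 2], [9, 0, 1], [2, 1, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        with pytest.raises(ValueError):
            nj_tree(d)

    def test_agrees_with_reference_implementation(self):
        """Cross-check against scikit-bio's neighbor joining on a noisy
        (non-additive) matrix: same unrooted topology."""
        import io

        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(7)
        _tree, D = _random_additive(7, 99)
        noisy = D + rng.uniform(0, 0.01, D.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy.values, 0.0)
        ours = nj_tree(noisy)
        theirs = sk_nj(SkDM(noisy.values, ids=list(noisy.index)))
        assert rf_distance(ours, str(theirs)) == 0

    def test_concatenation_order_invariance(self):
        tree = "((A:1,B:1):1,(C:1,D:1):1);"
        loci = [
            evolve_alignment(tree, 300, 0.05, seed=i, name=n)
            for i, n in enumerate(("atp1", "cob", "cox1"))
        ]
        d1 = p_distance_matrix(concatenate_loci(loci, ["atp1", "cob", "cox1"]))
        d2 = p_distance_matrix(concatenate_loci(loci, ["cox1", "atp1", "cob"]))
        assert np.allclose(d1.values, d2.values)


class TestRobinsonFoulds:
    def test_identical_zero(self):
        t = "((A,B),(C,D),E);"
        assert rf_distance(t, t) == 0

    def test_four_taxon_alternatives(self):
        assert rf_distance("((A,B),(C,D));", "((A,C),(B,D));") == 2

    def test_tip_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rf_distance("((A,B),C);", "((A,B),D);")

    def test_matches_bipartition_enumeration(self):
        """Random 8-taxon pairs agree with an explicit bipartition-set
        comparison done directly on the trees."""

        def bipartitions(newick):
            tree = dendropy.Tree.get(data=newick, schema="newick")
            tree.is_rooted = False
            all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
            out = set()
            for node in tree.preorder_node_iter():
                if node.is_leaf() or node is tree.seed_node:
                    continue
                below = frozenset(l.taxon.label for l in node.leaf_iter())
                if 1 < len(below) < len(all_tips) - 1:
                    out.add(min(below, all_tips - below, key=sorted))
            return out

        for seed in range(15):
            t1, _ = _random_additive(8, 1000 + seed)
            t2, _ = _random_additive(8, 2000 + seed)
            n1, n2 = (t.as_string(schema="newick") for t in (t1, t2))
            expect = len(bipartitions(n1) ^ bipartitions(n2))
            assert rf_distance(n1, n2) == expect


class TestEvolvedPanel:
    def test_nj_recovers_generating_topology(self):
        """Sequences evolved down a clock-like 8-taxon tree yield an NJ tree
        at RF 0 from the truth once the alignment is long enough."""
        tree = ("(((A:1,B:1):1,(C:1,D:1):1):1,"
                "((E:1,F:1):1,(G:1,H:1):1):1);")
        loci = [
            evolve_alignment(tree, 1500, 0.02, seed=i, name=f"locus{i}")
            for i in range(3)
        ]
        concat = concatenate_loci(loci, [l.name for l in loci])
        nwk = nj_tree(p_distance_matrix(concat))
        assert rf_distance(nwk, tree) == 0
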