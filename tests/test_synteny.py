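"""Circular gene orders, shared adjacencies and syntenic cluster counts."""

import itertools

import numpy as np
import pytest

from mitokit.simulate import (
    SimConfig,
    generate_mt_genome,
    generate_related_pair,
    genome_from_order,
)
from mitokit.synteny import (
    cluster_status,
    conserved_clusters,
    count_synteny_clusters,
    extract_gene_order,
    find_gene_clusters,
    presence_grid,
    shared_adjacencies,
    synteny_matrix,
)


def _order(entries, species="s", seed=0):
    return extract_gene_order(
        genome_from_order(entries, seed=seed, species=species)
    )


def _brute_force_pairs(e1, e2):
    """Independent O(n^2) oracle: distinct unordered label pairs that are
    circular neighbours with the same relative orientation in both orders."""

    def adjacencies(entries):
        n = len(entries)
        out = set()
        for i in range(n):
            (la, sa), (lb, sb) = entries[i], entries[(i + 1) % n]
            rel = sa == sb
            out.add((frozenset((la, lb)) if la != lb else frozenset((la,)), rel))
            if n == 2:
                break
        return out

    both = adjacencies(e1) & adjacencies(e2)
    return len({pair for pair, _rel in both})


class TestExtractOrder:
    def test_categories_and_blocks(self, small_genome):
        mt, _cp, truth = small_genome
        order = extract_gene_order(mt)
        assert list(order.entries) == truth.gene_order
        labels = [e[0] for e in order.entries]
        assert "nad1a" in labels and "nad1bc" in labels  # trans blocks split
        assert not any(l.startswith("trn") for l in labels)
        assert "rps19" not in labels  # remnant excluded

    def test_duplicate_copies_share_label(self):
        g = genome_from_order(
            [("cob", "+"), ("rrn26", "+"), ("atp9", "+"), ("rrn26", "-")], seed=3
        )
        order = extract_gene_order(g)
        assert [e[0] for e in order.entries].count("rrn26") == 2

    def test_empty_order_warns(self):
        g = genome_from_order([("x", "+")], seed=4)
        g.features = []
        with pytest.warns(UserWarning):
            assert extract_gene_order(g).entries == ()


class TestSharedAdjacencies:
    def test_identical_circular_orders(self):
        e = [(c, "+") for c in "abcdef"]
        assert len(shared_adjacencies(_order(e), _order(e, seed=1))) == 6

    def test_disjoint_gene_sets(self):
        e1 = [(c, "+") for c in "abc"]
        e2 = [(c, "+") for c in "xyz"]
        assert shared_adjacencies(_order(e1), _order(e2)) == set()

    def test_orientation_must_agree(self):
        e1 = [("a", "+"), ("b", "+"), ("c", "+"), ("d", "+")]
        # flipping b alone breaks both of its adjacencies' orientations
        e2 = [("a", "+"), ("b", "-"), ("c", "+"), ("d", "+")]
        shared = shared_adjacencies(_order(e1), _order(e2, seed=2))
        pairs = {adj.pair for adj in shared}
        assert ("a", "b") not in pairs and ("b", "c") not in pairs
        assert ("c", "d") in pairs and ("a", "d") in pairs

    def test_internal_inversion_loses_two(self):
        n = 8
        e1 = [(f"g{i}", "+") for i in range(n)]
        e2 = list(e1)
        e2[2:5] = [(l, "-") for l, _s in reversed(e2[2:5])]
        assert len(shared_adjacencies(_order(e1), _order(e2, seed=5))) == n - 2


class TestCounts:
    def test_pair_and_run_modes_identical_orders(self):
        e = [(c, "+") for c in "abcdef"]
        o1, o2 = _order(e), _order(e, seed=1)
        assert count_synteny_clusters(o1, o2, "pair") == 6
        assert count_synteny_clusters(o1, o2, "run") == 1

    def test_single_shared_pair(self):
        e1 = [("a", "+"), ("b", "+"), ("c", "+"), ("d", "+")]
        e2 = [("a", "+"), ("b", "+"), ("d", "+"), ("c", "+")]
        # neighbours of the circular pair: only a-b survives intact with
        # orientations; check run mode counts it once
        pair = count_synteny_clusters(_order(e1), _order(e2, seed=6), "pair")
        run = count_synteny_clusters(_order(e1), _order(e2, seed=7), "run")
        assert run <= pair

    def test_unknown_mode_rejected(self):
        e = [(c, "+") for c in "abc"]
        with pytest.raises(ValueError):
            count_synteny_clusters(_order(e), _order(e), mode="blocks")

    def test_matches_brute_force_on_random_pairs(self):
        """Pair-mode counts equal the independent O(n^2) oracle on >= 200
        random circular permutation pairs, n <= 12."""
        rng = np.random.default_rng(0)
        for trial in range(200):
            n = int(rng.integers(3, 13))
            labels = [f"g{i}" for i in range(n)]
            e1 = [
                (l, "+-"[int(rng.integers(0, 2))])
                for l in rng.permutation(labels)
            ]
            e2 = [
                (l, "+-"[int(rng.integers(0, 2))])
                for l in rng.permutation(labels)
            ]
            got = count_synteny_clusters(
                _order(e1, seed=trial), _order(e2, seed=1000 + trial), "pair"
            )
            assert got == _brute_force_pairs(e1, e2), (trial, e1, e2)

    def test_inversion_property_all_sizes(self):
        """Any single internal k-block inversion of an n-gene circular order
        leaves exactly n-2 shared adjacencies, for all 2 <= k <= n-2."""
        for n in range(4, 13):
            base = [(f"g{i}", "+") for i in range(n)]
            for k in range(2, n - 1):
                inv = list(base)
                inv[1 : 1 + k] = [(l, "-") for l, _s in reversed(inv[1 : 1 + k])]
                got = count_synteny_clusters(
                    _order(base, seed=n), _order(inv, seed=100 * n + k), "pair"
                )
                assert got == n - 2, (n, k)


class TestMatrix:
    def test_symmetry_and_diagonal(self):
        gs = [
            genome_from_order([(c, "+") for c in "abcde"], seed=i, species=f"s{i}")
            for i in range(3)
        ]
        mat = synteny_matrix(gs)
        assert (mat.values == mat.values.T).all()
        assert (np.diag(mat.values) == 5).all()

    def test_upper_bound(self, small_genome):
        mt, _cp, _ = small_genome
        o = extract_gene_order(mt)
        assert count_synteny_clusters(o, o, "pair") <= len(o)


class TestClusterStatus:
    def test_missing_member_wins(self):
        g = genome_from_order([("cob", "+"), ("atp9", "+")], seed=8)
        assert cluster_status(["cob", "rps14"], g) == "member_missing"

    def test_intact_cluster_present(self, small_genome):
        mt, _cp, truth = small_genome
        for labels, _strands in truth.clusters.values():
            assert cluster_status(labels, mt) == "present"

    def test_reverse_direction_counts_as_present(self):
        g = genome_from_order(
            [("rps14", "-"), ("cob", "-"), ("atp9", "+")], seed=9
        )
        assert cluster_status(["cob", "rps14"], g) == "present"

    def test_split_cluster_broken(self):
        g = genome_from_order(
            [("cob", "+"), ("atp9", "+"), ("rps14", "+"), ("nad3", "+")], seed=10
        )
        assert cluster_status(["cob", "rps14"], g) == "broken"

    def test_short_cluster_rejected(self, small_genome):
        mt, _cp, _ = small_genome
        with pytest.raises(ValueError):
            cluster_status(["cob"], mt)

    def test_presence_grid_symbols(self):
        g1 = genome_from_order([("cob", "+"), ("rps14", "+"), ("nad3", "+")], seed=11, species="s1")
        g2 = genome_from_order(
            [("cob", "+"), ("nad3", "+"), ("rps14", "+"), ("atp9", "+")],
            seed=12, species="s2",
        )
        g3 = genome_from_order([("cob", "+"), ("nad3", "+")], seed=13, species="s3")
        grid = presence_grid([g1, g2, g3], [["cob", "rps14"]])
        assert list(grid["cob-rps14"]) == ["+", "-", "#"]


class TestConservedClusters:
    def _panel(self):
        """Five universal adjacencies plus one monocot-specific one.

        Universal: the circular a-b-c-d-e backbone (5 adjacencies); the
        monocots insert m between e and a consistently (e-m and m-a),
        while dicots carry m elsewhere, splitting differently.
        """
        base = ["a", "b", "c", "d", "e"]
        monocot = [(x, "+") for x in base] + [("m", "+")]
        dicot1 = [("a", "+"), ("b", "+"), ("c", "+"), ("d", "+"),
                  ("m", "+"), ("x1", "+"), ("e", "+")]
        dicot2 = [("a", "+"), ("b", "+"), ("c", "+"), ("d", "+"),
                  ("m", "+"), ("x2", "+"), ("e", "+")]
        gs = [
            genome_from_order(monocot, seed=20, species="mono1", group="monocot"),
            genome_from_order(monocot, seed=21, species="mono2", group="monocot"),
            genome_from_order(dicot1, seed=22, species="dic1", group="dicot"),
            genome_from_order(dicot2, seed=23, species="dic2", group="dicot"),
        ]
        return gs

    def test_engineered_universal_and_group_specific(self):
        res = conserved_clusters(self._panel())
        universal = {adj.pair for adj in res["universal"]}
        assert {("a", "b"), ("b", "c"), ("c", "d")} <= universal
        mono = {adj.pair for adj in res["monocot"]}
        assert ("e", "m") in mono and ("a", "m") in mono

    def test_all_identical_everything_universal(self):
        e = [(c, "+") for c in "abcde"]
        gs = [
            genome_from_order(e, seed=i, species=f"s{i}", group="dicot")
            for i in range(3)
        ]
        res = conserved_clusters(gs)
        assert len(res["universal"]) == 5

    def test_missing_gene_is_non_informative(self):
        """A genome lacking one member never vetoes the adjacency."""
        full = [("a", "+"), ("b", "+"), ("c", "+")]
        lacking = [("a", "+"), ("c", "+")]
        gs = [
            genome_from_order(full, seed=30, species="s1", group="dicot"),
            genome_from_order(full, seed=31, species="s2", group="dicot"),
            genome_from_order(lacking, seed=32, species="s3", group="monocot"),
        ]
        res = conserved_clusters(gs)
        assert ("a", "b") in {adj.pair for adj in res["universal"]}


class TestRelatedPairTruth:
    def test_counts_match_generator_truth(self):
        """Scripted inversion/transposition genomes: the module count always
        equals the truth table's independently enumerated count."""
        rng = np.random.default_rng(3)
        for trial in range(25):
            cfg = SimConfig.small(seed=500 + trial)
            n_inv = int(rng.integers(0, 3))
            n_tr = int(rng.integers(0, 2))
            a, b, truth = generate_related_pair(
                cfg, n_inversions=n_inv, n_transpositions=n_tr
            )
            got = count_synteny_clusters(
                extract_gene_order(a), extract_gene_order(b), "pair"
            )
            assert got == truth.shared_adjacencies, (trial, n_inv, n_tr)

    def test_zero_operations_identity(self):
        cfg = SimConfig.small(seed=900)
        a, b, truth = generate_related_pair(cfg, 0, 0)
        oa, ob = extract_gene_order(a), extract_gene_order(b)
        assert [e[0] for e in oa.entries] != []
        assert truth.shared_adjacencies == count_synteny_clusters(oa, ob)
        assert truth.shared_adjacencies == len(
            {frozenset(p) for p in zip([e[0] for e in oa.entries],
                                       [e[0] for e in oa.entries][1:]
                                       + [oa.entries[0][0]])}
        )


class TestFindGeneClusters:
    def test_planted_clusters_found(self, small_genome):
        mt, _cp, truth = small_genome
        found = {"-".join(c["labels"]) for c in find_gene_clusters(mt)}
        expected = {"-".join(labels) for labels, _ in truth.clusters.values()}
        assert found == expected

    def test_gaps_match_plan(self, small_genome):
        mt, _cp, _ = small_genome
        by_name = {"-".join(c["labels"]): c for c in find_gene_clusters(mt)}
        assert by_name["cob-rps14"]["gaps"] == [1363]
        assert by_name["nad3-rps12"]["gaps"] == [48]
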