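"""tRNA origin classification and gain/loss parsimony on a species tree."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from mitokit.model import AnnotatedGenome, GeneFeature, Genome, Interval
from mitokit.simulate import (
    SimConfig,
    generate_mt_genome,
    generate_species_set,
    mutate_sequence,
    random_sequence,
)
from mitokit.trna import (
    annotate_trna_origins,
    build_distribution,
    classify_trna_origin,
    infer_gain_loss,
)


def _cp_with_trna(label="trnW(CCA)", length=80, seed=1):
    seq = random_sequence(4000, seed=seed)
    f = GeneFeature(label, "tRNA", (Interval(1001, 1000 + length, "+"),))
    return AnnotatedGenome(Genome("cp", seq), [f], species="cp")


class TestClassify:
    def test_identical_to_cp_is_cp_like(self):
        cp = _cp_with_trna()
        seq = cp.feature_sequence(cp.features[0])
        origin, ident = classify_trna_origin(seq, cp, label="trnW(CCA)")
        assert origin == "cp_like" and ident == 100.0

    def test_boundary_identity_inclusive(self):
        """Exactly 85% identity (12 substitutions over 80 nt) still counts
        as cp-like: the floor is inclusive."""
        cp = _cp_with_trna(length=80)
        ref = cp.feature_sequence(cp.features[0])
        # substitute every 7th base: 12 evenly spread substitutions that no
        # gapped alignment can shortcut, leaving identity at exactly 85%
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        seq = "".join(
            flip[c] if i % 7 == 0 and i < 78 else c for i, c in enumerate(ref)
        )
        origin, ident = classify_trna_origin(seq, cp, label="trnW(CCA)")
        assert ident == 85.0
        assert origin == "cp_like"

    def test_diverged_is_native(self):
        cp = _cp_with_trna()
        origin, ident = classify_trna_origin(
            random_sequence(80, seed=4), cp, label="trnW(CCA)"
        )
        assert origin == "native" and ident < 85

    def test_no_cp_genome_rejected(self):
        with pytest.raises(ValueError):
            classify_trna_origin("ACGT" * 20, None)

    def test_annotations_match_generator_truth(self, small_genome):
        mt, cp, truth = small_genome
        called = annotate_trna_origins(mt, cp)
        assert sorted((t.label, t.origin) for t in called) == sorted(
            (label, origin) for label, origin, _iv in truth.trnas
        )


class TestDistribution:
    def test_disjoint_sets_complement(self):
        from mitokit.trna import TrnaGene

        a = [TrnaGene("trnA(TGC)", "native", Interval(1, 72), 50.0)]
        b = [TrnaGene("trnB(XXX)", "cp_like", Interval(1, 72), 95.0)]
        grid = build_distribution({"s1": a, "s2": b})
        assert grid.loc["s1", "trnA(TGC)"] == "native"
        assert grid.loc["s2", "trnA(TGC)"] == "absent"
        assert grid.loc["s2", "trnB(XXX)(cp)"] == "cp_like"
        assert grid.loc["s1", "trnB(XXX)(cp)"] == "absent"

    def test_duplicates_collapse(self):
        from mitokit.trna import TrnaGene

        dup = [
            TrnaGene("trnM(CAT)", "cp_like", Interval(1, 72), 99.0),
            TrnaGene("trnM(CAT)", "cp_like", Interval(500, 571), 99.0),
        ]
        grid = build_distribution({"s": dup})
        assert list(grid.columns) == ["trnM(CAT)(cp)"]
        assert grid.loc["s", "trnM(CAT)(cp)"] == "cp_like"

    def test_native_and_cp_like_variants_are_distinct_characters(self):
        from mitokit.trna import TrnaGene

        both = [
            TrnaGene("trnP(TGG)", "native", Interval(1, 72), 60.0),
            TrnaGene("trnP(TGG)", "cp_like", Interval(500, 571), 97.0),
        ]
        grid = build_distribution({"s": both})
        assert set(grid.columns) == {"trnP(TGG)", "trnP(TGG)(cp)"}


TREE6 = "((A,B),((C,D),(E,F)));"


def _brute_force_minimum(tree: dendropy.Tree, present: set, model: str) -> int:
    """Exhaustive minimum event count over all internal presence labelings.

    The virtual ancestor of the root is absent for Dollo characters (the
    single gain must be paid somewhere) and present for native ones; Dollo
    allows at most one gain, loss-only forbids gains entirely.
    """
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best = None
    for states in itertools.product([False, True], repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), states))

        def state_of(node):
            if node.is_leaf():
                return node.taxon.label in present
            return assign[id(node)]

        gains = losses = 0
        root_parent = model == "loss_only"  # virtual ancestor state
        for node in tree.preorder_node_iter():
            parent = (
                root_parent
                if node is tree.seed_node
                else state_of(node.parent_node)
            )
            if state_of(node) and not parent:
                gains += 1
            elif parent and not state_of(node):
                losses += 1
        if model == "dollo" and gains > 1:
            continue
        if model == "loss_only" and gains > 0:
            continue
        total = gains + losses
        if best is None or total < best:
            best = total
    return best


class TestGainLoss:
    def _tree(self):
        t = dendropy.Tree.get(data=TREE6, schema="newick")
        t.is_rooted = True
        return t

    def test_present_everywhere_single_root_gain(self):
        grid = pd.DataFrame({"x(cp)": ["cp_like"] * 6}, index=list("ABCDEF"))
        ga = infer_gain_loss(grid, self._tree())
        assert ga.total_events == 1
        [(branch, et)] = ga.events_for("x(cp)")
        assert et == "gain" and branch == tuple("ABCDEF")

    def test_single_tip_gain_on_terminal_branch(self):
        grid = pd.DataFrame(
            {"y(cp)": ["cp_like"] + ["absent"] * 5}, index=list("ABCDEF")
        )
        ga = infer_gain_loss(grid, self._tree())
        assert ga.total_events == 1
        [(branch, et)] = ga.events_for("y(cp)")
        assert et == "gain" and branch == ("A",)

    def test_native_loss_on_maximal_absent_subtree(self):
        grid = pd.DataFrame(
            {"trnC": ["native", "native", "absent", "absent", "native", "native"]},
            index=list("ABCDEF"),
        )
        ga = infer_gain_loss(grid, self._tree())
        assert ga.total_events == 1
        [(branch, et)] = ga.events_for("trnC")
        assert et == "loss" and branch == ("C", "D")

    def test_tip_mismatch_rejected(self):
        grid = pd.DataFrame({"x": ["native"]}, index=["Z"])
        with pytest.raises(ValueError):
            infer_gain_loss(grid, self._tree())

    def test_event_totals_equal_exhaustive_minima(self):
        """Random 6-taxon grids: placements attain the brute-force minimum
        for both the Dollo and the loss-only model."""
        rng = np.random.default_rng(0)
        tips = list("ABCDEF")
        for trial in range(150):
            cp_col = rng.random(6) < 0.5
            nat_col = rng.random(6) < 0.6
            grid = pd.DataFrame(
                {
                    "z(cp)": np.where(cp_col, "cp_like", "absent"),
                    "trnZ": np.where(nat_col, "native", "absent"),
                },
                index=tips,
            )
            tree = self._tree()
            ga = infer_gain_loss(grid, tree)
            expect = _brute_force_minimum(
                tree, {t for t, p in zip(tips, cp_col) if p}, "dollo"
            ) + _brute_force_minimum(
                tree, {t for t, p in zip(tips, nat_col) if p}, "loss_only"
            )
            assert ga.total_events == expect, trial

    def test_replay_reproduces_tip_grid(self):
        rng = np.random.default_rng(1)
        tips = list("ABCDEF")
        for _ in range(30):
            grid = pd.DataFrame(
                {
                    "a(cp)": np.where(rng.random(6) < 0.5, "cp_like", "absent"),
                    "trnA": np.where(rng.random(6) < 0.5, "native", "absent"),
                },
                index=tips,
            )
            tree = self._tree()
            ga = infer_gain_loss(grid, tree)
            replay = ga.replay(tree)
            for ch in grid.columns:
                assert (replay[ch] == (grid[ch] != "absent")).all()

    def test_total_invariant_under_tip_order(self):
        rng = np.random.default_rng(2)
        tips = list("ABCDEF")
        grid = pd.DataFrame(
            {"b(cp)": np.where(rng.random(6) < 0.5, "cp_like", "absent")},
            index=tips,
        )
        t1 = infer_gain_loss(grid, self._tree()).total_events
        t2 = infer_gain_loss(
            grid.loc[list("FEDCBA")], self._tree()
        ).total_events
        assert t1 == t2


class TestScriptedHistory:
    def test_minimal_script_recovered_exactly(self):
        """A scripted gain on an internal branch and a scripted tip loss are
        recovered at the scripted branches by the parsimony placement."""
        tree = "((A:1,B:1):1,(C:1,D:1):1);"
        cfg = SimConfig.small(seed=31)
        events = {
            ("A", "B"): [("gain", "trnF(GAA)")],
            ("D",): [("loss", "trnC(GCA)")],
        }
        genomes, cp, truth = generate_species_set(tree, cfg, events=events)
        grid = build_distribution(
            {g.species: annotate_trna_origins(g, cp) for g in genomes}
        )
        ga = infer_gain_loss(grid, tree)
        assert (("A", "B"), "gain") in ga.events_for("trnF(GAA)(cp)")
        assert (("D",), "loss") in ga.events_for("trnC(GCA)")
        # parsimony bound: inferred total <= scripted plus root states
        scripted = ga.total_events
        assert scripted == len(
            [c for c in grid.columns if c.endswith("(cp)")]
        ) + 1  # one root gain per cp-like character, plus the one loss
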