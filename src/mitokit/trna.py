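"""tRNA origin census and gain/loss placement on a species tree.

Mitochondrial tRNA genes are either native (of ancestral mitochondrial
origin) or cp-like (acquired from the chloroplast by DNA transfer). A tRNA
is called cp-like when it aligns to a chloroplast tRNA of the same isotype
above an identity and coverage floor. Presence/absence of each tRNA kind
across species is then explained on a fixed species tree: cp-like
characters under Dollo parsimony (one gain, any number of losses), native
characters under loss-only parsimony (the ancestral mitochondrial set is
primitively present, so gains below the root are forbidden).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import dendropy
import pandas as pd

from . import homology
from .model import AnnotatedGenome, Interval, revcomp  # noqa: F401 (Interval in annotations)

__all__ = [
    "TrnaGene",
    "classify_trna_origin",
    "annotate_trna_origins",
    "build_distribution",
    "GainLossAssignment",
    "infer_gain_loss",
]


@dataclass(frozen=True)
class TrnaGene:
    label: str  # isotype + anticodon, e.g. trnS(GCT)
    origin: str  # native / cp_like
    interval: Interval
    best_cp_identity: float


def _isotype(label: str) -> str:
    return label.split("(")[0]


def classify_trna_origin(
    trna_seq: str,
    cp: AnnotatedGenome,
    label: Optional[str] = None,
    min_identity: float = 85.0,
    min_cov: float = 0.9,
) -> tuple:
    """Classify one mt tRNA sequence as native or cp-like.

    The sequence is aligned (both orientations) against every chloroplast
    tRNA gene — restricted to the same isotype when a label is given and the
    cp annotation contains that isotype. cp_like requires best identity >=
    ``min_identity`` (boundary inclusive) and length coverage >= ``min_cov``.
    Returns ``(origin, best_identity_percent)``.
    """
    if cp is None:
        raise ValueError("a chloroplast genome is required for origin classification")
    cp_trnas = cp.by_category("tRNA")
    if label is not None:
        same = [f for f in cp_trnas if _isotype(f.locus) == _isotype(label)]
        if same:
            cp_trnas = same
    best = 0.0
    for f in cp_trnas:
        ref = cp.feature_sequence(f)
        cov = min(len(trna_seq), len(ref)) / max(len(trna_seq), len(ref))
        if cov < min_cov:
            continue
        for cand in (trna_seq, revcomp(trna_seq)):
            ident, _ = homology.alignment_identity(cand, ref)
            best = max(best, ident)
    return ("cp_like" if best >= min_identity else "native"), best


def annotate_trna_origins(
    mt: AnnotatedGenome,
    cp: AnnotatedGenome,
    min_identity: float = 85.0,
    min_cov: float = 0.9,
) -> list:
    """Origin call for every annotated tRNA gene of an mt genome."""
    out = []
    for f in mt.by_category("tRNA"):
        seq = mt.feature_sequence(f)
        origin, ident = classify_trna_origin(
            seq, cp, label=f.locus, min_identity=min_identity, min_cov=min_cov
        )
        out.append(TrnaGene(f.locus, origin, f.span(mt.genome.length), ident))
    return out


def build_distribution(classified: dict) -> pd.DataFrame:
    """Species x tRNA grid with cells in {native, cp_like, absent}.

    ``classified`` maps species to their :class:`TrnaGene` lists. Native and
    cp-like variants of one isoacceptor are distinct characters (a species
    may carry both); cp-like characters are suffixed ``(cp)``. Duplicate
    copies collapse to a single presence cell.
    """
    columns: set = set()
    per_species: dict = {}
    for sp, genes in classified.items():
        cells = {}
        for t in genes:
            key = t.label + "(cp)" if t.origin == "cp_like" else t.label
            cells[key] = t.origin
        per_species[sp] = cells
        columns.update(cells)
    cols = sorted(columns)
    data = {
        sp: [per_species[sp].get(c, "absent") for c in cols]
        for sp in classified
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


# ------------------------------------------------------------ parsimony


@dataclass
class GainLossAssignment:
    """Per-branch gain/loss events explaining a presence grid on a tree.

    Branches are keyed by the sorted tuple of tip labels below them; the key
    with all tips denotes the root.
    """

    events: dict  # branch key -> list of (event type, character)
    models: dict  # character -> dollo | loss_only
    total_events: int = 0

    def events_for(self, character: str) -> list:
        out = []
        for branch, evs in self.events.items():
            out.extend((branch, et) for et, ch in evs if ch == character)
        return out

    def replay(self, tree: Union[str, dendropy.Tree]) -> pd.DataFrame:
        """Run the events down the tree; returns the implied tip grid
        (True = present) for every character."""
        tree = _as_tree(tree)
        tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        states = {}
        for ch, model in self.models.items():
            tip_state = {}

            def walk(node, state):
                key = _clade_key(node)
                for et, c in self.events.get(key, []):
                    if c != ch:
                        continue
                    state = et == "gain"
                if node.is_leaf():
                    tip_state[node.taxon.label] = state
                else:
                    for child in node.child_nodes():
                        walk(child, state)

            walk(tree.seed_node, model == "loss_only")
            states[ch] = [tip_state[t] for t in tips]
        return pd.DataFrame(states, index=tips)


def _as_tree(tree: Union[str, dendropy.Tree]) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        tree.is_rooted = True
        return tree
    t = dendropy.Tree.get(data=tree, schema="newick")
    t.is_rooted = True  # gain/loss placement needs a direction of time
    return t


def _clade_key(node) -> tuple:
    return tuple(sorted(leaf.taxon.label for leaf in node.leaf_iter()))


def infer_gain_loss(
    dist: pd.DataFrame, tree: Union[str, dendropy.Tree]
) -> GainLossAssignment:
    """Minimal gain/loss placement for every character of a distribution.

    cp-like characters (any ``cp_like`` cell, or a ``(cp)`` suffix) follow
    Dollo parsimony: one gain on the branch above the MRCA of the present
    tips, losses on the maximal subtrees inside that clade lacking the
    character. Native characters follow loss-only parsimony from a present
    root. Both placements delay events as far toward the tips as minimality
    allows and are exact minima for their models.
    """
    tree = _as_tree(tree)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if tips != set(dist.index):
        raise ValueError(
            f"tree tips and grid species differ: {sorted(tips ^ set(dist.index))}"
        )
    events: dict = {}
    models: dict = {}
    total = 0

    def add(node, et, ch):
        nonlocal total
        events.setdefault(_clade_key(node), []).append((et, ch))
        total += 1

    def place_losses(node, present: set):
        """Losses on maximal subtrees containing no present tip."""
        for child in node.child_nodes():
            below = set(_clade_key(child))
            if below & present:
                place_losses(child, present)
            else:
                add(child, "loss", ch)

    for ch in dist.columns:
        col = dist[ch]
        cp_like = ch.endswith("(cp)") or (col == "cp_like").any()
        models[ch] = "dollo" if cp_like else "loss_only"
        present = {sp for sp in dist.index if col[sp] != "absent"}
        if not present:
            if models[ch] == "loss_only":
                add(tree.seed_node, "loss", ch)
            continue
        if models[ch] == "dollo":
            if present == tips:
                mrca = tree.seed_node
            else:
                mrca = tree.mrca(taxon_labels=sorted(present))
            add(mrca, "gain", ch)
            place_losses(mrca, present)
        else:
            place_losses(tree.seed_node, present)
    return GainLossAssignment(events, models, total)
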