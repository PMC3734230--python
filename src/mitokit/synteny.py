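"""Circular gene-order comparison: shared adjacencies and syntenic clusters.

Gene order in plant mt genomes is scrambled by recombination; what survives
between two genomes is a set of conserved gene adjacencies ("any two genes
linked" counts as one syntenic cluster). The order is taken over protein and
rRNA genes only, with trans-spliced exon blocks as separate order units and
duplicate copies sharing one label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .model import AnnotatedGenome

__all__ = [
    "GeneOrder",
    "Adjacency",
    "extract_gene_order",
    "shared_adjacencies",
    "count_synteny_clusters",
    "synteny_matrix",
    "cluster_status",
    "conserved_clusters",
    "presence_grid",
]


@dataclass(frozen=True)
class Adjacency:
    """Unordered neighbour pair with relative orientation.

    Reading the circle in the other direction flips both strands, so the
    relative orientation (same / opposite) is direction-invariant.
    """

    pair: tuple  # sorted label pair
    relative_orientation: str  # same / opposite

    @classmethod
    def of(cls, a: tuple, b: tuple) -> "Adjacency":
        rel = "same" if a[1] == b[1] else "opposite"
        return cls(tuple(sorted((a[0], b[0]))), rel)


@dataclass(frozen=True)
class GeneOrder:
    species: str
    entries: tuple  # circular ordered (label, strand)

    def __len__(self) -> int:
        return len(self.entries)

    def adjacency_keys(self, orientation_aware: bool = True) -> set:
        """Distinct circular adjacencies as hashable keys."""
        n = len(self.entries)
        if n < 2:
            return set()
        keys = set()
        for i in range(n):
            a = self.entries[i]
            b = self.entries[(i + 1) % n]
            if n == 2 and i == 1:
                break  # two genes on a circle share one distinct adjacency
            adj = Adjacency.of(a, b)
            keys.add((adj.pair, adj.relative_orientation if orientation_aware else None))
        return keys


def extract_gene_order(g: AnnotatedGenome) -> GeneOrder:
    """Protein and rRNA features sorted by circular start coordinate.

    tRNAs, pseudogenes and remnants are excluded; trans-spliced blocks enter
    under their block label; duplicate copies each contribute one entry.
    """
    feats = g.by_category("protein", "rRNA")
    if not feats:
        warnings.warn(f"{g.species}: no protein/rRNA features, empty gene order")
        return GeneOrder(g.species, ())
    feats = sorted(feats, key=lambda f: (f.start(), f.label))
    return GeneOrder(g.species, tuple((f.label, f.strand) for f in feats))


def shared_adjacencies(o1: GeneOrder, o2: GeneOrder) -> set:
    """Adjacencies conserved between two circular orders.

    A match requires the unordered label pair and the relative orientation to
    agree; each distinct label pair is counted at most once regardless of how
    many duplicate copies realise it.
    """
    common = o1.adjacency_keys() & o2.adjacency_keys()
    # one Adjacency per distinct label pair
    by_pair: dict = {}
    for pair, rel in common:
        by_pair.setdefault(pair, rel)
    return {Adjacency(pair, rel) for pair, rel in by_pair.items()}


def count_synteny_clusters(o1: GeneOrder, o2: GeneOrder, mode: str = "pair") -> int:
    """Number of syntenic clusters between two genomes.

    ``pair`` counts every conserved adjacency as one cluster (two linked
    genes = one cluster). ``run`` counts maximal chains of >= 2 genes whose
    consecutive adjacencies are all conserved, walking the first order.
    """
    if mode == "pair":
        return len(shared_adjacencies(o1, o2))
    if mode != "run":
        raise ValueError(f"unknown mode {mode!r}")
    n = len(o1.entries)
    if n < 2:
        return 0
    shared_keys = o1.adjacency_keys() & o2.adjacency_keys()
    ok = []
    for i in range(n):
        a, b = o1.entries[i], o1.entries[(i + 1) % n]
        adj = Adjacency.of(a, b)
        ok.append((adj.pair, adj.relative_orientation) in shared_keys)
    if all(ok):
        return 1
    # maximal circular runs of conserved adjacencies = False->True transitions
    runs = 0
    prev = ok[-1]
    for flag in ok:
        if flag and not prev:
            runs += 1
        prev = flag
    return runs


def synteny_matrix(
    genomes: Sequence[AnnotatedGenome], mode: str = "pair"
) -> pd.DataFrame:
    """Symmetric species-by-species cluster-count matrix."""
    orders = [extract_gene_order(g) for g in genomes]
    names = [o.species for o in orders]
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, oi in enumerate(orders):
        for j, oj in enumerate(orders):
            if j < i:
                continue
            c = count_synteny_clusters(oi, oj, mode=mode)
            mat.iloc[i, j] = c
            mat.iloc[j, i] = c
    return mat


def cluster_status(
    cluster: Sequence[str],
    g: AnnotatedGenome,
    strands: Optional[Sequence[str]] = None,
) -> str:
    """Presence state of a gene cluster in one genome.

    ``member_missing`` (#) if any member gene is not annotated at all;
    ``present`` (+) if the members occur consecutively in the circular order,
    in either direction, with conserved relative orientations (the reference
    strand pattern, or all-same-strand when none is given); ``broken`` (−)
    otherwise. Missing members take precedence over broken.
    """
    cluster = list(cluster)
    if len(cluster) < 2:
        raise ValueError("a cluster needs at least two member genes")
    order = extract_gene_order(g)
    labels = [e[0] for e in order.entries]
    if any(m not in labels for m in cluster):
        return "member_missing"
    n = len(labels)
    pattern = list(strands) if strands is not None else None

    def matches(idx: int, members: Sequence[str], pat) -> bool:
        window = [order.entries[(idx + t) % n] for t in range(len(members))]
        if [w[0] for w in window] != list(members):
            return False
        ws = [w[1] for w in window]
        if pat is None:
            return len(set(ws)) == 1
        return ws == list(pat) or ws == [
            ("+" if p == "-" else "-") for p in pat
        ]

    rev_members = cluster[::-1]
    rev_pattern = (
        None
        if pattern is None
        else [("+" if p == "-" else "-") for p in pattern[::-1]]
    )
    for i in range(n):
        if matches(i, cluster, pattern) or matches(i, rev_members, rev_pattern):
            return "present"
    return "broken"


def find_gene_clusters(g: AnnotatedGenome, max_gap: int = 1500) -> list:
    """Co-transcribed gene clusters: maximal circular runs of >= 2 ordered
    genes on one strand separated by at most ``max_gap`` bp (overlaps count
    as separation 0). Returns dicts with member labels, spans and the
    signed intergenic gaps between consecutive members."""
    from .model import intergenic_gap

    L = g.genome.length
    feats = sorted(g.by_category("protein", "rRNA"), key=lambda f: (f.start(), f.label))
    n = len(feats)
    if n < 2:
        return []
    spans = [f.span(L) for f in feats]
    linked = []
    for i in range(n):
        j = (i + 1) % n
        gap = intergenic_gap(spans[i], spans[j], L)
        linked.append(gap <= max_gap and feats[i].strand == feats[j].strand)
    if all(linked):
        runs = [(0, n)]  # the whole circle is one run
    else:
        runs = []
        for i in range(n):
            if linked[i] and not linked[(i - 1) % n]:
                edges = 1
                j = i
                while linked[(j + 1) % n] and edges < n - 1:
                    j = (j + 1) % n
                    edges += 1
                runs.append((i, edges + 1))
    out = []
    for start, length in runs:
        idx = [(start + t) % n for t in range(length)]
        members = [feats[t] for t in idx]
        gaps = [
            intergenic_gap(spans[idx[t]], spans[idx[t + 1]], L)
            for t in range(len(idx) - 1)
        ]
        out.append(
            {
                "labels": [f.label for f in members],
                "spans": [spans[t] for t in idx],
                "gaps": gaps,
                "strand": members[0].strand,
            }
        )
    return out


_STATUS_SYMBOL = {"present": "+", "broken": "-", "member_missing": "#"}


def presence_grid(
    genomes: Sequence[AnnotatedGenome], clusters: Sequence[Sequence[str]]
) -> pd.DataFrame:
    """Species x cluster grid with +/−/# symbols."""
    names = ["-".join(c) for c in clusters]
    rows = {}
    for g in genomes:
        rows[g.species] = [
            _STATUS_SYMBOL[cluster_status(c, g)] for c in clusters
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


def conserved_clusters(
    genomes: Sequence[AnnotatedGenome], ignore_missing: bool = True
) -> dict:
    """Universal and group-specific conserved adjacencies.

    Enumerates every adjacency seen in any genome; reports those present in
    all genomes ('universal') and, per group label, those present in every
    member of the group and absent from every non-member. A genome lacking
    one of the pair's genes is non-informative when ``ignore_missing`` is on
    (it neither supports nor vetoes the adjacency).
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    orders = {g.species: extract_gene_order(g) for g in genomes}
    label_sets = {
        sp: {e[0] for e in o.entries} for sp, o in orders.items()
    }
    keys = {sp: o.adjacency_keys() for sp, o in orders.items()}
    groups = {g.species: g.group for g in genomes}
    distinct_groups = sorted({v for v in groups.values() if v})
    if len(distinct_groups) < 2:
        warnings.warn("fewer than two group labels: group-specific sets equal the universal set")
    all_keys = set().union(*keys.values())

    def state(sp, key):
        pair, _rel = key
        if ignore_missing and any(lbl not in label_sets[sp] for lbl in pair):
            return None  # non-informative
        return key in keys[sp]

    result: dict = {"universal": [], **{gname: [] for gname in distinct_groups}}
    for key in sorted(all_keys):
        states = {sp: state(sp, key) for sp in orders}
        informative = {sp: st for sp, st in states.items() if st is not None}
        if informative and all(informative.values()):
            result["universal"].append(Adjacency(*key))
            continue
        for gname in distinct_groups:
            ingroup = [st for sp, st in informative.items() if groups[sp] == gname]
            outgroup = [st for sp, st in informative.items() if groups[sp] != gname]
            if ingroup and all(ingroup) and outgroup and not any(outgroup):
                result[gname].append(Adjacency(*key))
    return result
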