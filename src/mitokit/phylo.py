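"""Concatenated-gene distance phylogeny: p-distances and neighbor joining.

The conserved mitochondrial respiratory-chain genes (17 respiratory complex
genes plus the four cytochrome c biogenesis genes) are concatenated
head-to-tail per species; pairwise p-distances (proportion of differing
sites under pairwise gap deletion) feed a standard neighbor-joining
agglomeration. Robinson–Foulds distances quantify topological congruence
with a reference taxonomy tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "GENE_SETS",
    "LocusAlignment",
    "ConcatAlignment",
    "concatenate_loci",
    "p_distance_matrix",
    "nj_tree",
    "rf_distance",
]

_COMPLEX_I = ["nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9"]
_COMPLEX_III = ["cob"]
_COMPLEX_IV = ["cox1", "cox3"]
_COMPLEX_V = ["atp1", "atp4", "atp6", "atp8", "atp9"]
_CCM = ["ccmB", "ccmC", "ccmFC", "ccmFN"]

GENE_SETS: Dict[str, list] = {
    "all21": _COMPLEX_V + _COMPLEX_III + _COMPLEX_IV + _COMPLEX_I + _CCM,
    "complexI": _COMPLEX_I,
    "complexIII": _COMPLEX_III,
    "complexIV": _COMPLEX_IV,
    "complexV": _COMPLEX_V,
    "ccm": _CCM,
}


@dataclass(frozen=True)
class LocusAlignment:
    """One aligned locus: species -> equal-length gapped sequences."""

    name: str
    sequences: dict

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.name}: aligned sequences differ in length")
        bad = set().union(*(set(s.upper()) for s in self.sequences.values())) - set(
            "ACGTN-"
        )
        if bad:
            raise ValueError(f"{self.name}: illegal characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))


@dataclass(frozen=True)
class ConcatAlignment:
    loci: tuple  # locus names in concatenation order
    sequences: dict  # species -> concatenated sequence
    partitions: tuple  # (locus, start, end) 1-based inclusive

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def split(self) -> list:
        """Recover the per-locus alignments from the partition record."""
        out = []
        for name, s, e in self.partitions:
            out.append(
                LocusAlignment(
                    name, {sp: seq[s - 1 : e] for sp, seq in self.sequences.items()}
                )
            )
        return out


def concatenate_loci(
    loci: Sequence[LocusAlignment], gene_set: Union[str, Sequence[str]] = "all21"
) -> ConcatAlignment:
    """Head-to-tail concatenation of the named loci, all species required.

    ``gene_set`` is one of the named functional sets or an explicit list of
    locus names; concatenation follows that order.
    """
    names = GENE_SETS[gene_set] if isinstance(gene_set, str) else list(gene_set)
    by_name = {l.name: l for l in loci}
    missing = [n for n in names if n not in by_name]
    if missing:
        raise ValueError(f"loci absent from input: {missing}")
    species = set(by_name[names[0]].sequences)
    for n in names:
        sp = set(by_name[n].sequences)
        if sp != species:
            diff = sorted(species ^ sp)
            raise ValueError(f"locus {n}: species set differs ({diff})")
    parts = []
    pos = 1
    for n in names:
        L = by_name[n].length
        parts.append((n, pos, pos + L - 1))
        pos += L
    sequences = {
        s: "".join(by_name[n].sequences[s] for n in names) for s in sorted(species)
    }
    return ConcatAlignment(tuple(names), sequences, tuple(parts))


def p_distance_matrix(a: Union[ConcatAlignment, LocusAlignment]) -> pd.DataFrame:
    """Pairwise proportion of differing sites, pairwise gap/N deletion."""
    species = sorted(a.sequences)
    if len(species) < 2:
        raise ValueError("need at least two species")
    arrs = {
        sp: np.frombuffer(a.sequences[sp].upper().encode(), dtype=np.uint8)
        for sp in species
    }
    bad = (ord("-"), ord("N"))
    mat = pd.DataFrame(0.0, index=species, columns=species)
    for i, si in enumerate(species):
        for sj in species[i + 1 :]:
            x, y = arrs[si], arrs[sj]
            ok = ~(np.isin(x, bad) | np.isin(y, bad))
            n = int(ok.sum())
            if n == 0:
                raise ValueError(f"no comparable columns between {si} and {sj}")
            d = float((x[ok] != y[ok]).mean())
            mat.loc[si, sj] = mat.loc[sj, si] = d
    return mat


def nj_tree(d: pd.DataFrame) -> str:
    """Neighbor joining; returns a newick string with branch lengths.

    Ties in the Q criterion break deterministically by species-name order;
    negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.
    """
    if not np.allclose(d.values, d.values.T):
        raise ValueError("distance matrix is not symmetric")
    if len(d) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    labels = list(d.index)  # newick fragment per active node
    names = list(d.index)  # sort key: smallest original name in the clade
    D = d.values.astype(float).copy()

    def clamp(li, lj):
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(labels) > 3:
        n = len(labels)
        r = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                key = (q, *sorted((names[i], names[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, lj)
        new_label = f"({labels[i]}:{li:.10g},{labels[j]}:{lj:.10g})"
        new_name = min(names[i], names[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(n) if x not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[: len(keep), : len(keep)] = D[np.ix_(keep, keep)]
        D2[-1, : len(keep)] = D2[: len(keep), -1] = dnew[keep]
        D = D2
        labels = [labels[x] for x in keep] + [new_label]
        names = [names[x] for x in keep] + [new_name]

    # closed-form star resolution for the last three nodes
    a, b, c = 0, 1, 2
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return (
        f"({labels[a]}:{la:.10g},{labels[b]}:{lb:.10g},{labels[c]}:{lc:.10g});"
    )


def rf_distance(
    t1: Union[str, dendropy.Tree], t2: Union[str, dendropy.Tree]
) -> int:
    """Robinson–Foulds symmetric difference of internal bipartitions."""
    tns = dendropy.TaxonNamespace()

    def load(t):
        if isinstance(t, dendropy.Tree):
            t = t.as_string(schema="newick")
        tree = dendropy.Tree.get(data=t, schema="newick", taxon_namespace=tns)
        tree.is_rooted = False  # RF compares unrooted bipartitions
        return tree

    a, b = load(t1), load(t2)
    tips_a = {l.taxon.label for l in a.leaf_node_iter()}
    tips_b = {l.taxon.label for l in b.leaf_node_iter()}
    if tips_a != tips_b:
        raise ValueError(f"tip sets differ: {sorted(tips_a ^ tips_b)}")
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)
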