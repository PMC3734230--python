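"""Masked shared-sequence totals between mitochondrial genomes.

Before measuring how much sequence two mt genomes share, each genome is
masked: chloroplast-derived segments are removed (they would register as
shared through their common plastid source, not common mitochondrial
ancestry) and all but one copy of every large repeat family is removed (so
a multi-copy region is not counted multiply). Shared length is then the
union of the query's kept intervals matched by local homology search
against the other masked genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from . import homology
from .model import AnnotatedGenome, Genome, Interval, merge_intervals

__all__ = ["MaskedGenome", "mask_genome", "shared_length", "shared_matrix"]

_SEPARATOR = "N" * 25  # longer than any seed; blocks cross-segment matches


@dataclass
class MaskedGenome:
    source: AnnotatedGenome
    kept: tuple  # non-overlapping plus-strand intervals
    removed: tuple  # (Interval, reason) with reason cp_derived / repeat_extra_copy

    @property
    def species(self) -> str:
        return self.source.species

    @property
    def kept_length(self) -> int:
        L = self.source.genome.length
        return sum(iv.length(L) for iv in self.kept)

    def kept_sequence(self) -> str:
        """Kept segments joined by N spacers (seeds never cross a spacer)."""
        g = self.source.genome
        parts = [g.seq[iv.start - 1 : iv.end] for iv in self.kept]
        return _SEPARATOR.join(parts)

    def kept_segments(self) -> list:
        g = self.source.genome
        return [g.seq[iv.start - 1 : iv.end] for iv in self.kept]


def mask_genome(
    g: AnnotatedGenome,
    homologs: Sequence = (),
    families: Sequence = (),
    large_cutoff: int = 1000,
) -> MaskedGenome:
    """Remove cp-derived intervals and extra copies of large repeats.

    For every repeat family with alignment length >= ``large_cutoff`` the
    copy with the lowest start coordinate is kept and the rest removed.
    Kept and removed intervals partition the genome exactly.
    """
    L = g.genome.length
    removals = []
    for h in homologs:
        removals.append((h.mt_interval, "cp_derived"))
    for fam in families:
        if fam.rep_length >= large_cutoff:
            extra = sorted(fam.copies, key=lambda c: c.interval.start)[1:]
            removals.extend((c.interval, "repeat_extra_copy") for c in extra)
    removed_merged = merge_intervals([iv for iv, _ in removals], L)
    # kept = complement of the removed union
    kept = []
    pos = 1
    for iv in removed_merged:
        if iv.start > pos:
            kept.append(Interval(pos, iv.start - 1))
        pos = max(pos, iv.end + 1)
    if pos <= L:
        kept.append(Interval(pos, L))
    # annotate each merged removal with the reasons feeding it
    removed = []
    for iv in removed_merged:
        reasons = sorted(
            {
                reason
                for src, reason in removals
                if _overlaps(src, iv, L)
            }
        )
        removed.append((iv, "+".join(reasons)))
    return MaskedGenome(g, tuple(kept), tuple(removed))


def _overlaps(a: Interval, b: Interval, L: int) -> bool:
    def segs(iv):
        return [(iv.start, L), (1, iv.end)] if iv.wraps else [(iv.start, iv.end)]

    return any(
        min(e1, e2) >= max(s1, s2)
        for s1, e1 in segs(a)
        for s2, e2 in segs(b)
    )


def shared_length(
    q: MaskedGenome,
    s: MaskedGenome,
    min_identity: float = 70.0,
    min_len: int = 50,
    k: int = 9,
) -> int:
    """Total bp of the query's kept sequence matched somewhere in ``s``.

    Query-based: matched query intervals are merged before measuring, so
    a query region matching multiple subject locations counts once.
    """
    if not q.kept or not s.kept:
        warnings.warn("shared_length on an empty kept set")
        return 0
    subject = s.kept_sequence()
    matched = 0
    for segment in q.kept_segments():
        if len(segment) < min_len:
            continue
        hits = homology.search(
            segment,
            subject,
            k=k,
            min_len=min_len,
            min_identity=min_identity,
            min_seeds=2,
            max_gap=80,
            band=12,
        )
        ivs = [Interval(h.q_start, h.q_end) for h in hits]
        matched += sum(
            iv.length(len(segment)) for iv in merge_intervals(ivs, len(segment))
        )
    return matched


def shared_matrix(
    genomes: Sequence[MaskedGenome],
    min_identity: float = 70.0,
    min_len: int = 50,
    k: int = 9,
) -> pd.DataFrame:
    """Full query-by-subject matrix of shared bp (row = query).

    The matrix is near- but not exactly symmetric because matched-interval
    merging is query-based. The diagonal is the masked (kept) length.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    names = [g.species for g in genomes]
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, gi in enumerate(genomes):
        for j, gj in enumerate(genomes):
            if i == j:
                mat.iloc[i, j] = gi.kept_length
            else:
                mat.iloc[i, j] = shared_length(
                    gi, gj, min_identity=min_identity, min_len=min_len, k=k
                )
    return mat
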