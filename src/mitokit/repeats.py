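"""Repeat detection and classification by genome self-comparison.

Plant mitochondrial genomes carry repeat families from 20 bp up to tens of
kilobases; large repeats mediate intramolecular recombination. The scan
finds all copy pairs above a length and identity floor, clusters copies into
families by single linkage, classifies each family as direct (DR), inverted
(IR) or mixed (IR/DR), and tabulates the size-class landscape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from . import homology
from .model import (
    AnnotatedGenome,
    Genome,
    Interval,
    interval_union_length,
    round1,
)

__all__ = [
    "RepeatCopy",
    "RepeatFamily",
    "RepeatLandscape",
    "LandscapeRow",
    "find_repeats",
    "classify_family",
    "tabulate_landscape",
]

DEFAULT_BOUNDS = (20, 40, 60, 80, 100, 1000)


@dataclass(frozen=True)
class RepeatCopy:
    interval: Interval
    orientation: str  # forward / reverse, relative to the family's first copy


@dataclass(frozen=True)
class RepeatFamily:
    family_id: str
    rep_length: int  # alignment length incl. indels of the longest copy pair
    identity: float  # minimum pairwise percent identity among copies
    copies: tuple
    type: str  # DR / IR / IR/DR

    @property
    def copy_count(self) -> int:
        return len(self.copies)


def classify_family(copies: Sequence[RepeatCopy]) -> str:
    """DR if all copies share orientation, IR for an opposite pair,
    IR/DR for >= 3 copies in mixed orientations."""
    if len(copies) < 2:
        raise ValueError("a repeat family needs at least two copies")
    orientations = {c.orientation for c in copies}
    if len(orientations) == 1:
        return "DR"
    return "IR" if len(copies) == 2 else "IR/DR"


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _split_palindrome(seq2: str, h, min_len: int, min_identity: float):
    """Resolve a self-overlapping reverse hit into its two inverted copies.

    The matched region spans both copies (plus any short spacer); the first
    half is realigned against the reverse complement of the second half and
    the trimmed alignment becomes the copy pair."""
    from . import homology
    from .model import revcomp

    s = min(h.q_start, h.s_start)
    e = max(h.q_end, h.s_end)
    mid = (s + e) // 2
    first = seq2[s - 1 : mid]
    second = revcomp(seq2[mid : e])
    trimmed = homology.trimmed_local_alignment(first, second)
    if trimmed is None:
        return None
    a0, a1, b0, b1, ident, cols = trimmed
    if cols < min_len or ident < min_identity:
        return None
    return homology.Hit(
        q_start=s + a0,
        q_end=s + a1,
        s_start=e - b1,
        s_end=e - b0,
        strand="-",
        identity=ident,
        aln_len=cols,
    )


def _norm(start: int, end: int, L: int) -> tuple:
    """Map a doubled-sequence interval back onto the circle (may wrap)."""
    s = (start - 1) % L + 1
    e = (end - 1) % L + 1
    return s, e


def _circ_overlap(a: tuple, b: tuple, L: int) -> int:
    """Overlap in bp of two (start, end) intervals on a circle of length L."""

    def segments(iv):
        s, e = iv
        return [(s, L), (1, e)] if s > e else [(s, e)]

    total = 0
    for s1, e1 in segments(a):
        for s2, e2 in segments(b):
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def find_repeats(
    g: Union[Genome, AnnotatedGenome],
    min_len: int = 20,
    min_identity: float = 80.0,
    seed_k: int = 15,
    max_gap: int = 80,
    band: int = 12,
    max_occ: int = 64,
) -> list:
    """Detect repeat families >= ``min_len`` bp at >= ``min_identity`` %.

    The circular genome is scanned as a doubled sequence on both strands;
    images of the same pair in the second copy are removed, copies are
    clustered into families by single linkage over mutual matches, and
    families are numbered R01, R02 ... by decreasing alignment length.
    """
    genome = g.genome if isinstance(g, AnnotatedGenome) else g
    if min_len < seed_k:
        raise ValueError(f"min_len ({min_len}) must be >= seed_k ({seed_k})")
    L = genome.length
    if L <= 2 * min_len:
        raise ValueError("genome too short for repeat scanning")
    seq2 = genome.seq + genome.seq if genome.circular else genome.seq
    hits = homology.search(
        seq2,
        seq2,
        k=seed_k,
        min_len=min_len,
        min_identity=min_identity,
        self_mode=True,
        max_gap=max_gap,
        band=band,
        max_occ=max_occ,
    )

    # deduplicate circular images and self-matches
    pairs = []  # (copyA (s,e), copyB (s,e), strand, identity, aln_len)
    seen = set()
    for h in hits:
        if h.q_start > L:
            continue
        if h.strand == "+" and h.s_start - h.q_start >= L:
            continue
        if h.strand == "-" and max(h.q_start, h.s_start) <= min(h.q_end, h.s_end):
            # an inverted pair of abutting copies reads as one palindromic
            # self-match; split it at the anti-diagonal centre and re-verify
            # the halves against each other
            h = _split_palindrome(seq2, h, min_len, min_identity)
            if h is None:
                continue
        a = _norm(h.q_start, h.q_end, L)
        b = _norm(h.s_start, h.s_end, L)
        if a == b:
            continue  # degenerate self-match
        key = tuple(sorted((a, b))) + (h.strand,)
        if key in seen:
            continue
        seen.add(key)
        pairs.append((a, b, h.strand, h.identity, h.aln_len))
    if not pairs:
        return []

    # cluster copy intervals: same copy if they overlap >= 50% of the shorter
    intervals = []
    for a, b, *_ in pairs:
        intervals.append(a)
        intervals.append(b)
    uf = _UnionFind(len(intervals))
    lengths = [_circ_overlap(iv, iv, L) for iv in intervals]
    plain = [i for i in range(len(intervals)) if intervals[i][0] <= intervals[i][1]]
    wraps = [i for i in range(len(intervals)) if intervals[i][0] > intervals[i][1]]
    plain.sort(key=lambda i: intervals[i])
    for ii in range(len(plain)):
        i = plain[ii]
        for jj in range(ii + 1, len(plain)):
            j = plain[jj]
            if intervals[j][0] > intervals[i][1]:
                break
            ov = _circ_overlap(intervals[i], intervals[j], L)
            if ov >= 0.5 * min(lengths[i], lengths[j]):
                uf.union(i, j)
    for i in wraps:  # wrap-origin copies are few; compare against everything
        for j in range(len(intervals)):
            if i == j:
                continue
            ov = _circ_overlap(intervals[i], intervals[j], L)
            if ov >= 0.5 * min(lengths[i], lengths[j]):
                uf.union(i, j)

    # orientation parity propagation across the match graph
    copy_of = [uf.find(i) for i in range(len(intervals))]
    adj: dict = {}
    for p_idx, (a, b, strand, ident, alen) in enumerate(pairs):
        ca, cb = copy_of[2 * p_idx], copy_of[2 * p_idx + 1]
        parity = 0 if strand == "+" else 1
        adj.setdefault(ca, []).append((cb, parity))
        adj.setdefault(cb, []).append((ca, parity))

    orientation: dict = {}
    conflict_roots = set()
    fam_uf: dict = {}

    def fam_find(a):
        while fam_uf.setdefault(a, a) != a:
            fam_uf[a] = fam_uf[fam_uf[a]]
            a = fam_uf[a]
        return a

    for root in adj:
        if root in orientation:
            continue
        orientation[root] = 0
        stack = [root]
        while stack:
            u = stack.pop()
            for v, parity in adj.get(u, []):
                ra, rb = fam_find(u), fam_find(v)
                if ra != rb:
                    fam_uf[rb] = ra
                want = orientation[u] ^ parity
                if v not in orientation:
                    orientation[v] = want
                    stack.append(v)
                elif orientation[v] != want:
                    conflict_roots.add(fam_find(v))

    # aggregate copies per family
    fam_members: dict = {}
    for cid in set(copy_of):
        fam_members.setdefault(fam_find(cid), set()).add(cid)
    copy_span: dict = {}
    for i, iv in enumerate(intervals):
        cid = copy_of[i]
        cur = copy_span.get(cid)
        # union span of clustered intervals (they overlap, so min/max works
        # after unwrapping relative to the first seen start)
        if cur is None:
            copy_span[cid] = iv
        else:
            s0, e0 = cur
            s1, e1 = iv
            if s0 > e0 or s1 > e1:  # wrap involved: keep longer representative
                copy_span[cid] = cur if _circ_overlap(cur, cur, L) >= _circ_overlap(iv, iv, L) else iv
            else:
                copy_span[cid] = (min(s0, s1), max(e0, e1))

    fam_stats: dict = {}
    for p_idx, (a, b, strand, ident, alen) in enumerate(pairs):
        froot = fam_find(copy_of[2 * p_idx])
        st = fam_stats.setdefault(froot, {"identity": ident, "rep_length": alen})
        st["identity"] = min(st["identity"], ident)
        st["rep_length"] = max(st["rep_length"], alen)

    families = []
    for froot, members in fam_members.items():
        if len(members) < 2:
            continue
        spans = sorted(members, key=lambda cid: copy_span[cid][0])
        first = spans[0]
        base = orientation.get(first, 0)
        copies = tuple(
            RepeatCopy(
                Interval(*copy_span[cid]),
                "forward" if orientation.get(cid, 0) == base else "reverse",
            )
            for cid in spans
        )
        ftype = classify_family(copies)
        if froot in conflict_roots and len(copies) >= 3:
            ftype = "IR/DR"
        st = fam_stats[froot]
        families.append((st["rep_length"], copies[0].interval.start, st["identity"], copies, ftype))

    families.sort(key=lambda t: (-t[0], t[1]))
    width = max(2, len(str(len(families))))
    return [
        RepeatFamily(f"R{i + 1:0{width}d}", rep_length, identity, copies, ftype)
        for i, (rep_length, _, identity, copies, ftype) in enumerate(families)
    ]


@dataclass(frozen=True)
class LandscapeRow:
    lower: int
    upper: Optional[int]  # exclusive; None = unbounded
    count: int
    total_bp: int
    coverage_pct: float

    @property
    def label(self) -> str:
        return f"{self.lower}-{self.upper - 1}" if self.upper else f">={self.lower}"


@dataclass(frozen=True)
class RepeatLandscape:
    genome_length: int
    rows: tuple
    union_bp: int
    union_coverage_pct: float

    @property
    def family_count(self) -> int:
        return sum(r.count for r in self.rows)

    @property
    def total_copy_bp(self) -> int:
        return sum(r.total_bp for r in self.rows)


def tabulate_landscape(
    families: Sequence[RepeatFamily],
    genome_length: int,
    bounds: Sequence[int] = DEFAULT_BOUNDS,
) -> RepeatLandscape:
    """Size-class frequency table: per class the family count (by alignment
    length), summed copy length, and its percent of the genome; classes are
    closed-open ``[lo, hi)`` with the last unbounded. Union coverage merges
    all copy intervals before measuring."""
    bounds = list(bounds)
    if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
        raise ValueError("size-class bounds must be strictly increasing")
    edges = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    edges.append((bounds[-1], None))
    rows = []
    for lo, hi in edges:
        fams = [
            f
            for f in families
            if f.rep_length >= lo and (hi is None or f.rep_length < hi)
        ]
        total = sum(
            c.interval.length(genome_length) for f in fams for c in f.copies
        )
        rows.append(
            LandscapeRow(lo, hi, len(fams), total, round1(100.0 * total / genome_length))
        )
    union = interval_union_length(
        [c.interval for f in families for c in f.copies], genome_length
    )
    return RepeatLandscape(
        genome_length, tuple(rows), union, round1(100.0 * union / genome_length)
    )
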