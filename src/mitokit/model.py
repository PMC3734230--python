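"""Core data model for circular annotated organelle genomes.

Coordinates are 1-based and inclusive throughout, matching the convention of
organelle annotation tables. On a circular genome an interval with
``start > end`` wraps through the origin (position ``length`` is followed by
position 1). Conversions to 0-based half-open (BED) coordinates live in
:mod:`mitokit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

__all__ = [
    "Genome",
    "Interval",
    "GeneFeature",
    "AnnotatedGenome",
    "GenicContentTable",
    "revcomp",
    "round1",
    "extract_subsequence",
    "intergenic_gap",
    "genic_content_table",
    "merge_intervals",
    "interval_union_length",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

GENE_CATEGORIES = ("protein", "rRNA", "tRNA", "pseudogene", "remnant")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round1(x: float) -> float:
    """Round to one decimal, ties away from zero.

    Percentages in the published organelle tables (9.9, 1.1, 18.9 ...) are
    reproduced under this rule, whereas banker's rounding is not guaranteed to.
    """
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Genome:
    """A nucleotide sequence, by default a circular master-circle molecule."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id!r}: non-ACGTN characters {sorted(bad)}")
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """1-based inclusive interval; ``start > end`` wraps the circular origin."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"coordinates must be >= 1: {self.start}..{self.end}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: Optional[int] = None) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError("wrap interval needs genome_length to compute length")
        return genome_length - self.start + 1 + self.end

    def validate(self, genome_length: int, circular: bool = True) -> None:
        if self.start > genome_length or self.end > genome_length:
            raise ValueError(
                f"interval {self.start}..{self.end} outside [1, {genome_length}]"
            )
        if self.wraps and not circular:
            raise ValueError(
                f"wrap interval {self.start}..{self.end} on a linear genome"
            )

    def shifted(self, offset: int, genome_length: int) -> "Interval":
        """Interval translated by ``offset`` around a circle of given length."""
        s = (self.start - 1 + offset) % genome_length + 1
        e = (self.end - 1 + offset) % genome_length + 1
        return Interval(s, e, self.strand)


@dataclass(frozen=True)
class GeneFeature:
    """A gene (or gene fragment) as an ordered list of exon intervals.

    Trans-spliced genes are represented as one feature per cis-contiguous exon
    block; the blocks share ``locus`` and are distinguished by ``trans_block``
    (e.g. nad1 blocks "nad1bc" / "nad1de"). Duplicate gene copies share the
    locus label and are numbered by ``copy_index``.
    """

    locus: str
    category: str
    exons: tuple
    trans_block: Optional[str] = None
    copy_index: int = 1

    def __post_init__(self) -> None:
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        exons = tuple(self.exons)
        if not exons:
            raise ValueError(f"{self.locus}: feature needs at least one exon")
        strands = {e.strand for e in exons}
        if len(strands) != 1:
            raise ValueError(f"{self.locus}: exons on mixed strands")
        object.__setattr__(self, "exons", exons)
        if self.copy_index < 1:
            raise ValueError("copy_index must be >= 1")

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def label(self) -> str:
        """Gene-order label: the trans-spliced block name when present."""
        return self.trans_block if self.trans_block else self.locus

    def start(self) -> int:
        """Leftmost annotated coordinate (first exon start in genome order)."""
        return min(min(e.start, e.end) for e in self.exons)

    def span(self, genome_length: int) -> Interval:
        """Smallest interval covering all exons of this cis block.

        For a wrap feature the span is taken along the circle in the direction
        that keeps it shorter than the genome.
        """
        if any(e.wraps for e in self.exons):
            # unwrap: express all coordinates past the origin as > genome_length
            points = []
            for e in self.exons:
                s, t = e.start, e.end
                if e.wraps:
                    t += genome_length
                points.extend((s, t))
            lo, hi = min(points), max(points)
            return Interval(lo, (hi - 1) % genome_length + 1, self.strand)
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return Interval(lo, hi, self.strand)

    def exon_length(self, genome_length: int) -> int:
        return sum(e.length(genome_length) for e in self.exons)

    def intron_length(self, genome_length: int) -> int:
        """Span minus exon total, within this cis block only."""
        return self.span(genome_length).length(genome_length) - self.exon_length(
            genome_length
        )


@dataclass
class AnnotatedGenome:
    genome: Genome
    features: list
    species: str = ""
    group: Optional[str] = None  # gymnosperm / monocot / dicot

    def __post_init__(self) -> None:
        seen = set()
        for f in self.features:
            for e in f.exons:
                e.validate(self.genome.length, self.genome.circular)
            key = (f.locus, f.trans_block, f.copy_index)
            if key in seen:
                raise ValueError(f"duplicate locus/copy pair {key}")
            seen.add(key)
        if not self.species:
            self.species = self.genome.id

    def by_category(self, *categories: str) -> list:
        return [f for f in self.features if f.category in categories]

    def feature_sequence(self, f: GeneFeature) -> str:
        """Spliced sequence of a feature, exons joined in annotation order."""
        parts = [extract_subsequence(self.genome, e) for e in f.exons]
        return "".join(parts)


def extract_subsequence(g: Genome, iv: Interval) -> str:
    """Slice of the genome; reverse-complemented for minus-strand intervals.

    Wrap intervals (start > end) read through the origin of a circular genome.
    """
    iv.validate(g.length, g.circular)
    if iv.wraps:
        s = g.seq[iv.start - 1 :] + g.seq[: iv.end]
    else:
        s = g.seq[iv.start - 1 : iv.end]
    return revcomp(s) if iv.strand == "-" else s


def intergenic_gap(upstream: Interval, downstream: Interval, genome_length: int) -> int:
    """Signed gap in bp between two genes along the annotated direction.

    Uniformly ``downstream.start - upstream.end - 1`` (modulo the genome length
    when the pair straddles the origin). Zero means the genes touch; a negative
    value is the number of overlapping coding positions.
    """
    if (upstream.start, upstream.end) == (downstream.start, downstream.end):
        raise ValueError("identical intervals do not form a gene pair")
    gap = downstream.start - upstream.end - 1
    # a 'negative' gap larger than half the circle is really a wrap-around gap
    if gap < -(genome_length // 2):
        gap += genome_length
    return gap


@dataclass(frozen=True)
class GenicContentTable:
    """Per-category genic totals in bp with percentages of genome length."""

    genome_length: int
    protein_exon_bp: int
    protein_intron_bp: int
    trna_bp: int
    rrna_bp: int

    @property
    def protein_bp(self) -> int:
        return self.protein_exon_bp + self.protein_intron_bp

    def percent(self, bp: int) -> float:
        return round1(100.0 * bp / self.genome_length)

    @property
    def protein_percent(self) -> float:
        return self.percent(self.protein_bp)

    @property
    def trna_percent(self) -> float:
        return self.percent(self.trna_bp)

    @property
    def rrna_percent(self) -> float:
        return self.percent(self.rrna_bp)


def genic_content_table(g: AnnotatedGenome) -> GenicContentTable:
    """Tabulate protein exon/intron, tRNA and rRNA content of a genome.

    Intron length is defined per cis-contiguous exon block (trans-spliced
    'introns' are undefined and never counted). Pseudogenes and remnant
    fragments are excluded from all categories.
    """
    L = g.genome.length
    exon = intron = trna = rrna = 0
    for f in g.features:
        if f.category == "protein":
            exon += f.exon_length(L)
            intron += f.intron_length(L)
        elif f.category == "tRNA":
            trna += f.exon_length(L)
        elif f.category == "rRNA":
            rrna += f.exon_length(L)
    return GenicContentTable(L, exon, intron, trna, rrna)


def merge_intervals(
    ivs: Iterable[Interval], genome_length: int
) -> list:
    """Union of intervals on a circle, as a sorted list of non-overlapping
    plus-strand intervals (wrap intervals are split at the origin first)."""
    segs = []
    for iv in ivs:
        if iv.wraps:
            segs.append((iv.start, genome_length))
            segs.append((1, iv.end))
        else:
            segs.append((min(iv.start, iv.end), max(iv.start, iv.end)))
    if not segs:
        return []
    segs.sort()
    merged = [list(segs[0])]
    for s, e in segs[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [Interval(s, e, "+") for s, e in merged]


def interval_union_length(ivs: Iterable[Interval], genome_length: int) -> int:
    return sum(iv.length(genome_length) for iv in merge_intervals(ivs, genome_length))
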