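"""Chloroplast-derived (MTPT) sequence detection in mitochondrial genomes.

Plant mt genomes take up chloroplast DNA by intracellular transfer; the
integrated segments (mitochondrial plastid DNA, MTPT) are recognised as
mt intervals matching the species' chloroplast genome at or above an
identity floor (80% by default, the conventional reporting threshold).
Segments are classified by what they overlap in the chloroplast: tRNA
genes, photosynthesis genes, or other sequence.
"""

from __future__ import annotations

import re
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
    "PlastidHomolog",
    "MtptSummary",
    "LinkageRecord",
    "scan_plastid_homologs",
    "classify_homolog",
    "summarize_mtpt",
    "conserved_linkage",
]

_PHOTO_RE = re.compile(r"^(psa|psb|pet|ndh)|^rbcL", re.IGNORECASE)


@dataclass
class PlastidHomolog:
    """An mt interval derived from the chloroplast genome."""

    mt_interval: Interval
    cp_interval: Interval
    identity: float  # percent of the best supporting alignment
    length: int  # merged mt interval length in bp
    klass: Optional[str] = None  # tRNA / photosynthesis / other
    cp_gene: Optional[str] = None  # overlapped cp gene, when any


@dataclass(frozen=True)
class MtptSummary:
    species: str
    total_bp: int
    count: int
    coverage_pct: float


@dataclass(frozen=True)
class LinkageRecord:
    homolog_label: str
    left_gene: Optional[str]
    right_gene: Optional[str]
    species: tuple


def _overlap_1d(a: Interval, b: Interval) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def scan_plastid_homologs(
    mt: Union[Genome, AnnotatedGenome],
    cp: Union[Genome, AnnotatedGenome],
    min_identity: float = 80.0,
    min_len: int = 30,
    word_size: int = 7,
    sensitive: bool = True,
) -> list:
    """Find cp-derived segments of the mt genome on both strands.

    A fast seed pass (``word_size``-mer chains) is complemented, when
    ``sensitive`` is on, by a sliding-window infix sweep that guarantees
    recovery of short segments near the identity floor, where an exact seed
    may not survive the divergence. Overlapping mt intervals are merged into
    one homolog keeping the best-identity supporting alignment.
    """
    mt_genome = mt.genome if isinstance(mt, AnnotatedGenome) else mt
    cp_genome = cp.genome if isinstance(cp, AnnotatedGenome) else cp
    if cp_genome.length == 0:
        raise ValueError("empty chloroplast genome")
    L = mt_genome.length
    query = mt_genome.seq + mt_genome.seq if mt_genome.circular else mt_genome.seq
    hits = homology.search(
        query,
        cp_genome.seq,
        k=word_size,
        min_len=min_len,
        min_identity=min_identity,
        min_seeds=2,
        max_gap=50,
        band=10,
    )
    if sensitive:
        window = max(12, min_len - 6)
        max_mismatch = max(4, int(round(window * (1.0 - min_identity / 100.0))) + 3)
        # the sweep only needs one circular pass plus a wrap margin
        sweep_query = (
            mt_genome.seq + mt_genome.seq[: min_len + window]
            if mt_genome.circular
            else mt_genome.seq
        )
        hits += homology.sweep_search(
            sweep_query,
            cp_genome.seq,
            window=window,
            step=max(1, min_len - window + 1),
            max_mismatch=max_mismatch,
            min_len=min_len,
            min_identity=min_identity,
        )
    # drop circular images from the doubled query
    hits = [h for h in hits if h.q_start <= L]

    # merge overlapping mt intervals; the best-identity hit titles the homolog
    hits.sort(key=lambda h: (h.q_start, -h.q_end))
    components: list = []
    for h in hits:
        if components and h.q_start <= components[-1]["end"]:
            comp = components[-1]
            comp["end"] = max(comp["end"], min(h.q_end, 2 * L))
            comp["hits"].append(h)
        else:
            components.append({"start": h.q_start, "end": h.q_end, "hits": [h]})
    homologs = []
    for comp in components:
        best = max(comp["hits"], key=lambda h: (h.identity, h.aln_len))
        s, e = comp["start"], comp["end"]
        mt_iv = Interval((s - 1) % L + 1, (e - 1) % L + 1)
        homologs.append(
            PlastidHomolog(
                mt_interval=mt_iv,
                cp_interval=Interval(best.s_start, best.s_end, best.strand),
                identity=best.identity,
                length=e - s + 1,
            )
        )
    # a wrap-origin homolog can shadow a partial duplicate found at the
    # start of the doubled sequence; merge circularly overlapping results
    merged: list = []
    for h in sorted(homologs, key=lambda x: -x.length):
        absorbed = False
        for m in merged:
            if _circular_overlap(m.mt_interval, h.mt_interval, L) > 0:
                absorbed = True
                if h.identity > m.identity:
                    m.identity, m.cp_interval = h.identity, h.cp_interval
                break
        if not absorbed:
            merged.append(h)
    merged.sort(key=lambda h: h.mt_interval.start)
    return merged


def _circular_overlap(a: Interval, b: Interval, L: int) -> int:
    def segs(iv):
        return [(iv.start, L), (1, iv.end)] if iv.wraps else [(iv.start, iv.end)]

    return sum(
        max(0, min(e1, e2) - max(s1, s2) + 1)
        for s1, e1 in segs(a)
        for s2, e2 in segs(b)
    )


def classify_homolog(h: PlastidHomolog, cp: AnnotatedGenome) -> str:
    """tRNA if the cp source overlaps a cp tRNA gene (precedence),
    photosynthesis for psa*/psb*/pet*/ndh*/rbcL overlap, else other."""
    src = Interval(
        min(h.cp_interval.start, h.cp_interval.end),
        max(h.cp_interval.start, h.cp_interval.end),
    )
    trna_hit = photo_hit = None
    for f in cp.features:
        for e in f.exons:
            ee = Interval(min(e.start, e.end), max(e.start, e.end))
            if _overlap_1d(src, ee) > 0:
                if f.category == "tRNA" and trna_hit is None:
                    trna_hit = f.locus
                elif _PHOTO_RE.match(f.locus) and photo_hit is None:
                    photo_hit = f.locus
    if trna_hit:
        h.klass, h.cp_gene = "tRNA", trna_hit
    elif photo_hit:
        h.klass, h.cp_gene = "photosynthesis", photo_hit
    else:
        h.klass = "other"
    return h.klass


def summarize_mtpt(pairs: Sequence[tuple], **scan_kwargs) -> list:
    """One summary row per (mt, cp) genome pair, from merged homologs.

    Each element of ``pairs`` is either ``(mt AnnotatedGenome, cp)`` — the
    scan is run — or ``(species, homolog list, genome_length)`` for
    precomputed results.
    """
    rows = []
    for item in pairs:
        if len(item) == 3 and isinstance(item[1], list):
            species, homologs, L = item
        else:
            mt, cp = item
            homologs = scan_plastid_homologs(mt, cp, **scan_kwargs)
            species = mt.species if isinstance(mt, AnnotatedGenome) else mt.id
            L = (mt.genome if isinstance(mt, AnnotatedGenome) else mt).length
        total = interval_union_length([h.mt_interval for h in homologs], L)
        rows.append(
            MtptSummary(species, total, len(homologs), round1(100.0 * total / L))
        )
    return rows


def _nearest_genes(
    homolog: PlastidHomolog, mt: AnnotatedGenome, window: int
) -> tuple:
    """Nearest annotated mt gene within ``window`` bp on each side."""
    L = mt.genome.length
    hv = homolog.mt_interval
    left = right = None
    left_d = right_d = window + 1
    for f in mt.features:
        if f.category in ("pseudogene", "remnant"):
            continue
        span = f.span(L)
        # distance from gene end to homolog start, going left around circle
        d_left = (hv.start - span.end - 1) % L
        d_right = (span.start - hv.end - 1) % L
        if d_left < left_d:
            left_d, left = d_left, f.label
        if d_right < right_d:
            right_d, right = d_right, f.label
    return (left if left_d <= window else None, right if right_d <= window else None)


def conserved_linkage(
    species_results: dict, window: int = 2000
) -> list:
    """Group identical (cp homolog, flanking mt gene) arrangements across
    species.

    ``species_results`` maps species name to ``(homolog list, mt
    AnnotatedGenome)``; homologs should be classified so tRNA-derived
    segments carry their cp gene label. Records are reported most-shared
    first.
    """
    arrangements: dict = {}
    for species, (homologs, mt) in species_results.items():
        for h in homologs:
            label = h.cp_gene or (
                f"cp:{h.cp_interval.start}-{h.cp_interval.end}"
            )
            left, right = _nearest_genes(h, mt, window)
            key = (label, left, right)
            arrangements.setdefault(key, set()).add(species)
    records = [
        LinkageRecord(label, left, right, tuple(sorted(sp)))
        for (label, left, right), sp in arrangements.items()
    ]
    records.sort(key=lambda r: (-len(r.species), r.homolog_label))
    return records
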