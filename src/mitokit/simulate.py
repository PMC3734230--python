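"""Synthetic plant-mtDNA generator with exact truth tables.

Emulates the composition of a large circular plant mitochondrial genome —
multi-exon and trans-spliced genes arranged in co-transcribed clusters,
repeat families from tens of bp to tens of kb in direct and inverted
orientation, chloroplast-derived insertions, cp-like and native tRNA genes,
pseudogene remnants — together with a matching annotated chloroplast
genome, so that every analysis stage can be exercised against known ground
truth without downloading data.

Background sequence is i.i.d. nucleotides at a target GC (0.45, typical of
plant mtDNA); divergence is applied as an exact count of point
substitutions (``floor(rate * length)`` at distinct positions), so a copy
planted at divergence d has identity exactly ``1 - d`` rounded up to the
nearest achievable value — planted truth never falls below its nominal
identity by sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from .model import AnnotatedGenome, GeneFeature, Genome, Interval, revcomp

__all__ = [
    "SimConfig",
    "GenePlan",
    "TrnaSpec",
    "RepeatSpec",
    "MtptSpec",
    "TruthTable",
    "generate_mt_genome",
    "generate_related_pair",
    "generate_species_set",
    "genome_from_order",
    "random_sequence",
    "mutate_sequence",
    "evolve_alignment",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_sequence(length: int, gc: float = 0.45, seed=0) -> str:
    """i.i.d. nucleotide string at the target GC fraction."""
    rng = _rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = _BASES[rng.choice(4, size=length, p=p)]
    return arr.tobytes().decode("ascii")


def mutate_sequence(seq: str, divergence: float, seed=0) -> str:
    """Apply exactly ``floor(divergence * len)`` substitutions, each to a
    different position and a different base."""
    rng = _rng(seed)
    n = int(np.floor(divergence * len(seq)))
    if n == 0:
        return seq
    arr = bytearray(seq, "ascii")
    pos = rng.choice(len(seq), size=n, replace=False)
    for p in pos:
        old = arr[p]
        choices = [b for b in b"ACGT" if b != old]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.decode("ascii")


# ------------------------------------------------------------------ plans


@dataclass(frozen=True)
class GenePlan:
    locus: str
    category: str = "protein"
    exon_lengths: tuple = (600,)
    intron_lengths: tuple = ()
    strand: str = "+"
    trans_block: Optional[str] = None
    cluster: Optional[str] = None  # genes sharing an id are placed adjacently
    gap_after: int = 150  # intergenic gap to the next cluster member


@dataclass(frozen=True)
class TrnaSpec:
    label: str
    origin: str = "native"  # native / cp_like
    divergence: float = 0.02  # for cp-like copies, relative to the cp gene
    length: int = 72


@dataclass(frozen=True)
class RepeatSpec:
    length: int
    copies: int = 2
    orientations: Optional[tuple] = None  # default all '+'
    divergence: float = 0.0


@dataclass(frozen=True)
class MtptSpec:
    length: int
    klass: str = "other"  # tRNA / photosynthesis / other (picks the cp source)
    divergence: float = 0.0
    strand: str = "+"


def _default_gene_roster() -> list:
    """Cotton-like roster: 35 protein loci (three trans-spliced), four rRNA
    features (one duplicated locus), ten co-transcribed clusters."""
    P = GenePlan
    roster = [
        # ten clusters of closely spaced, co-transcribed genes
        P("rpl16", cluster="c1", exon_lengths=(435,), gap_after=60),
        P("rps3", cluster="c1", exon_lengths=(900, 700), intron_lengths=(1100,)),
        P("cob", cluster="c2", exon_lengths=(1179,), gap_after=1363),
        P("rps14", cluster="c2", exon_lengths=(303,)),
        P("rpl2", cluster="c3", exon_lengths=(1005,), gap_after=497),
        P("rpl5", cluster="c3", exon_lengths=(582,), gap_after=1117),
        P("nad5", cluster="c3", trans_block="nad5c", exon_lengths=(22,)),
        P("nad2", cluster="c4", trans_block="nad2abc", exon_lengths=(390, 480, 580), intron_lengths=(120, 98), gap_after=899),
        P("sdh3", cluster="c4", exon_lengths=(435,)),
        P("mttB", cluster="c5", exon_lengths=(801,), gap_after=184),
        P("nad9", cluster="c5", exon_lengths=(573,)),
        P("sdh4", cluster="c6", exon_lengths=(399,), gap_after=80),
        P("cox3", cluster="c6", exon_lengths=(798,)),
        P("cox1", cluster="c7", exon_lengths=(1593,), gap_after=186),
        P("rps10", cluster="c7", exon_lengths=(500, 382), intron_lengths=(300,)),
        P("atp9", cluster="c8", exon_lengths=(312,), gap_after=220),
        P("nad5", cluster="c8", trans_block="nad5ab", exon_lengths=(966, 1333), intron_lengths=(980,)),
        P("nad3", cluster="c9", exon_lengths=(372,), gap_after=48),
        P("rps12", cluster="c9", exon_lengths=(357,)),
        P("nad1", cluster="c10", trans_block="nad1e", exon_lengths=(259,), gap_after=806),
        P("matR", cluster="c10", exon_lengths=(1968,), gap_after=661),
        P("nad1", cluster="c10", trans_block="nad1d", exon_lengths=(58,)),
        # singleton protein genes
        P("atp1", exon_lengths=(1530,)),
        P("atp4", exon_lengths=(594,)),
        P("atp6", exon_lengths=(1158,)),
        P("atp8", exon_lengths=(480,)),
        P("ccmB", exon_lengths=(621,)),
        P("ccmC", exon_lengths=(753,)),
        P("ccmFC", exon_lengths=(700, 660), intron_lengths=(1200,)),
        P("ccmFN", exon_lengths=(1743,)),
        P("cox2", exon_lengths=(450, 330), intron_lengths=(800,)),
        P("nad1", trans_block="nad1a", exon_lengths=(386,)),
        P("nad1", trans_block="nad1bc", exon_lengths=(191, 100), intron_lengths=(1000,)),
        P("nad2", trans_block="nad2de", exon_lengths=(460, 570), intron_lengths=(850,)),
        P("nad4", exon_lengths=(460, 520, 410, 90), intron_lengths=(700, 600, 500)),
        P("nad4L", exon_lengths=(303,)),
        P("nad5", trans_block="nad5de", exon_lengths=(150, 520), intron_lengths=(900,)),
        P("nad6", exon_lengths=(720,)),
        P("nad7", exon_lengths=(150, 200, 470, 250, 120), intron_lengths=(800, 700, 600, 500)),
        P("rps4", exon_lengths=(1050,)),
        P("rps7", exon_lengths=(447,)),
        # rRNA: rrn26 duplicated (two copies of one locus)
        P("rrn5", category="rRNA", exon_lengths=(118,)),
        P("rrn18", category="rRNA", exon_lengths=(1935,)),
        P("rrn26", category="rRNA", exon_lengths=(3374,)),
        P("rrn26", category="rRNA", exon_lengths=(3374,)),
        # degenerate traces of partially deleted genes
        P("rps19", category="remnant", exon_lengths=(54,)),
        P("rps1", category="remnant", exon_lengths=(120,)),
        P("rps3", category="pseudogene", exon_lengths=(1056,)),
    ]
    return roster


def _default_trna_roster() -> list:
    """29 tRNA features: 22 native + 7 cp-like (trnH/M/N/P/W with two
    duplicated cp-like copies), the cotton-like census."""
    native = [
        "trnC(GCA)", "trnD(GTC)", "trnE(TTC)", "trnF(GAA)", "trnG(GCC)",
        "trnI(CAT)", "trnK(TTT)", "trnL(CAA)", "trnQ(TTG)", "trnS(GCT)",
        "trnS(TGA)", "trnY(GTA)", "trnfM(CAT)", "trnfM(CAT)", "trnS(GCT)",
        "trnP(TGG)", "trnA(TGC)", "trnV(TAC)", "trnR(ACG)", "trnT(GGT)",
        "trnL(TAA)", "trnG(TCC)",
    ]
    cp_like = [
        "trnH(GTG)", "trnM(CAT)", "trnN(GTT)", "trnP(TGG)", "trnW(CCA)",
        "trnW(CCA)", "trnM(CAT)",
    ]
    return [TrnaSpec(l, "native") for l in native] + [
        TrnaSpec(l, "cp_like") for l in cp_like
    ]


def _default_repeat_plan(rng: np.random.Generator) -> list:
    """Repeat landscape shaped like a large plant mt genome: four families
    over 10 kb and hundreds of short scattered repeats."""
    plan = [
        RepeatSpec(27495, divergence=0.001),
        RepeatSpec(10623, orientations=("+", "-"), divergence=0.002),
        RepeatSpec(10302, orientations=("+", "-"), divergence=0.0),
        RepeatSpec(10251, divergence=0.001),
    ]
    # (size lo, size hi, family count, copy-count choices): copy numbers rise
    # in the middle size classes, as in published landscapes where class
    # totals far exceed twice the class size range
    classes = [
        (20, 40, 192, (2,)),
        (40, 60, 69, (2, 3, 4)),
        (60, 80, 35, (2, 3, 4, 5, 6)),
        (80, 100, 11, (6, 7, 8, 9, 10, 11)),
        (100, 300, 32, (2, 3, 4)),
    ]
    for lo, hi, n, copy_choices in classes:
        for _ in range(n):
            length = int(rng.integers(lo, hi))
            inverted = rng.random() < 0.4
            copies = int(rng.choice(copy_choices))
            orient = tuple(
                "+" if (i == 0 or not inverted) else "-" for i in range(copies)
            )
            plan.append(RepeatSpec(length, copies=copies, orientations=orient,
                                   divergence=float(rng.uniform(0, 0.1)) if length >= 100 else 0.0))
    return plan


def _default_mtpt_plan(rng: np.random.Generator) -> list:
    """27 plastid-derived insertions totalling 6,833 bp (36–2,185 bp each):
    12 tRNA-related, 3 photosynthesis-related, 12 other."""
    trna_sizes = [60, 65, 70, 72, 75, 78, 80, 85, 90, 95, 100, 110]
    photo_sizes = [300, 400, 500]
    other_sizes = [2185, 36, 45, 55, 120, 150, 180, 210, 240, 280, 460, 692]
    plan = []
    for sizes, klass in (
        (trna_sizes, "tRNA"),
        (photo_sizes, "photosynthesis"),
        (other_sizes, "other"),
    ):
        for s in sizes:
            plan.append(
                MtptSpec(
                    s,
                    klass=klass,
                    divergence=float(rng.uniform(0, 0.18)),
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
    return plan


# cp roster: (locus, category, length); names drive MTPT classification
_CP_ROSTER = (
    [(f"trn{x}", "tRNA", 72) for x in (
        "A(TGC)", "C(GCA)", "D(GTC)", "E(TTC)", "F(GAA)", "G(GCC)", "H(GTG)",
        "I(GAT)", "K(TTT)", "L(CAA)", "M(CAT)", "fM(CAT)", "N(GTT)", "P(TGG)",
        "Q(TTG)", "R(ACG)", "S(GCT)", "S(TGA)", "T(GGT)", "V(TAC)", "W(CCA)",
        "Y(GTA)",
    )]
    + [
        ("psbA", "protein", 1062),
        ("psaA", "protein", 2253),
        ("psaB", "protein", 2205),
        ("petA", "protein", 963),
        ("petB", "protein", 648),
        ("rbcL", "protein", 1428),
        ("ndhA", "protein", 1080),
        ("ndhB", "protein", 1530),
        ("matK", "protein", 1530),
        ("clpP", "protein", 600),
        ("rpoB", "protein", 3212),
        ("rrn16", "rRNA", 1490),
        ("rrn23", "rRNA", 2810),
    ]
)


@dataclass(kw_only=True)
class SimConfig:
    """Study conditions for one synthetic genome.

    Defaults emulate the upland-cotton-scale molecule: 620 kb circular at
    GC 0.45 with 68 genes (35 protein + 4 rRNA + 29 tRNA), a repeat
    landscape with four families over 10 kb, and 27 plastid-derived
    insertions totalling 6,833 bp. ``None`` plan fields are filled from the
    defaults at generation time (short-repeat sizes and insert divergences
    are drawn from the seeded generator).
    """

    seed: int
    length: int = 620_000
    gc: float = 0.45
    circular: bool = True
    species: str = "synthetic"
    group: Optional[str] = None
    genes: Optional[list] = None
    trnas: Optional[list] = None
    repeat_plan: Optional[list] = None
    mtpt_plan: Optional[list] = None
    cp_length: int = 120_000
    placement_margin: int = 40

    @classmethod
    def small(cls, seed: int, **kw) -> "SimConfig":
        """A scaled-down configuration for quick exercises: 60 kb genome,
        20 kb plastid, reduced rosters and plans."""
        genes = [
            GenePlan("cob", cluster="c1", exon_lengths=(1179,), gap_after=1363),
            GenePlan("rps14", cluster="c1", exon_lengths=(303,)),
            GenePlan("nad3", cluster="c2", exon_lengths=(372,), gap_after=48),
            GenePlan("rps12", cluster="c2", exon_lengths=(357,)),
            GenePlan("atp1", exon_lengths=(1530,)),
            GenePlan("atp9", exon_lengths=(312,)),
            GenePlan("cox1", exon_lengths=(1593,)),
            GenePlan("nad1", trans_block="nad1a", exon_lengths=(386,)),
            GenePlan("nad1", trans_block="nad1bc", exon_lengths=(191, 100), intron_lengths=(600,)),
            GenePlan("matR", exon_lengths=(1968,)),
            GenePlan("rrn5", category="rRNA", exon_lengths=(118,)),
            GenePlan("rrn18", category="rRNA", exon_lengths=(1935,)),
            GenePlan("rps19", category="remnant", exon_lengths=(54,)),
        ]
        trnas = [
            TrnaSpec("trnC(GCA)", "native"),
            TrnaSpec("trnD(GTC)", "native"),
            TrnaSpec("trnE(TTC)", "native"),
            TrnaSpec("trnY(GTA)", "native"),
            TrnaSpec("trnH(GTG)", "cp_like"),
            TrnaSpec("trnM(CAT)", "cp_like"),
            TrnaSpec("trnW(CCA)", "cp_like"),
            TrnaSpec("trnP(TGG)", "native"),
        ]
        repeat_plan = [
            RepeatSpec(5000, divergence=0.01),
            RepeatSpec(1500, orientations=("+", "-"), divergence=0.0),
            RepeatSpec(450, copies=3, orientations=("+", "+", "-"), divergence=0.02),
            RepeatSpec(120, orientations=("+", "-")),
            RepeatSpec(80),
            RepeatSpec(55, orientations=("+", "-")),
            RepeatSpec(30),
            RepeatSpec(22),
        ]
        mtpt_plan = [
            MtptSpec(36, klass="other", divergence=0.19),
            MtptSpec(75, klass="tRNA", divergence=0.05),
            MtptSpec(120, klass="tRNA", divergence=0.12, strand="-"),
            MtptSpec(400, klass="photosynthesis", divergence=0.08),
            MtptSpec(900, klass="other", divergence=0.15, strand="-"),
            MtptSpec(2185, klass="other", divergence=0.02),
        ]
        kw.setdefault("length", 75_000)
        kw.setdefault("cp_length", 32_000)
        return cls(
            seed=seed,
            genes=genes,
            trnas=trnas,
            repeat_plan=repeat_plan,
            mtpt_plan=mtpt_plan,
            **kw,
        )


# ------------------------------------------------------------------ truth


@dataclass
class TruthTable:
    """Exact record of everything planted in a generated genome or panel."""

    repeats: list = field(default_factory=list)  # dicts: copies, divergence, length
    mtpt: list = field(default_factory=list)  # dicts: mt_interval, cp_interval, klass, ...
    trnas: list = field(default_factory=list)  # (label, origin, Interval)
    gene_order: list = field(default_factory=list)  # [(label, strand)]
    clusters: dict = field(default_factory=dict)  # id -> (labels, strands)
    shared_adjacencies: Optional[int] = None
    orders: Optional[dict] = None  # species -> [(label, strand)]
    branch_events: Optional[dict] = None
    tip_trnas: Optional[dict] = None
    tree_distances: Optional[pd.DataFrame] = None


class _Allocator:
    """Non-overlapping placement of blocks on [1, L] with a safety margin.

    Free space is tracked as explicit gap segments; a block is placed at a
    uniform position inside a capacity-weighted random gap, so placement
    succeeds whenever the plan physically fits, independent of load order.
    """

    def __init__(self, length: int, rng: np.random.Generator, margin: int,
                 origin_buffer: int = 2000):
        self.L = length
        self.rng = rng
        self.margin = margin
        # keep a clear zone around the origin so blocks at the two linear
        # ends are never circular neighbours
        buf = min(origin_buffer, length // 10)
        self.free = [(1 + buf, length - buf)]

    def place(self, size: int, margin: Optional[int] = None) -> int:
        margin = self.margin if margin is None else margin
        need = size + margin
        candidates = [
            (i, (e - s + 1) - need + 1)
            for i, (s, e) in enumerate(self.free)
            if (e - s + 1) >= need
        ]
        if not candidates:
            free_bp = sum(e - s + 1 for s, e in self.free)
            raise ValueError(
                f"placement overflow: no gap fits a {size} bp block "
                f"({free_bp} bp free in fragments on a {self.L} bp genome)"
            )
        weights = np.array([c[1] for c in candidates], dtype=float)
        pick = int(self.rng.choice(len(candidates), p=weights / weights.sum()))
        gi, _ = candidates[pick]
        s, e = self.free[gi]
        # place against a gap edge so the remainder stays contiguous —
        # interior placement would fragment free space and starve later
        # large blocks
        if self.rng.random() < 0.5:
            pos = s
            repl = [(pos + size + margin, e)]
        else:
            pos = e - size + 1
            repl = [(s, pos - 1 - margin)]
        self.free[gi : gi + 1] = [seg for seg in repl if seg[1] >= seg[0]]
        return pos  # 1-based start


def _write(seq: bytearray, pos: int, segment: str) -> None:
    seq[pos - 1 : pos - 1 + len(segment)] = segment.encode("ascii")


def _generate_cp(cfg: SimConfig, rng: np.random.Generator) -> AnnotatedGenome:
    seq = bytearray(random_sequence(cfg.cp_length, cfg.gc, rng), "ascii")
    alloc = _Allocator(cfg.cp_length, rng, cfg.placement_margin)
    features = []
    counts: dict = {}
    for locus, category, length in sorted(_CP_ROSTER, key=lambda x: -x[2]):
        pos = alloc.place(length)
        counts[locus] = counts.get(locus, 0) + 1
        features.append(
            GeneFeature(
                locus, category, (Interval(pos, pos + length - 1, "+"),),
                copy_index=counts[locus],
            )
        )
    genome = Genome(cfg.species + "_cp", bytes(seq).decode("ascii"), circular=True)
    return AnnotatedGenome(genome, sorted(features, key=lambda f: f.start()),
                           species=cfg.species + " chloroplast")


def generate_mt_genome(cfg: SimConfig):
    """Generate one annotated mt genome, its cp partner and the truth table.

    Deterministic for a fixed seed. Genes (in their clusters), repeat
    copies, plastid insertions and tRNAs are placed without unplanned
    overlap; an infeasible plan raises with the overflow amount.
    """
    rng = np.random.default_rng(cfg.seed)
    cp = _generate_cp(cfg, rng)
    genes = cfg.genes if cfg.genes is not None else _default_gene_roster()
    trnas = cfg.trnas if cfg.trnas is not None else _default_trna_roster()
    repeat_plan = (
        cfg.repeat_plan if cfg.repeat_plan is not None else _default_repeat_plan(rng)
    )
    mtpt_plan = cfg.mtpt_plan if cfg.mtpt_plan is not None else _default_mtpt_plan(rng)

    seq = bytearray(random_sequence(cfg.length, cfg.gc, rng), "ascii")
    alloc = _Allocator(cfg.length, rng, cfg.placement_margin)
    truth = TruthTable()
    features: list = []
    counts: dict = {}

    def add_feature(plan: GenePlan, start: int) -> int:
        """Lay out exons/introns from ``start``; returns the end coordinate."""
        exons = []
        pos = start
        for i, ex in enumerate(plan.exon_lengths):
            exons.append(Interval(pos, pos + ex - 1, plan.strand))
            pos += ex
            if i < len(plan.intron_lengths):
                pos += plan.intron_lengths[i]
        if plan.strand == "-":
            exons = exons[::-1]  # exon order follows transcription
        key = (plan.locus, plan.trans_block)
        counts[key] = counts.get(key, 0) + 1
        features.append(
            GeneFeature(plan.locus, plan.category, tuple(exons),
                        plan.trans_block, counts[key])
        )
        return pos - 1

    # gene clusters placed as blocks, singletons individually
    by_cluster: dict = {}
    singles: list = []
    for plan in genes:
        if plan.cluster:
            by_cluster.setdefault(plan.cluster, []).append(plan)
        else:
            singles.append(plan)
    # genes get a wide randomised berth so distinct clusters stay separated
    # by more than any cluster-calling gap threshold
    def gene_margin() -> int:
        return int(rng.integers(1600, 2600))

    for cid, members in by_cluster.items():
        span = sum(
            sum(m.exon_lengths) + sum(m.intron_lengths) for m in members
        ) + sum(m.gap_after for m in members[:-1])
        start = alloc.place(span, margin=gene_margin())
        strand = members[0].strand
        pos = start
        labels, strands = [], []
        for m in members:
            m_end = add_feature(
                GenePlan(m.locus, m.category, m.exon_lengths, m.intron_lengths,
                         strand, m.trans_block, m.cluster, m.gap_after),
                pos,
            )
            labels.append(m.trans_block or m.locus)
            strands.append(strand)
            pos = m_end + 1 + m.gap_after
        truth.clusters[cid] = (labels, strands)
    for plan in singles:
        span = sum(plan.exon_lengths) + sum(plan.intron_lengths)
        start = alloc.place(span, margin=gene_margin())
        add_feature(plan, start)

    # repeat families: a fresh random source per family, copies placed apart
    for spec in repeat_plan:
        orients = spec.orientations or tuple("+" for _ in range(spec.copies))
        if len(orients) != spec.copies:
            raise ValueError("orientations length must equal copy count")
        source = random_sequence(spec.length, cfg.gc, rng)
        copies = []
        for orient in orients:
            copy_seq = mutate_sequence(source, spec.divergence, rng) if copies else source
            if orient == "-":
                copy_seq = revcomp(copy_seq)
            # separate copies by more than any chaining gap so a family is
            # never planted as a tandem array
            pos = alloc.place(spec.length, margin=int(rng.integers(100, 250)))
            _write(seq, pos, copy_seq)
            copies.append((Interval(pos, pos + spec.length - 1), orient))
        truth.repeats.append(
            {"copies": copies, "divergence": spec.divergence, "length": spec.length}
        )

    # plastid-derived insertions copied from class-appropriate cp regions
    cp_trnas = cp.by_category("tRNA")
    cp_photo = [f for f in cp.features
                if f.category == "protein" and f.locus[:3] in ("psa", "psb", "pet", "ndh")
                or f.locus == "rbcL"]
    # 'other' sources must only avoid tRNA and photosynthesis genes — overlap
    # with e.g. matK/rpoB/rrn loci still classifies as 'other'
    cp_avoid = sorted(
        (f.span(cp.genome.length).start, f.span(cp.genome.length).end)
        for f in cp_trnas + cp_photo
    )

    def cp_source(spec: MtptSpec) -> Interval:
        if spec.klass == "tRNA":
            f = cp_trnas[int(rng.integers(0, len(cp_trnas)))]
        elif spec.klass == "photosynthesis":
            f = cp_photo[int(rng.integers(0, len(cp_photo)))]
        else:
            for _ in range(300):
                s = int(rng.integers(1, cp.genome.length - spec.length))
                e = s + spec.length - 1
                if all(e < a or s > b for a, b in cp_avoid):
                    return Interval(s, e)
            raise ValueError("no tRNA/photosynthesis-free cp source available")
        span = f.span(cp.genome.length)
        mid = (span.start + span.end) // 2
        s = max(1, min(mid - spec.length // 2, cp.genome.length - spec.length))
        return Interval(s, s + spec.length - 1)

    for spec in mtpt_plan:
        src = cp_source(spec)
        segment = cp.genome.seq[src.start - 1 : src.end]
        segment = mutate_sequence(segment, spec.divergence, rng)
        if spec.strand == "-":
            segment = revcomp(segment)
        pos = alloc.place(spec.length)
        _write(seq, pos, segment)
        truth.mtpt.append(
            {
                "mt_interval": Interval(pos, pos + spec.length - 1),
                "cp_interval": src,
                "klass": spec.klass,
                "divergence": spec.divergence,
                "length": spec.length,
            }
        )

    # tRNA genes: native are fresh random sequence, cp-like copy the cp gene
    cp_by_label = {}
    for f in cp_trnas:
        cp_by_label.setdefault(f.locus, f)
    for spec in trnas:
        if spec.origin == "cp_like":
            f = cp_by_label.get(spec.label)
            if f is None:
                raise ValueError(f"cp roster lacks {spec.label} for a cp-like tRNA")
            segment = mutate_sequence(cp.feature_sequence(f), spec.divergence, rng)
        else:
            segment = random_sequence(spec.length, cfg.gc, rng)
        pos = alloc.place(len(segment))
        _write(seq, pos, segment)
        iv = Interval(pos, pos + len(segment) - 1, "+")
        key = (spec.label, None)
        counts[key] = counts.get(key, 0) + 1
        features.append(GeneFeature(spec.label, "tRNA", (iv,), None, counts[key]))
        truth.trnas.append((spec.label, spec.origin, iv))
        if spec.origin == "cp_like":
            f = cp_by_label[spec.label]
            truth.mtpt.append(
                {
                    "mt_interval": iv,
                    "cp_interval": f.span(cp.genome.length),
                    "klass": "tRNA",
                    "divergence": spec.divergence,
                    "length": len(segment),
                }
            )

    features.sort(key=lambda f: f.start())
    genome = Genome(cfg.species, bytes(seq).decode("ascii"), circular=cfg.circular)
    mt = AnnotatedGenome(genome, features, species=cfg.species, group=cfg.group)
    truth.gene_order = [
        (f.label, f.strand)
        for f in sorted(mt.by_category("protein", "rRNA"), key=lambda f: (f.start(), f.label))
    ]
    return mt, cp, truth


# ------------------------------------------------- related pairs / panels


def _adjacency_set(entries: Sequence[tuple]) -> set:
    """Independent circular adjacency enumeration used for truth tables."""
    n = len(entries)
    keys = set()
    for i in range(n):
        (la, sa), (lb, sb) = entries[i], entries[(i + 1) % n]
        rel = "same" if sa == sb else "opposite"
        keys.add((tuple(sorted((la, lb))), rel))
        if n == 2:
            break
    return keys


def _shared_pair_count(o1, o2) -> int:
    common = _adjacency_set(o1) & _adjacency_set(o2)
    return len({pair for pair, _ in common})


def _genome_arcs(g: AnnotatedGenome):
    """Cut the circle into one arc per protein/rRNA feature, cutting midway
    through each intergenic gap; returns rotated arcs starting at a cut."""
    L = g.genome.length
    feats = sorted(g.by_category("protein", "rRNA"), key=lambda f: (f.start(), f.label))
    others = [f for f in g.features if f.category not in ("protein", "rRNA")]
    n = len(feats)
    spans = [f.span(L) for f in feats]
    cuts = []
    for i in range(n):
        end_i = spans[i].end
        start_next = spans[(i + 1) % n].start
        gap = (start_next - end_i - 1) % L
        cuts.append((end_i + 1 + gap // 2 - 1) % L + 1)  # cut point after arc i
    arcs = []
    for i in range(n):
        a0 = cuts[(i - 1) % n] % L + 1
        a1 = cuts[i]
        arcs.append((a0, a1, feats[i]))
    # rotate sequence so that the first arc starts at position 1
    shift = -(arcs[0][0] - 1)
    seq = g.genome.seq
    rot = seq[arcs[0][0] - 1 :] + seq[: arcs[0][0] - 1]
    out = []
    for a0, a1, f in arcs:
        s0 = (a0 - 1 + shift) % L
        s1 = (a1 - 1 + shift) % L
        arc_seq = rot[s0 : s1 + 1] if s1 >= s0 else rot[s0:] + rot[: s1 + 1]
        rel_exons = tuple(
            Interval(
                (e.start - 1 + shift) % L - s0 + 1,
                (e.end - 1 + shift) % L - s0 + 1,
                e.strand,
            )
            for e in f.exons
        )
        out.append({"seq": arc_seq, "feature": f, "exons": rel_exons, "flipped": False})
    # non-ordered features (tRNA etc.) are dropped from rearranged copies
    return out


def _assemble_arcs(arcs, species: str) -> AnnotatedGenome:
    parts = []
    features = []
    pos = 1
    counts: dict = {}
    for arc in arcs:
        m = len(arc["seq"])
        if arc["flipped"]:
            seq = revcomp(arc["seq"])
            exons = tuple(
                Interval(m - e.end + 1 + pos - 1, m - e.start + 1 + pos - 1,
                         "+" if e.strand == "-" else "-")
                for e in reversed(arc["exons"])
            )
        else:
            seq = arc["seq"]
            exons = tuple(
                Interval(e.start + pos - 1, e.end + pos - 1, e.strand)
                for e in arc["exons"]
            )
        f = arc["feature"]
        key = (f.locus, f.trans_block)
        counts[key] = counts.get(key, 0) + 1
        features.append(
            GeneFeature(f.locus, f.category, exons, f.trans_block, counts[key])
        )
        parts.append(seq)
        pos += m
    genome = Genome(species, "".join(parts), circular=True)
    features.sort(key=lambda f: f.start())
    return AnnotatedGenome(genome, features, species=species)


def generate_related_pair(
    cfg: SimConfig, n_inversions: int = 1, n_transpositions: int = 0
):
    """Genome B = genome A after scripted gene-block rearrangements.

    Inversions reverse an internal block of 2..n-2 consecutive order units
    (reverse-complementing the sequence); transpositions move a block to a
    new position. Blocks never split genes. The truth table records both
    orders and the exact surviving shared-adjacency count.
    """
    mt, cp, truth = generate_mt_genome(cfg)
    rng = np.random.default_rng(cfg.seed + 101)
    arcs = _genome_arcs(mt)
    n = len(arcs)
    if n_inversions + n_transpositions > 0 and n < 4:
        raise ValueError("rearrangements need at least four ordered genes")
    for _ in range(n_inversions):
        k = int(rng.integers(2, n - 1))  # block of 2..n-2 units
        i = int(rng.integers(0, n - k))
        block = arcs[i : i + k][::-1]
        for arc in block:
            arc["flipped"] = not arc["flipped"]
        arcs[i : i + k] = block
    for _ in range(n_transpositions):
        k = int(rng.integers(1, max(2, n // 3)))
        i = int(rng.integers(0, n - k))
        block = arcs[i : i + k]
        rest = arcs[:i] + arcs[i + k :]
        j = int(rng.integers(0, len(rest) + 1))
        arcs = rest[:j] + block + rest[j:]
    b = _assemble_arcs(arcs, mt.species + "_rearranged")
    order_a = truth.gene_order
    order_b = [
        (f.label, f.strand)
        for f in sorted(b.by_category("protein", "rRNA"), key=lambda f: (f.start(), f.label))
    ]
    truth.orders = {mt.species: order_a, b.species: order_b}
    truth.shared_adjacencies = _shared_pair_count(order_a, order_b)
    return mt, b, truth


def genome_from_order(
    entries: Sequence[tuple],
    seed: int = 0,
    species: str = "ordered",
    group: Optional[str] = None,
    gene_length: int = 300,
    gap: int = 200,
    category: str = "protein",
) -> AnnotatedGenome:
    """Small genome realising an explicit circular gene order.

    ``entries`` are (label, strand) pairs; labels may repeat (duplicate
    copies). Convenient for engineering synteny scenarios directly.
    """
    rng = np.random.default_rng(seed)
    parts = []
    features = []
    pos = 1
    counts: dict = {}
    for label, strand in entries:
        pad = random_sequence(gap, 0.45, rng)
        gene = random_sequence(gene_length, 0.45, rng)
        parts.extend([pad, gene])
        s = pos + gap
        counts[label] = counts.get(label, 0) + 1
        features.append(
            GeneFeature(label, category, (Interval(s, s + gene_length - 1, strand),),
                        None, counts[label])
        )
        pos = s + gene_length
    parts.append(random_sequence(gap, 0.45, rng))
    genome = Genome(species, "".join(parts), circular=True)
    return AnnotatedGenome(genome, features, species=species, group=group)


def _clade_key(node) -> tuple:
    return tuple(sorted(leaf.taxon.label for leaf in node.leaf_iter()))


def generate_species_set(
    tree: Union[str, dendropy.Tree],
    cfg: SimConfig,
    events: Optional[dict] = None,
    subst_rate: float = 0.0,
    turnover_rate: float = 0.0,
    groups: Optional[dict] = None,
):
    """Evolve the configured genome down a species tree.

    ``events`` maps a branch — keyed by the sorted tuple of tip labels below
    it — to a list of scripted operations: ``("gain", trn_label)`` inserts a
    cp-like tRNA copy, ``("loss", trn_label)`` deletes a tRNA gene and
    randomises its sequence, ``("invert", k)`` reverses a block of k ordered
    genes in place. ``subst_rate`` is substitutions per site per unit branch
    length, applied as exact counts. ``turnover_rate`` is the fraction of
    the genome replaced per unit branch length by fresh random sequence in
    feature-free chunks — the rapid gain/loss of intergenic DNA that
    dominates divergence between real plant mt genomes. Tips become species
    named after the taxa; the one cp genome is shared by the panel.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    events = events or {}
    root_mt, cp, truth = generate_mt_genome(cfg)
    rng = np.random.default_rng(cfg.seed + 202)
    L = root_mt.genome.length
    for key in events:
        if tuple(sorted(key)) != tuple(key):
            raise ValueError(f"event branch key must be sorted: {key}")
    valid_keys = {_clade_key(nd) for nd in tree.preorder_node_iter()}
    unknown = set(events) - valid_keys
    if unknown:
        raise ValueError(f"event script names branches not in the tree: {sorted(unknown)}")

    cp_trna = {}
    for f in cp.by_category("tRNA"):
        cp_trna.setdefault(f.locus, f)

    def apply_branch(state, node, edge_length):
        seq, feats, trn = state
        seq = bytearray(seq, "ascii")
        feats = list(feats)
        trn = dict(trn)
        nsub = int(np.floor(subst_rate * (edge_length or 0.0) * L))
        if nsub:
            mutated = mutate_sequence(bytes(seq).decode("ascii"), nsub / L, rng)
            seq = bytearray(mutated, "ascii")
        turn_bp = int(np.floor(turnover_rate * (edge_length or 0.0) * L))
        if turn_bp:
            spans = sorted((f.span(L).start, f.span(L).end) for f in feats)
            done: list = []  # chunks replaced on this branch (no double count)
            replaced = 0
            guard = 0
            while replaced < turn_bp and guard < 20_000:
                guard += 1
                chunk = int(rng.integers(200, 600))
                pos = int(rng.integers(1, L - chunk))
                end = pos + chunk - 1
                if any(pos <= b and end >= a for a, b in spans):
                    continue
                if any(pos <= b and end >= a for a, b in done):
                    continue
                seq[pos - 1 : pos - 1 + chunk] = random_sequence(
                    chunk, cfg.gc, rng
                ).encode("ascii")
                done.append((pos, end))
                replaced += chunk
        for op, arg in events.get(_clade_key(node), []):
            if op == "gain":
                f = cp_trna.get(arg)
                if f is None:
                    raise ValueError(f"cp roster lacks tRNA {arg}")
                segment = mutate_sequence(cp.feature_sequence(f), 0.02, rng)
                pos = _free_position(feats, L, len(segment), rng)
                seq[pos - 1 : pos - 1 + len(segment)] = segment.encode("ascii")
                iv = Interval(pos, pos + len(segment) - 1, "+")
                feats.append(GeneFeature(arg, "tRNA", (iv,), None,
                                         max((f2.copy_index for f2 in feats
                                              if f2.locus == arg), default=0) + 1))
                trn[arg] = "cp_like"
            elif op == "loss":
                victim = next((f2 for f2 in feats
                               if f2.category == "tRNA" and f2.locus == arg), None)
                if victim is None:
                    raise ValueError(f"loss of absent tRNA {arg}")
                span = victim.span(L)
                seq[span.start - 1 : span.end] = random_sequence(
                    span.end - span.start + 1, cfg.gc, rng
                ).encode("ascii")
                feats.remove(victim)
                if not any(f2.locus == arg and f2.category == "tRNA" for f2 in feats):
                    trn.pop(arg, None)
            elif op == "invert":
                feats, seq = _invert_block(feats, seq, L, int(arg), rng)
            else:
                raise ValueError(f"unknown scripted operation {op!r}")
        return bytes(seq).decode("ascii"), feats, trn

    root_trn = {label: origin for label, origin, _ in truth.trnas}
    states = {id(tree.seed_node): (root_mt.genome.seq, root_mt.features, root_trn)}
    tips: dict = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            state = states[id(node)]
            # root-branch events (key = all tips) are applied to the root state
            state = apply_branch(state, node, 0.0) if _clade_key(node) in events else state
            states[id(node)] = state
            continue
        parent_state = states[id(node.parent_node)]
        state = apply_branch(parent_state, node, node.edge.length or 1.0)
        states[id(node)] = state
        if node.is_leaf():
            tips[node.taxon.label] = state

    genomes = []
    tip_trnas = {}
    for label, (seq, feats, trn) in sorted(tips.items()):
        genome = Genome(label, seq, circular=True)
        feats = sorted(feats, key=lambda f: f.start())
        genomes.append(
            AnnotatedGenome(genome, feats, species=label,
                            group=(groups or {}).get(label))
        )
        tip_trnas[label] = dict(trn)
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(tips)
    dist = pd.DataFrame(0.0, index=labels, columns=labels)
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            if t1.label in labels and t2.label in labels:
                dist.loc[t1.label, t2.label] = pdm.patristic_distance(t1, t2)
    truth.branch_events = events
    truth.tip_trnas = tip_trnas
    truth.tree_distances = dist
    return genomes, cp, truth


def _free_position(feats, L: int, size: int, rng) -> int:
    spans = sorted((f.span(L).start, f.span(L).end) for f in feats)
    for _ in range(400):
        pos = int(rng.integers(2, L - size - 2))
        if all(pos + size - 1 < a or pos > b for a, b in spans):
            return pos
    raise ValueError("no free region for insertion")


def _invert_block(feats, seq: bytearray, L: int, k: int, rng):
    ordered = sorted(
        (f for f in feats if f.category in ("protein", "rRNA")),
        key=lambda f: f.start(),
    )
    n = len(ordered)
    if not 1 <= k <= n - 1:
        raise ValueError(f"cannot invert a block of {k} of {n} ordered genes")
    i = int(rng.integers(0, n - k))
    block = ordered[i : i + k]
    s = min(f.span(L).start for f in block)
    e = max(f.span(L).end for f in block)
    # nothing else may live inside the reversed window
    inside = [f for f in feats if s <= f.span(L).start and f.span(L).end <= e]
    segment = bytes(seq[s - 1 : e]).decode("ascii")
    seq[s - 1 : e] = revcomp(segment).encode("ascii")
    new_feats = [f for f in feats if f not in inside]
    for f in inside:
        exons = tuple(
            Interval(s + e - x.end, s + e - x.start, "+" if x.strand == "-" else "-")
            for x in reversed(f.exons)
        )
        new_feats.append(GeneFeature(f.locus, f.category, exons, f.trans_block, f.copy_index))
    return new_feats, seq


def evolve_alignment(
    tree: Union[str, dendropy.Tree],
    length: int,
    rate: float,
    seed: int,
    name: str = "locus",
):
    """Ungapped alignment evolved down a tree by exact-count substitutions.

    Jukes-Cantor-like: each branch applies ``floor(rate * branch_length *
    length)`` substitutions at distinct sites. Returns a
    :class:`mitokit.phylo.LocusAlignment`.
    """
    from .phylo import LocusAlignment

    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)
    root = random_sequence(length, 0.5, rng)
    seqs = {id(tree.seed_node): root}
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = seqs[id(node.parent_node)]
        d = rate * (node.edge.length or 1.0)
        seqs[id(node)] = mutate_sequence(parent, d, rng)
        if node.is_leaf():
            out[node.taxon.label] = seqs[id(node)]
    return LocusAlignment(name, out)
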