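"""Reading and writing annotated organelle genomes.

Supported formats:

* GenBank flat files (via Biopython) — the usual source of published
  organelle annotations; ``join``/``complement`` locations become multi-exon
  features, origin-spanning locations become single wrap intervals.
* FASTA plus a tab-separated feature table — the package's lossless native
  format (columns: locus, category, strand, exons as ``start..end`` joined by
  commas, trans_block, copy_index).
* GFF3 output (1-based) and BED output (0-based half-open).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import AnnotatedGenome, GeneFeature, Genome, Interval

__all__ = [
    "read_annotated_genome",
    "write_annotated_genome",
    "read_genbank",
    "write_genbank",
    "read_feature_table",
    "write_feature_table",
    "write_gff3",
    "read_gff3",
    "write_bed",
    "write_fasta",
]

_CATEGORY_TO_GB = {
    "protein": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "pseudogene": "gene",
    "remnant": "misc_feature",
}


def read_annotated_genome(path, format: str = "genbank") -> AnnotatedGenome:
    """Read an annotated genome; ``format`` is ``genbank`` or ``fasta+features``.

    For ``fasta+features``, ``path`` is the FASTA path and a sibling file with
    suffix ``.features.tsv`` is expected (or pass a ``(fasta, table)`` tuple).
    """
    if format == "genbank":
        return read_genbank(path)
    if format == "fasta+features":
        if isinstance(path, (tuple, list)):
            fasta, table = path
        else:
            fasta = Path(path)
            table = fasta.with_suffix(".features.tsv")
        return read_feature_table(fasta, table)
    raise ValueError(f"unknown format {format!r}")


def write_annotated_genome(g: AnnotatedGenome, path, format: str = "genbank") -> None:
    if format == "genbank":
        write_genbank(g, path)
    elif format == "fasta+features":
        fasta = Path(path)
        write_fasta(g.genome, fasta)
        write_feature_table(g, fasta.with_suffix(".features.tsv"))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------- GenBank


def _location_to_exons(loc, genome_length: int) -> list:
    """Convert a Biopython location to 1-based inclusive exon intervals.

    Adjacent parts that abut through the origin (``x..L`` followed by ``1..y``)
    are re-joined into a single wrap interval.
    """
    strand = "-" if loc.strand == -1 else "+"
    parts = list(loc.parts)
    if strand == "-":
        # Biopython stores complement(join(...)) parts in genome order; exon
        # order for a minus-strand gene is reversed
        parts = parts[::-1]
    exons = []
    for p in parts:
        s = int(p.start) + 1
        e = int(p.end)
        if s < 1 or e > genome_length:
            raise ValueError(f"feature coordinate out of range: {s}..{e}")
        exons.append(Interval(s, e, strand))
    # merge origin-spanning split (plus strand: ...L then 1...; minus: 1.. then ..L)
    merged = []
    for iv in exons:
        if merged:
            prev = merged[-1]
            if strand == "+" and prev.end == genome_length and iv.start == 1:
                merged[-1] = Interval(prev.start, iv.end, strand)
                continue
            if strand == "-" and prev.start == 1 and iv.end == genome_length:
                merged[-1] = Interval(iv.start, prev.end, strand)
                continue
        merged.append(iv)
    return merged


def _exons_to_location(f: GeneFeature, genome_length: int):
    strand = 1 if f.strand == "+" else -1
    simple = []
    for iv in f.exons:
        if iv.wraps:
            a = SimpleLocation(iv.start - 1, genome_length, strand)
            b = SimpleLocation(0, iv.end, strand)
            simple.extend([a, b] if strand == 1 else [b, a])
        else:
            simple.append(SimpleLocation(iv.start - 1, iv.end, strand))
    if strand == -1:
        simple = simple[::-1]
    if len(simple) == 1:
        return simple[0]
    return CompoundLocation(simple)


def read_genbank(path) -> AnnotatedGenome:
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"malformed GenBank file {path}: {exc}") from exc
    genome = Genome(
        rec.id or rec.name,
        str(rec.seq),
        circular=rec.annotations.get("topology", "circular") == "circular",
    )
    features = []
    counts: dict = {}
    for ft in rec.features:
        if ft.type in ("source", "gene"):
            if ft.type == "gene" and "pseudo" not in ft.qualifiers:
                continue
        category = _gb_type_to_category(ft)
        if category is None:
            continue
        locus = ft.qualifiers.get("gene", ft.qualifiers.get("locus_tag", ["?"]))[0]
        note = ft.qualifiers.get("note", [])
        trans_block = None
        copy_index = None
        for n in note:
            for part in n.split(";"):
                part = part.strip()
                if part.startswith("trans_block:"):
                    trans_block = part.split(":", 1)[1]
                elif part.startswith("copy_index:"):
                    copy_index = int(part.split(":", 1)[1])
        exons = _location_to_exons(ft.location, genome.length)
        if copy_index is None:
            key = (locus, trans_block)
            counts[key] = counts.get(key, 0) + 1
            copy_index = counts[key]
        features.append(
            GeneFeature(locus, category, tuple(exons), trans_block, copy_index)
        )
    species = rec.annotations.get("organism", "") or ""
    if species in ("", "."):
        species = rec.id
    return AnnotatedGenome(genome, features, species=species)


def _gb_type_to_category(ft) -> Optional[str]:
    note = ";".join(ft.qualifiers.get("note", []))
    if "category:remnant" in note:
        return "remnant"
    if "pseudo" in ft.qualifiers or "category:pseudogene" in note:
        return "pseudogene"
    return {"CDS": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}.get(ft.type)


def write_genbank(g: AnnotatedGenome, path) -> None:
    rec = SeqRecord(
        Seq(g.genome.seq),
        id=g.genome.id,
        name=g.genome.id[:16].replace(" ", "_"),
        description=g.species,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if g.genome.circular else "linear",
            "organism": g.species,
        },
    )
    for f in g.features:
        gb_type = _CATEGORY_TO_GB[f.category]
        quals = {"gene": [f.locus]}
        note = [f"copy_index:{f.copy_index}"]
        if f.trans_block:
            note.append(f"trans_block:{f.trans_block}")
        if f.category == "pseudogene":
            quals["pseudo"] = [""]
        if f.category == "remnant":
            note.append("category:remnant")
        quals["note"] = [";".join(note)]
        rec.features.append(
            SeqFeature(_exons_to_location(f, g.genome.length), gb_type, qualifiers=quals)
        )
    with open(path, "w") as fh:
        SeqIO.write(rec, fh, "genbank")


# ---------------------------------------------------- FASTA + feature table

_TABLE_HEADER = "locus\tcategory\tstrand\texons\ttrans_block\tcopy_index"


def write_fasta(g: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{g.id} {'circular' if g.circular else 'linear'}\n")
        for i in range(0, len(g.seq), 70):
            fh.write(g.seq[i : i + 70] + "\n")


def read_fasta(path) -> Genome:
    rec = next(SeqIO.parse(str(path), "fasta"))
    circular = "linear" not in rec.description.split()
    return Genome(rec.id, str(rec.seq), circular=circular)


def write_feature_table(g: AnnotatedGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# species={g.species}\tgroup={g.group or '-'}\n")
        fh.write(_TABLE_HEADER + "\n")
        for f in g.features:
            exons = ",".join(f"{e.start}..{e.end}" for e in f.exons)
            fh.write(
                f"{f.locus}\t{f.category}\t{f.strand}\t{exons}\t"
                f"{f.trans_block or '-'}\t{f.copy_index}\n"
            )


def read_feature_table(fasta_path, table_path) -> AnnotatedGenome:
    genome = read_fasta(fasta_path)
    features = []
    species, group = genome.id, None
    with open(table_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for kv in line[1:].split("\t"):
                    k, _, v = kv.strip().partition("=")
                    if k == "species":
                        species = v
                    elif k == "group" and v != "-":
                        group = v
                continue
            if line.startswith("locus\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{table_path}:{lineno}: expected 6 columns")
            locus, category, strand, exons_s, tb, ci = parts
            exons = []
            for tok in exons_s.split(","):
                try:
                    s, e = tok.split("..")
                    exons.append(Interval(int(s), int(e), strand))
                except Exception as exc:
                    raise ValueError(
                        f"{table_path}:{lineno}: malformed exon {tok!r}"
                    ) from exc
            features.append(
                GeneFeature(
                    locus,
                    category,
                    tuple(exons),
                    None if tb == "-" else tb,
                    int(ci),
                )
            )
    return AnnotatedGenome(genome, features, species=species, group=group)


# ------------------------------------------------------------- GFF3 / BED


def write_gff3(g: AnnotatedGenome, path) -> None:
    """One GFF3 line per exon, grouped by an ID shared within each feature.

    Wrap exons are emitted as two lines carrying the same ID.
    """
    L = g.genome.length
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {g.genome.id} 1 {L}\n")
        for f in g.features:
            fid = f.locus + (f".{f.trans_block}" if f.trans_block else "") + f".{f.copy_index}"
            attrs = f"ID={fid};locus={f.locus};category={f.category};copy_index={f.copy_index}"
            if f.trans_block:
                attrs += f";trans_block={f.trans_block}"
            for e in f.exons:
                pieces = [(e.start, L), (1, e.end)] if e.wraps else [(e.start, e.end)]
                for s, t in pieces:
                    fh.write(
                        f"{g.genome.id}\tmitokit\texon\t{s}\t{t}\t.\t{f.strand}\t.\t{attrs}\n"
                    )


def read_gff3(gff_path, fasta_path) -> AnnotatedGenome:
    genome = read_fasta(fasta_path)
    L = genome.length
    groups: dict = {}
    order: list = []
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{gff_path}:{lineno}: expected 9 columns")
            _, _, _, s, e, _, strand, _, attrs = cols
            kv = dict(p.split("=", 1) for p in attrs.split(";") if "=" in p)
            fid = kv["ID"]
            if fid not in groups:
                groups[fid] = {"meta": kv, "strand": strand, "parts": []}
                order.append(fid)
            groups[fid]["parts"].append((int(s), int(e)))
    features = []
    for fid in order:
        ginfo = groups[fid]
        strand = ginfo["strand"]
        parts = ginfo["parts"]
        # rejoin wrap splits: a part ending at L followed by one starting at 1
        exons: list = []
        i = 0
        while i < len(parts):
            s, e = parts[i]
            if e == L and i + 1 < len(parts) and parts[i + 1][0] == 1:
                exons.append(Interval(s, parts[i + 1][1], strand))
                i += 2
            else:
                exons.append(Interval(s, e, strand))
                i += 1
        meta = ginfo["meta"]
        features.append(
            GeneFeature(
                meta["locus"],
                meta["category"],
                tuple(exons),
                meta.get("trans_block"),
                int(meta.get("copy_index", 1)),
            )
        )
    return AnnotatedGenome(genome, features, species=genome.id)


def write_bed(g: AnnotatedGenome, path) -> None:
    """0-based half-open exon intervals; wrap exons split at the origin."""
    L = g.genome.length
    with open(path, "w") as fh:
        for f in g.features:
            name = f.locus + (f".{f.trans_block}" if f.trans_block else "") + f".{f.copy_index}"
            for e in f.exons:
                pieces = [(e.start, L), (1, e.end)] if e.wraps else [(e.start, e.end)]
                for s, t in pieces:
                    fh.write(f"{g.genome.id}\t{s - 1}\t{t}\t{name}\t0\t{f.strand}\n")
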