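"""Published reference values for the upland cotton mitochondrial genome.

Worked-example inputs taken from the published annotation of the
*Gossypium hirsutum* mitochondrial genome (GenBank JX065074, 621,884 bp):
gene-cluster coordinates, the repeat landscape, the >100 bp repeat table
and the cross-species plastid-homolog summary. These are inputs for worked
examples and regression anchors, not outputs of this package.
"""

from __future__ import annotations

GENOME_LENGTH = 621_884
GC_PERCENT = 45.0

GENE_COUNTS = {"protein": 35, "rRNA": 4, "tRNA": 29}

# genic content, bp
PROTEIN_EXON_BP = 31_721
PROTEIN_INTRON_BP = 29_861
TRNA_BP = 2_234
RRNA_BP = 8_826

# Ten co-transcribed gene clusters: member names and the printed exon-block
# coordinates (start, end) in transcription order. The nad2abc-sdh3 pair's
# printed interval (999 bp) disagrees with its own coordinates (899 bp) and
# is therefore not used as a worked-number anchor.
GENE_CLUSTERS = [
    ("rpl16-rps3", [(593447, 593881), (593853, 597250)]),
    ("cob-rps14", [(547956, 549134), (550498, 550800)]),
    ("rpl2-rpl5-nad5c", [(532722, 533726), (534224, 534805), (535923, 535944)]),
    ("nad2abc-sdh3", [(418598, 420365), (421265, 421699)]),
    ("mttB-nad9", [(308702, 309502), (309687, 310259)]),
    ("sdh4-cox3", [(258268, 258666), (258594, 259391)]),
    ("cox1-rps10", [(260808, 262400), (262587, 263768)]),
    ("atp9-nad5ab", [(162829, 163140), (163361, 165659)]),
    ("nad3-rps12", [(129383, 129754), (129803, 130159)]),
    ("nad1e-matR-nad1d", [(81154, 81412), (82219, 84186), (84848, 84905)]),
]

# printed positive intergenic gaps, in the order they appear above
PRINTED_POSITIVE_GAPS = [1363, 497, 1117, 184, 186, 220, 806, 661, 48]

# repeat landscape (size class lower bound, count, total copy length bp)
REPEAT_SIZE_CLASSES = [
    (20, 192, 10_747),
    (40, 69, 9_667),
    (60, 35, 9_567),
    (80, 11, 8_365),
    (100, 32, 18_368),
    (1000, 4, 117_300),
]
REPEAT_COVERAGE_ROW = [1.7, 1.6, 1.5, 1.3, 3.0, 18.9]
REPEAT_UNION_COVERAGE = 22.9
REPEAT_COUNT = 343

# the four repeat families over 10 kb (id, alignment length, identity %)
LARGE_REPEATS = [
    ("R01", 27_495, 99.92, "DR"),
    ("R02", 10_623, 99.81, "IR"),
    ("R03", 10_302, 99.98, "IR"),
    ("R04", 10_251, 99.86, "DR"),
]

# chloroplast-derived sequence
MTPT_TOTAL_BP = 6_833
MTPT_COUNT = 27
MTPT_MIN_BP = 36
MTPT_MAX_BP = 2_185
MTPT_TRNA_COUNT = 12
MTPT_PHOTO_COUNT = 3
MTPT_CONSERVED_ALL = ["trnH", "trnM", "trnN", "trnP", "trnW"]

# cross-species plastid-homolog capacity (species, total bp, count, coverage %)
MTPT_SPECIES_TABLE = [
    ("Arabidopsis thaliana", 4803, 24, 1.3),
    ("Brassica napus", 8749, 23, 3.9),
    ("Carica papaya", 21368, 25, 4.5),
    ("Nicotiana tabacum", 11184, 37, 2.6),
    ("Cucurbita pepo", 88208, 204, 9.0),
    ("Gossypium hirsutum", 6833, 27, 1.1),
    ("Vigna radiata", 2109, 17, 0.5),
    ("Vitis vinifera", 64357, 73, 8.3),
    ("Ricinus communis", 5649, 26, 1.1),
    ("Silene latifolia", 1998, 16, 0.8),
    ("Sorghum bicolor", 26357, 45, 5.6),
    ("Triticum aestivum", 13855, 36, 3.1),
    ("Zea mays", 23445, 39, 4.1),
    ("Oryza sativa ssp indica", 33176, 41, 6.7),
    ("Oryza sativa ssp japonica", 33157, 41, 6.7),
]

# tRNA census across 25 plant mt genomes
NATIVE_TRNA_KINDS = 19
CP_LIKE_TRNA_KINDS = 19

# the 21 conserved respiratory-chain genes used for concatenated phylogeny
CONSERVED_GENES_21 = [
    "atp1", "atp4", "atp6", "atp8", "atp9",
    "cob", "cox1", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9",
    "ccmB", "ccmC", "ccmFC", "ccmFN",
]

# NCBI-taxonomy-shaped species tree for a compact eight-taxon panel used in
# the worked examples (gymnosperm outgroup, monocots, dicots)
EXAMPLE_SPECIES_TREE = (
    "((((Arabidopsis,Brassica),(Gossypium,Carica)),(Vitis,Nicotiana)),"
    "(Oryza,Zea));"
)
EXAMPLE_GROUPS = {
    "Arabidopsis": "dicot",
    "Brassica": "dicot",
    "Gossypium": "dicot",
    "Carica": "dicot",
    "Vitis": "dicot",
    "Nicotiana": "dicot",
    "Oryza": "monocot",
    "Zea": "monocot",
}
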