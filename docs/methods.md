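# Methods

This note documents the models, algorithms, defaults and design choices
behind `mitokit`, and what the synthetic-data tests do and do not show
about real data.

## Coordinates and the data model

All coordinates are 1-based inclusive, the convention of organelle
annotation tables; BED output converts to 0-based half-open and GFF3 stays
1-based, with both conversions round-trip tested. On a circular genome an
interval with `start > end` wraps through the origin and is stored as one
interval, never split into two features. A trans-spliced gene (nad1, nad2,
nad5) is one feature per cis-contiguous exon block; blocks share the locus
and carry a block label (`nad1bc`), which is also their unit in gene-order
analyses. Intron length is defined per cis block (block span minus exon
total); "introns" between trans-spliced blocks are undefined and never
counted.

Intergenic gaps are uniformly `start₂ − end₁ − 1` (modulo genome length on
wrap): touching genes give 0 and a k-bp coding overlap gives −k. Published
cluster tables sometimes print overlaps as `start₂ − end₁` instead; we keep
the single formula and accept a one-unit difference on overlapping pairs,
because one testable convention beats two contradictory ones.

Percentages are rounded half-away-from-zero to one decimal; this is the
rule under which the reference genome's printed 9.9%, 1.1% and 18.9%
recompute exactly from their integer numerators.

## Local homology search

One engine (`mitokit.homology`) backs repeat detection, plastid-transfer
scanning and shared-sequence totals:

1. **Seeds.** Exact k-mer matches between query and subject, both strands,
   computed with integer-coded rolling k-mers (k ≤ 25); k-mers occurring
   more than 64 times in the subject are skipped.
2. **Chains.** Seeds sharing a diagonal chain when their query gap is at
   most `max_gap`; chains on diagonals within `band` of one another merge
   (indel tolerance). A chain must carry `min_seeds` seeds or already span
   `min_len`.
3. **Extension.** Ungapped X-drop extension (match +2, mismatch −3,
   drop 40) on both ends.
4. **Verification and trimming.** The candidate is globally aligned with
   edlib; the reported segment is the maximal-scoring window along the
   alignment path (match +1, mismatch −2, gap −3), which keeps boundaries
   within a few bp of a planted segment's edges. If that window is shorter
   than `min_len` (possible when substitutions cluster), the candidate is
   re-examined — on its own diagonal when ungapped, so flank noise cannot
   bend the alignment path — for the longest window of ≥ `min_len` columns
   meeting the identity floor. Identity is always matches over alignment
   columns, so a family's alignment length can exceed its coordinate span
   when indels are present.

**Sensitivity floor.** An exact seed of any useful length can be destroyed
by the divergence it is supposed to tolerate: a 36 bp segment with 7
substitutions often contains no clean 7-mer. Where recovery of *every*
segment above the floor matters (the plastid scan), a vectorised mismatch
sweep complements the seed pass: every step-aligned 24 bp subject window is
compared against the query at every offset by batched diagonal correlation,
and windows within 8 mismatches become candidates. A covering argument
shows any substitution-only match of ≥30 bp at ≥80% identity yields at
least one such window, so the sweep cannot miss such a segment. Its cost is
O(|q|·|s|), appropriate for organelle-scale inputs; the CLI exposes
`--fast` to skip it.

**Reported extents at the identity floor.** A segment planted at exactly
80% identity with mutated ends is reported as its best-scoring core, which
can cover as little as ~70% of the planted extent; for segments at ≤10%
divergence boundaries land within ±5 bp. The test suite therefore asserts
majority (≥50%) coverage for recovery and tight boundaries only below 10%
divergence.

## Repeats

`find_repeats` scans the doubled circular sequence on both strands
(min_len 20, min_identity 80, seed k 15 by default), removes the
self-diagonal, circular images and mirror duplicates, splits palindromic
self-overlapping reverse hits at their anti-diagonal centre (an abutting
inverted pair otherwise reads as one self-match), and clusters copies into
families by single linkage (copies are merged when they overlap by half the
shorter copy). Family identity is the minimum pairwise identity among
copies; alignment length is the maximum; families are numbered R01… by
decreasing length, ties by first start. The 80% default floor bounds the
published landscape, whose lowest printed family identity is 83.2%.

The landscape uses closed-open size classes [20,40) … [100,1000), [1000,∞):
published prose about what counts as "larger than 100 bp" is ambiguous at
the class edges, and closed-open intervals are the one self-consistent
choice. Per class we report family count, summed copy length and its
percent of the genome; union coverage merges all copy intervals first and
is therefore at most the class-total sum (22.9% vs 28.0% for the reference
genome).

## Plastid-derived sequence

`scan_plastid_homologs` runs the seed pass (word size 7 — the word length
short-sequence BLAST tasks use; an 11-mer seed cannot guarantee the
smallest reported segments at the identity floor) plus the mismatch sweep,
merges overlapping mt intervals keeping the best-identity supporting
alignment, and merges circularly overlapping results once more so a
wrap-origin segment is reported exactly once. Classification looks at the
chloroplast source interval: overlap with a cp tRNA gene wins, then
photosynthesis genes by name class (psa*/psb*/pet*/ndh*/rbcL), else other.
Coverage summaries use merged, non-redundant mt intervals. At a 30 bp /
80% floor, random organelle-scale sequence yields occasional chance
segments just above threshold — the same behaviour as a BLAST scan at
these settings, and the reason published minimum segments sit a little
above the floor.

## tRNA origins and gain/loss

A tRNA is cp-like when its sequence aligns to a chloroplast tRNA of the
same isotype at ≥85% identity with ≥90% length coverage (both floors are
configuration keys; the boundary is inclusive). Native and cp-like
variants of one isoacceptor are distinct characters — a species can carry
both — so cp-like characters are suffixed `(cp)` in the distribution grid.

Gain/loss placement on a fixed species tree (the tree is an input, never
estimated): cp-like characters follow Dollo parsimony — one gain on the
branch above the MRCA of the present tips, losses on the maximal subtrees
within that clade lacking the character; native characters follow loss-only
parsimony from a primitively present root. Both placements are exact
minima for their models (verified against exhaustive enumeration) and are
replayed down the tree to confirm they reproduce the tip grid.

## Gene order and synteny

Gene orders cover protein and rRNA features only, sorted by circular start;
duplicate copies contribute one entry each under the shared label. An
adjacency is an unordered label pair plus relative orientation (same /
opposite), which is invariant under reading direction. Matching is
orientation-aware by default (co-transcribed clusters are strand-coherent);
each distinct label pair counts at most once regardless of copy
multiplicity, so multicopy loci do not inflate counts. `pair` mode counts
conserved adjacencies (two linked genes = one cluster); `run` mode counts
maximal chains of ≥2 genes. Strict adjacency is required — no gap
tolerance — and a label absent from either genome simply never matches.

Cluster presence uses `+` (members consecutive, in either circular
direction, orientations conserved — all-same-strand when no reference
pattern is given), `−` (broken), `#` (a member gene is missing entirely;
`#` takes precedence over `−`). In conserved-cluster enumeration a genome
missing one of the pair's genes is non-informative rather than a veto.

## Shared sequence

Masking removes cp-derived intervals and every copy but the
lowest-coordinate one of each repeat family with alignment length ≥1,000 bp
(the cutoff matches the top landscape class; a configuration key). Kept and
removed intervals partition the genome exactly. Shared length is
query-based: kept query segments are searched (≥50 bp at ≥70% identity,
word size 9) against the subject's kept sequence (segments joined by N
spacers longer than any seed), and merged matched query intervals are
summed. Both directions of the matrix are reported; they differ slightly
because merging is query-based, and the diagonal is the masked length.

## Distance phylogeny

Per-locus alignments are inputs (no aligner is bundled). Concatenation is
head-to-tail in the declared gene-set order with an exact partition record;
the gene sets are the 21 conserved respiratory-chain genes and the
functional subsets (complex I, III, IV, V, cytochrome c biogenesis).
p-distance uses pairwise deletion of gap/N columns. Neighbor joining is the
standard Q-criterion agglomeration with deterministic tie-breaking by
species name and negative branch lengths clamped to zero with the deficit
moved to the sister branch; on additive matrices it reproduces the
generating tree exactly, topology and branch lengths. Robinson–Foulds
distances compare unrooted bipartition sets. Maximum-likelihood inference
is deliberately out of scope.

## Synthetic data

The generator emulates a plant mt genome's composition, not its history:
i.i.d. background at GC 0.45 (no Markov structure — enough to exercise
identity thresholds, but real mtDNA has local composition structure);
genes, repeat copies, plastid insertions and tRNAs placed without
unplanned overlap by a gap-tracking allocator (blocks sit against gap edges
so free space stays contiguous; genes get a randomised 1.6–2.6 kb berth so
distinct clusters never read as one; repeat copies a 100–250 bp berth so a
family is never planted as a tandem array; a 2 kb origin buffer keeps the
two linear ends from becoming circular neighbours). Divergence is applied
as exactly `floor(rate·length)` substitutions at distinct positions, so
planted identity never undershoots its nominal value by sampling noise.

Defaults mirror the reference-genome conditions: 620 kb at GC 0.45; 68
genes (35 protein loci with three trans-spliced, four rRNA features with a
duplicated rrn26, 29 tRNAs of which 7 are cp-like copies); ten
co-transcribed clusters with the published intergenic spacings; a repeat
plan with four families over 10 kb (27,495 / 10,623 / 10,302 / 10,251 bp)
and per-class counts and copy-number mixes shaped to the published
landscape totals; 27 plastid insertions totalling 6,833 bp (36–2,185 bp;
12 tRNA-related, 3 photosynthesis) at divergences drawn up to 18%.
`SimConfig.small()` is a 75 kb scaled version for exercises and tests.

Related pairs rearrange gene-anchored arcs (inversions reverse-complement
a block of 2…n−2 order units; transpositions move a block), never cutting
genes, and record the surviving adjacency set by direct enumeration.
Species panels evolve the root genome down a tree with exact-count
substitutions, scripted cp-like tRNA gains, tRNA losses (feature removed,
sequence randomised), in-place block inversions — and, optionally,
**intergenic sequence turnover**: a fraction of the feature-free genome per
unit branch length is replaced by fresh random sequence in 200–600 bp
chunks. Turnover is what separates real plant mt genomes; with point
substitutions alone, shared-sequence totals are a cliff function of
distance (saturated below ~25% divergence, zero above ~30% at the 70%
floor) and carry almost no rank information, whereas under turnover the
expected shared total decays smoothly with distance. The rank-concordance
panels use a quartet whose six pairwise distances are distinct and
separated by ≥0.4 units at turnover 0.12 per unit, so expected share
differences exceed sampling noise by a wide margin.

What passing these tests shows: the detectors recover what was planted
under the stated noise models, and the combinatorial stages agree with
exhaustive oracles. What they do not show: performance on real data's
compositional biases, tandem and nested repeat structure, RNA editing, or
annotation error; and the turnover model is a caricature of real
intergenic evolution (no duplications, no horizontal acquisitions).

## Problem sizes in the test and acceptance runs

Oracle suites run at sizes chosen to keep the default suite fast while
leaving the mechanisms untouched: repeat recall over 40 seeds × 4 planted
families per genome (16 kb genomes) at divergence 0 and 2%; plastid recall
over 8 panels of 6 inserts each, including 30–36 bp inserts at 19–20%
divergence; 150–500 random 6-taxon parsimony grids against exhaustive
minima (the acceptance script runs 300); 100 random additive matrices for
NJ; 200 random circular permutation pairs (n ≤ 12) plus every single-block
inversion for synteny. All rates measured at these sizes are 100%, and
none of the algorithms has a size-dependent branch that these scales would
miss.

## Known limitations

- Indel-mode divergence is supported in alignment and verification but the
  generator's default divergence is substitution-only; the mismatch-sweep
  recovery guarantee is proved only for substitution-only segments.
- The mismatch sweep is quadratic and intended for organelle-scale inputs;
  chromosome-scale scans should use the seed pass alone.
- Counts of plastid segments are parameter-sensitive (merge policy, floors)
  — totals and coverages are the stable quantities.
- Shared-matrix asymmetry (query-based merging) is reported, not hidden;
  published shared-sequence tables rarely state their symmetrisation.
- The NJ implementation is O(n⁴) in the worst case with the deterministic
  tie-break scan; fine for dozens of taxa, not thousands.
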