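"""Repeat detection and the size-class landscape.

Self-compares a generated genome, clusters repeat copies into families,
classifies each as direct (DR), inverted (IR) or mixed (IR/DR), and prints
the frequency distribution of repeat lengths — the classic repeat summary
for a plant mt genome, where large repeats mediate recombination.
"""

from mitokit import find_repeats, tabulate_landscape
from mitokit.simulate import SimConfig, generate_mt_genome

mt, _cp, truth = generate_mt_genome(SimConfig.small(seed=5))
families = find_repeats(mt)  # >=20 bp at >=80% identity

print(f"{len(families)} repeat families (planted: {len(truth.repeats)})")
for f in families:
    copies = ", ".join(
        f"{c.interval.start}-{c.interval.end}({c.orientation[0]})"
        for c in f.copies
    )
    print(f"  {f.family_id}: {f.rep_length} bp @ {f.identity:.1f}% {f.type}  [{copies}]")

scape = tabulate_landscape(families, mt.genome.length)
print("\nsize class   count  total bp  coverage%")
for row in scape.rows:
    print(f"  {row.label:>8}  {row.count:5d}  {row.total_bp:8d}  {row.coverage_pct:8.1f}")
print(f"union coverage {scape.union_coverage_pct}% "
      "(less than the class sum because copies overlap)")
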