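"""Plain-TSV renderers mirroring the conventional published table layouts
of comparative plant-mtDNA studies: gene-cluster locations, repeat tables,
repeat-length frequency distributions, plastid-homolog capacity, syntenic
cluster-count matrices, cluster presence grids and shared-sequence
matrices."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

__all__ = ["render_tables"]


def _table1(clusters: Sequence[dict]) -> str:
    """Gene clusters with 'Location and Interval' strings."""
    lines = ["Gene cluster\tLocation and Interval\tStrand"]
    for c in clusters:
        parts = []
        for i, span in enumerate(c["spans"]):
            parts.append(f"{span.start}..{span.end}")
            if i < len(c["gaps"]):
                parts.append(f"-({c['gaps'][i]}bp)-")
        lines.append(f"{'-'.join(c['labels'])}\t{''.join(parts)}\t{c['strand']}")
    return "\n".join(lines) + "\n"


def _table2(families) -> str:
    """Repeat families: size, identity, per-copy coordinates, DR/IR type.

    Reverse-orientation copies print end before start, the conventional
    marker for an inverted copy.
    """
    max_copies = max((f.copy_count for f in families), default=2)
    head = ["No.", "Size (bp)", "Identity (%)"]
    for i in range(max_copies):
        head += [f"Copy-{i + 1} start", f"Copy-{i + 1} end"]
    head.append("Type")
    lines = ["\t".join(head)]
    for f in families:
        row = [f.family_id, str(f.rep_length), f"{f.identity:.2f}"]
        for i in range(max_copies):
            if i < f.copy_count:
                c = f.copies[i]
                s, e = c.interval.start, c.interval.end
                if c.orientation == "reverse":
                    s, e = e, s
                row += [str(s), str(e)]
            else:
                row += ["", ""]
        row.append(f.type)
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def _table3(landscape) -> str:
    rows = landscape.rows
    lines = [
        "Size, bp\t" + "\t".join(r.label for r in rows),
        "Number\t" + "\t".join(str(r.count) for r in rows),
        "Total length of repeats, bp\t" + "\t".join(str(r.total_bp) for r in rows),
        "Coverage, %\t" + "\t".join(f"{r.coverage_pct:.1f}" for r in rows),
        f"Union coverage, %\t{landscape.union_coverage_pct:.1f}",
    ]
    return "\n".join(lines) + "\n"


def _table4(summaries) -> str:
    lines = [
        "Species\tTotal length of chloroplast homologous sequence in mt genome"
        "\tNumbers of chloroplast homologs\tCoverage of chloroplast homologous sequence"
    ]
    for s in summaries:
        lines.append(f"{s.species}\t{s.total_bp}\t{s.count}\t{s.coverage_pct:.1f}%")
    return "\n".join(lines) + "\n"


def _matrix_lower(mat: pd.DataFrame) -> str:
    """Lower-triangular species matrix (diagonal and above blank)."""
    names = list(mat.index)
    lines = ["Species\t" + "\t".join(names[:-1])]
    for i, sp in enumerate(names):
        if i == 0:
            continue
        cells = [str(int(mat.iloc[i, j])) for j in range(i)]
        lines.append(sp + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def _grid(mat: pd.DataFrame) -> str:
    lines = ["\t" + "\t".join(map(str, mat.columns))]
    for sp, row in mat.iterrows():
        lines.append(str(sp) + "\t" + "\t".join(map(str, row)))
    return "\n".join(lines) + "\n"


_RENDERERS = {
    "table1": _table1,
    "table2": _table2,
    "table3": _table3,
    "table4": _table4,
    "table5": _matrix_lower,
    "table6": _grid,
    "tableS3": _grid,
}


def render_tables(results, layout: str) -> str:
    """Render stage results as TSV text in the named published layout.

    layouts: table1 gene clusters, table2 repeats >threshold, table3 repeat
    size classes, table4 plastid-homolog capacity, table5 syntenic cluster
    counts (lower triangular), table6 presence grid (+/−/#), tableS3 shared
    sequence matrix.
    """
    if layout not in _RENDERERS:
        raise ValueError(f"unknown layout {layout!r}")
    try:
        return _RENDERERS[layout](results)
    except (AttributeError, KeyError, TypeError) as exc:
        raise ValueError(
            f"results object does not fit layout {layout!r}: {exc}"
        ) from exc
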