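"""CSV and HTML reports for an inference result.

Peptide marker convention: a unique peptide is listed plainly, ``*`` is
appended to discriminating peptides and ``**`` to non-discriminating
peptides.

Both writers are deterministic: the same result produces byte-identical
output (no timestamps unless explicitly requested), so reports can be
diffed across reruns.
"""

from __future__ import annotations

import csv
import html
import logging
from pathlib import Path

from .model import (
    ClassificationResult,
    PeptideCategory,
    ProteinCategory,
)

logger = logging.getLogger("protinfer")

__all__ = ["peptide_marker", "write_csv", "write_html"]

_MARKERS = {
    PeptideCategory.UNIQUE: "",
    PeptideCategory.DISCRIMINATING: "*",
    PeptideCategory.NON_DISCRIMINATING: "**",
}

_STATS_ORDER = (
    ProteinCategory.CONCLUSIVE,
    ProteinCategory.INDISTINGUISHABLE,
    ProteinCategory.AMBIGUOUS_GROUP,
    ProteinCategory.NON_CONCLUSIVE,
    ProteinCategory.FILTERED,
)


def peptide_marker(category: PeptideCategory) -> str:
    """Report suffix for a peptide: '' unique, '*' discriminating, '**' non-discriminating."""
    return _MARKERS[category]


def _marked(result: ClassificationResult, seq: str) -> str:
    return seq + peptide_marker(result.graph.peptides[seq].category)


def _stats_cell(result: ClassificationResult, cat: ProteinCategory) -> str:
    """Protein count, with group count in parentheses for multi-member categories."""
    n, k = result.stats[cat]
    if cat in (ProteinCategory.INDISTINGUISHABLE, ProteinCategory.AMBIGUOUS_GROUP):
        return f"{n} ({k})"
    return str(n)


CSV_HEADER = [
    "group_id",
    "category",
    "accession",
    "description",
    "peptides",
    "runs_presence",
    "n_unique",
    "n_discriminating",
    "n_non_discriminating",
]


def write_csv(result: ClassificationResult, path: str | Path) -> None:
    """Write one CSV row per (group, member protein), plus a stats block.

    Columns: group id, category label, accession, description, the
    protein's peptides with evidence markers (semicolon-separated), the
    number of its peptides observed in each run ("2/3/3" for three runs),
    and the per-category peptide counts.  Category statistics follow as
    ``#``-prefixed comment lines.  RFC 4180 quoting, UTF-8.
    """
    path = Path(path)
    graph = result.graph
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\r\n")
        writer.writerow(CSV_HEADER)
        for group in result.groups:
            for acc in group.members:
                prot = graph.proteins[acc]
                seqs = sorted(prot.peptides)
                cats = [graph.peptides[s].category for s in seqs]
                presence = "/".join(
                    str(
                        sum(
                            1
                            for s in seqs
                            if run in graph.peptides[s].runs
                        )
                    )
                    for run in range(1, result.n_runs + 1)
                )
                writer.writerow(
                    [
                        group.group_id,
                        group.category.label,
                        acc,
                        prot.description,
                        ";".join(_marked(result, s) for s in seqs),
                        presence,
                        sum(c is PeptideCategory.UNIQUE for c in cats),
                        sum(c is PeptideCategory.DISCRIMINATING for c in cats),
                        sum(c is PeptideCategory.NON_DISCRIMINATING for c in cats),
                    ]
                )
        handle.write("# stats\r\n")
        handle.write("# category,proteins,groups\r\n")
        for cat in _STATS_ORDER:
            n, k = result.stats[cat]
            handle.write(f"# {cat.label},{n},{k}\r\n")
    logger.info("%s: wrote CSV report (%d groups)", path, len(result.groups))


def write_html(result: ClassificationResult, path: str | Path) -> None:
    """Write a self-contained HTML report.

    Three sections linked by intra-page anchors: analysis configuration and
    category statistics; a summary list of groups and their proteins (each
    linking to its details); and per-protein details with peptides, their
    evidence markers, run occupancy and modification variants.
    """
    path = Path(path)
    graph = result.graph
    e = html.escape
    parts: list[str] = []
    parts.append(
        "<!DOCTYPE html>\n<html lang=\"en\">\n<head>\n<meta charset=\"utf-8\">\n"
        "<title>Protein inference report</title>\n"
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:"
        "collapse}td,th{border:1px solid #999;padding:0.3em 0.6em}"
        "h2{margin-top:1.5em}</style>\n</head>\n<body>\n"
        "<h1>Protein inference report</h1>\n"
    )

    # Section 1: configuration and stats.
    parts.append('<section id="config">\n<h2>Configuration and statistics</h2>\n')
    parts.append(f"<p>Replicate runs analysed: {result.n_runs}</p>\n")
    parts.append("<table>\n<tr><th>Category</th><th>Proteins (groups)</th></tr>\n")
    for cat in _STATS_ORDER:
        parts.append(
            f"<tr><td>{e(cat.label)}</td><td>{e(_stats_cell(result, cat))}</td></tr>\n"
        )
    parts.append(
        f"<tr><td>total</td><td>{result.protein_count()}</td></tr>\n</table>\n"
        "</section>\n"
    )

    # Section 2: group summary.
    parts.append('<section id="summary">\n<h2>Protein groups</h2>\n')
    parts.append(
        "<table>\n<tr><th>Group</th><th>Category</th><th>Proteins</th>"
        "<th>Peptides</th></tr>\n"
    )
    for group in result.groups:
        links = ", ".join(
            f'<a href="#prot-{e(acc)}">{e(acc)}</a>' for acc in group.members
        )
        peps = "; ".join(
            e(_marked(result, s)) for s in sorted(group.peptide_annotations)
        )
        parts.append(
            f"<tr><td>{group.group_id}</td><td>{e(group.category.label)}</td>"
            f"<td>{links}</td><td>{peps}</td></tr>\n"
        )
    parts.append("</table>\n</section>\n")

    # Section 3: per-protein details.
    parts.append('<section id="details">\n<h2>Protein details</h2>\n')
    for group in result.groups:
        for acc in group.members:
            prot = graph.proteins[acc]
            parts.append(
                f'<h3 id="prot-{e(acc)}">{e(acc)} '
                f"({e(group.category.label)}, group {group.group_id})</h3>\n"
            )
            if prot.description:
                parts.append(f"<p>{e(prot.description)}</p>\n")
            parts.append(
                "<table>\n<tr><th>Peptide</th><th>Runs</th><th>Variants</th></tr>\n"
            )
            for seq in sorted(prot.peptides):
                pep = graph.peptides[seq]
                runs = "runs: " + ",".join(str(r) for r in sorted(pep.runs))
                var_texts = []
                for variant in pep.variants:
                    if variant:
                        var_texts.append(
                            "; ".join(f"{name}@{pos}" for pos, name in variant)
                        )
                    else:
                        var_texts.append("no PTMs")
                parts.append(
                    f"<tr><td>{e(_marked(result, seq))}</td><td>{e(runs)}</td>"
                    f"<td>{e(' | '.join(var_texts))}</td></tr>\n"
                )
            parts.append("</table>\n")
    if result.filtered_accessions:
        parts.append("<h3>Filtered proteins</h3>\n<p>")
        parts.append(
            ", ".join(e(a) for a in sorted(result.filtered_accessions))
        )
        parts.append("</p>\n")
    parts.append("</section>\n</body>\n</html>\n")

    path.write_text("".join(parts), encoding="utf-8")
    logger.info("%s: wrote HTML report (%d groups)", path, len(result.groups))
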