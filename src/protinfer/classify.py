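"""Peptide and protein classification.

The classifier assigns every peptide one of three evidence types (unique /
discriminating / non-discriminating) and then partitions proteins into
evidence groups:

* **conclusive** — has at least one unique peptide;
* **non-conclusive** — all of its peptides are non-discriminating;
* **indistinguishable** — a group of proteins with identical peptide sets,
  including at least one discriminating peptide;
* **ambiguous group** — a connected set of proteins jointly explaining a
  set of discriminating peptides.

The procedure runs in three steps:

1. Mark every peptide discriminating; peptides mapping to a single protein
   become *unique*; proteins holding a unique peptide become *conclusive*;
   non-unique peptides whose protein set contains a conclusive protein
   become *non-discriminating*.
2. Iterate over the peptides still marked discriminating, in canonical
   (lexicographic) order.  The current peptide's protein set is a temporary
   group; any other still-discriminating peptide shared by all proteins of
   that group *and* by proteins outside it (i.e. whose protein set is a
   strict superset) is re-marked non-discriminating.  Repeat until the last
   discriminating peptide has served as a seed.
3. Proteins with only non-discriminating peptides become non-conclusive;
   the remaining proteins are merged into groups as connected components of
   "co-occur in some discriminating peptide's protein set"; a component
   whose members all carry exactly the same peptides is indistinguishable,
   otherwise it is an ambiguous group.

:func:`oracle_classify` is an independent closed-form re-statement of the
peptide step used for testing: a shared peptide is non-discriminating iff
some other peptide's protein set is a strict subset of its own.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .model import (
    ClassificationResult,
    ConsistencyError,
    EvidenceGraph,
    PeptideCategory,
    PeptideRecord,
    ProteinCategory,
    ProteinGroup,
    ValidationError,
    build_graph,
)

logger = logging.getLogger("protinfer")

__all__ = [
    "classify_peptides",
    "classify_proteins",
    "classify",
    "infer",
    "oracle_classify",
]


def classify_peptides(graph: EvidenceGraph) -> EvidenceGraph:
    """Assign a :class:`PeptideCategory` to every peptide in ``graph``.

    Mutates and returns ``graph``.  Steps 1 and 2 of the classification
    procedure (see module docstring).
    """
    if not graph.peptides:
        raise ValidationError("cannot classify an empty evidence graph")

    # Step 1: initial marking.
    for pep in graph.peptides.values():
        pep.category = PeptideCategory.DISCRIMINATING
    for prot in graph.proteins.values():
        prot.category = None

    conclusive: set[str] = set()
    for pep in graph.peptides.values():
        if len(pep.proteins) == 1:
            pep.category = PeptideCategory.UNIQUE
            conclusive.update(pep.proteins)
    for acc in conclusive:
        graph.proteins[acc].category = ProteinCategory.CONCLUSIVE
    for pep in graph.peptides.values():
        if pep.category is PeptideCategory.DISCRIMINATING and pep.proteins & conclusive:
            pep.category = PeptideCategory.NON_DISCRIMINATING

    # Step 2: iterative refinement.  Each still-discriminating peptide in
    # turn seeds a temporary group; any other still-discriminating peptide
    # whose protein set strictly contains the group is demoted.  A demoted
    # peptide never needs to seed: its strict superset relation is implied
    # by the peptide that demoted it.
    ordered = sorted(graph.peptides)
    for seed_seq in ordered:
        seed = graph.peptides[seed_seq]
        if seed.category is not PeptideCategory.DISCRIMINATING:
            continue
        group = seed.proteins
        for other_seq in ordered:
            other = graph.peptides[other_seq]
            if other is seed or other.category is not PeptideCategory.DISCRIMINATING:
                continue
            if other.proteins > group:
                other.category = PeptideCategory.NON_DISCRIMINATING

    for seq, pep in graph.peptides.items():
        if pep.category is None:  # pragma: no cover - unreachable by construction
            raise ConsistencyError(f"peptide {seq!r} left unclassified")
    return graph


def _union_find_components(
    nodes: Iterable[str], edges: Iterable[frozenset[str]]
) -> list[list[str]]:
    """Connected components over ``nodes``; each edge set is a clique."""
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for clique in edges:
        members = sorted(clique)
        for other in members[1:]:
            ra, rb = find(members[0]), find(other)
            if ra != rb:
                parent[rb] = ra

    comps: dict[str, list[str]] = {}
    for n in parent:
        comps.setdefault(find(n), []).append(n)
    return [sorted(c) for c in comps.values()]


def classify_proteins(
    graph: EvidenceGraph, filtered_accessions: Iterable[str] = ()
) -> ClassificationResult:
    """Partition the proteins of a peptide-classified graph into groups.

    Step 3 of the classification procedure.  ``filtered_accessions`` are
    proteins that lost every peptide to upstream filtering; they are carried
    into the result's ``filtered`` bucket and never grouped.
    """
    filtered = frozenset(filtered_accessions)
    if any(p.category is None for p in graph.peptides.values()):
        raise ValidationError("classify_peptides must run before classify_proteins")

    for acc, prot in graph.proteins.items():
        if prot.category is ProteinCategory.CONCLUSIVE:
            continue
        cats = {graph.peptides[s].category for s in prot.peptides}
        if cats == {PeptideCategory.NON_DISCRIMINATING}:
            prot.category = ProteinCategory.NON_CONCLUSIVE
        # else: carries >= 1 discriminating peptide -> grouped below.

    ungrouped = [
        acc for acc, prot in graph.proteins.items() if prot.category is None
    ]
    disc_sets = [
        frozenset(pep.proteins)
        for pep in graph.peptides.values()
        if pep.category is PeptideCategory.DISCRIMINATING
    ]
    for s in disc_sets:
        stray = s - set(ungrouped)
        if stray:  # pragma: no cover - provably impossible
            raise ConsistencyError(
                f"discriminating peptide maps to categorised protein(s) {sorted(stray)}"
            )
    components = _union_find_components(ungrouped, disc_sets)

    groups: list[tuple[ProteinCategory, list[str]]] = []
    for comp in components:
        peptide_sets = {frozenset(graph.proteins[a].peptides) for a in comp}
        if len(comp) >= 2 and len(peptide_sets) == 1:
            cat = ProteinCategory.INDISTINGUISHABLE
        else:
            cat = ProteinCategory.AMBIGUOUS_GROUP
        if len(comp) < 2:  # pragma: no cover - needs a discriminating singleton
            raise ConsistencyError(
                f"grouped component {comp} has a single member; a lone protein "
                "cannot hold a discriminating peptide"
            )
        for acc in comp:
            graph.proteins[acc].category = cat
        groups.append((cat, comp))

    for acc, prot in graph.proteins.items():
        if prot.category is None:  # pragma: no cover - unreachable
            raise ConsistencyError(f"protein {acc!r} left unclassified")

    for acc, prot in graph.proteins.items():
        if prot.category in (
            ProteinCategory.CONCLUSIVE,
            ProteinCategory.NON_CONCLUSIVE,
        ):
            groups.append((prot.category, [acc]))

    # Canonical numbering: by lexicographically smallest member accession.
    groups.sort(key=lambda item: item[1][0])
    out: list[ProteinGroup] = []
    for gid, (cat, members) in enumerate(groups, start=1):
        annotations = {
            seq: graph.peptides[seq].category
            for acc in members
            for seq in graph.proteins[acc].peptides
        }
        out.append(
            ProteinGroup(
                group_id=gid,
                category=cat,
                members=tuple(members),
                peptide_annotations=annotations,
            )
        )

    stats = _compute_stats(out, filtered)
    n_grouped = sum(len(g.members) for g in out)
    if n_grouped != len(graph.proteins):  # pragma: no cover - unreachable
        raise ConsistencyError(
            f"partition broken: {n_grouped} grouped of {len(graph.proteins)} proteins"
        )
    logger.info(
        "classified %d proteins into %d groups (%d filtered)",
        len(graph.proteins),
        len(out),
        len(filtered),
    )
    return ClassificationResult(
        groups=out, stats=stats, filtered_accessions=filtered, graph=graph
    )


def _compute_stats(
    groups: Sequence[ProteinGroup], filtered: frozenset[str]
) -> dict[ProteinCategory, tuple[int, int]]:
    stats = {cat: (0, 0) for cat in ProteinCategory}
    for g in groups:
        n, k = stats[g.category]
        stats[g.category] = (n + len(g.members), k + 1)
    stats[ProteinCategory.FILTERED] = (len(filtered), 0)
    return stats


def classify(
    graph: EvidenceGraph, filtered_accessions: Iterable[str] = ()
) -> ClassificationResult:
    """Run the full classification (peptides then proteins) on ``graph``."""
    classify_peptides(graph)
    return classify_proteins(graph, filtered_accessions)


def infer(
    records: Sequence[PeptideRecord],
    n_runs: int | None = None,
    runs_threshold: int = 1,
    prefiltered_accessions: Iterable[str] = (),
) -> ClassificationResult:
    """End-to-end inference from raw records.

    Applies the replicate-runs filter at ``runs_threshold``, builds the
    evidence graph and classifies it.  ``prefiltered_accessions`` lets
    callers merge in proteins already removed by an upstream (score) filter.
    When every peptide is filtered out the result has no groups and every
    accession sits in the filtered bucket.
    """
    from .replicates import filter_by_runs  # local import, avoids cycle

    if not records and n_runs is None:
        raise ValidationError("no identifications: the record list is empty")
    if n_runs is None:
        n_runs = max(r.run_index for r in records)
    kept, run_filtered = filter_by_runs(records, runs_threshold)
    filtered = frozenset(run_filtered) | frozenset(prefiltered_accessions)
    if not kept:
        empty = EvidenceGraph(peptides={}, proteins={}, n_runs=n_runs)
        return ClassificationResult(
            groups=[],
            stats=_compute_stats([], filtered),
            filtered_accessions=filtered,
            graph=empty,
        )
    graph = build_graph(kept, n_runs=n_runs)
    return classify(graph, filtered)


# --------------------------------------------------------------------------
# Independent oracle (testing aid)
# --------------------------------------------------------------------------


def oracle_classify(graph: EvidenceGraph) -> dict[str, PeptideCategory]:
    """Closed-form peptide classification by exhaustive subset comparison.

    A peptide is *unique* iff it maps to one protein; otherwise it is
    *non-discriminating* iff some other peptide's protein set is a strict
    subset of its own, and *discriminating* otherwise.  No iteration state;
    deliberately independent of :func:`classify_peptides`.
    """
    out: dict[str, PeptideCategory] = {}
    items = list(graph.peptides.items())
    for seq, pep in items:
        if len(pep.proteins) == 1:
            out[seq] = PeptideCategory.UNIQUE
            continue
        dominated = any(
            other.proteins < pep.proteins for oseq, other in items if oseq != seq
        )
        out[seq] = (
            PeptideCategory.NON_DISCRIMINATING
            if dominated
            else PeptideCategory.DISCRIMINATING
        )
    return out
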