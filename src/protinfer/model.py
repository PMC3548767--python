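"""Domain model for peptide-evidence protein inference.

Shotgun proteomics identifies peptides, not proteins; shared (degenerate)
peptides make the step from peptides to proteins ambiguous.  This module
defines the in-memory types for that problem — peptide assignment records as
read from identification files, the deduplicated bipartite peptide<->protein
evidence graph, the peptide and protein evidence categories, and the grouped
classification result — plus :func:`build_graph`, which turns raw records
into a canonical graph.

Peptide identity is the amino-acid sequence alone: records with the same
sequence are merged, their protein sets and run sets unioned, and their
modification states kept as *variants* of a single peptide.  Leucine and
isoleucine are not equated; sequences compare byte-wise.  Accessions are
opaque identifiers.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("protinfer")

# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class ProtInferError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ProtInferError):
    """Invalid input data or parameters."""


class ParseError(ProtInferError):
    """A file could not be parsed (malformed XML, dangling references...)."""


class UnsupportedVersionError(ParseError):
    """An input document uses a format version this package does not read."""


class UnsupportedOperationError(ProtInferError):
    """A requested operation is not applicable to the given inputs."""


class ConsistencyError(ProtInferError):
    """An internal invariant was violated; indicates a bug, not bad input."""


# --------------------------------------------------------------------------
# Categories
# --------------------------------------------------------------------------


class PeptideCategory(enum.Enum):
    """Evidence type of an identified peptide.

    * ``UNIQUE`` — maps to exactly one protein.
    * ``DISCRIMINATING`` — shared, but required to explain the data: its
      protein set is not a strict superset of any other peptide's set.
    * ``NON_DISCRIMINATING`` — shared and already explained by proteins that
      carry unique or discriminating peptides.
    """

    UNIQUE = "unique"
    DISCRIMINATING = "discriminating"
    NON_DISCRIMINATING = "non_discriminating"


class ProteinCategory(enum.Enum):
    """Evidence category of an inferred protein (or protein group member).

    ``FILTERED`` is reserved for proteins whose every peptide was removed by
    score/replicate filtering; such proteins are reported, never silently
    dropped.
    """

    CONCLUSIVE = "conclusive"
    NON_CONCLUSIVE = "non_conclusive"
    INDISTINGUISHABLE = "indistinguishable"
    AMBIGUOUS_GROUP = "ambiguous_group"
    FILTERED = "filtered"

    @property
    def label(self) -> str:
        """Human-readable label, as written to reports and mzIdentML."""
        return _CATEGORY_LABELS[self]


_CATEGORY_LABELS = {
    ProteinCategory.CONCLUSIVE: "conclusive",
    ProteinCategory.NON_CONCLUSIVE: "non-conclusive",
    ProteinCategory.INDISTINGUISHABLE: "indistinguishable",
    ProteinCategory.AMBIGUOUS_GROUP: "ambiguous group",
    ProteinCategory.FILTERED: "filtered",
}

#: One modification variant: tuple of (1-based position, modification name).
ModVariant = tuple[tuple[int, str], ...]


# --------------------------------------------------------------------------
# Records and graph nodes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PeptideRecord:
    """One observed peptide assignment, as read from an identification file.

    Parameters
    ----------
    sequence:
        Upper-case amino-acid sequence.
    proteins:
        Accessions of every protein this observation maps to (non-empty).
    run_index:
        1-based index of the replicate run the observation came from.
    score:
        Search-engine peptide score (``None`` when the source has none).
    modifications:
        One modification variant: ``((position, name), ...)``, 1-based.
    passes_threshold:
        Acceptance flag carried from the source file.
    protein_descriptions:
        Optional ``((accession, description), ...)`` pairs carried from the
        source so reports can show them.
    """

    sequence: str
    proteins: frozenset[str]
    run_index: int = 1
    score: float | None = None
    modifications: ModVariant = ()
    passes_threshold: bool = True
    protein_descriptions: tuple[tuple[str, str], ...] = ()

    def __init__(
        self,
        sequence: str,
        proteins: Iterable[str],
        run_index: int = 1,
        score: float | None = None,
        modifications: Iterable[tuple[int, str]] = (),
        passes_threshold: bool = True,
        protein_descriptions: Iterable[tuple[str, str]] = (),
    ) -> None:
        object.__setattr__(self, "sequence", str(sequence).upper())
        object.__setattr__(self, "proteins", frozenset(proteins))
        object.__setattr__(self, "run_index", int(run_index))
        object.__setattr__(self, "score", None if score is None else float(score))
        object.__setattr__(
            self, "modifications", tuple((int(p), str(n)) for p, n in modifications)
        )
        object.__setattr__(self, "passes_threshold", bool(passes_threshold))
        object.__setattr__(
            self, "protein_descriptions", tuple(tuple(x) for x in protein_descriptions)
        )

    def validate(self) -> None:
        """Raise :class:`ValidationError` if the record breaks an invariant."""
        if not self.sequence:
            raise ValidationError("peptide record with empty sequence")
        if not self.proteins:
            raise ValidationError(
                f"peptide record {self.sequence!r} has an empty protein accession set"
            )
        if any(not a for a in self.proteins):
            raise ValidationError(
                f"peptide record {self.sequence!r} contains an empty accession"
            )
        if self.run_index < 1:
            raise ValidationError(
                f"peptide record {self.sequence!r} has run_index "
                f"{self.run_index} (must be >= 1)"
            )


@dataclass
class Peptide:
    """A distinct peptide sequence in the evidence graph."""

    sequence: str
    proteins: set[str] = field(default_factory=set)
    runs: set[int] = field(default_factory=set)
    variants: list[ModVariant] = field(default_factory=list)
    category: PeptideCategory | None = None


@dataclass
class Protein:
    """A protein accession in the evidence graph."""

    accession: str
    description: str = ""
    peptides: set[str] = field(default_factory=set)
    category: ProteinCategory | None = None


@dataclass
class EvidenceGraph:
    """Deduplicated bipartite peptide<->protein map.

    ``peptides`` and ``proteins`` are dicts built in lexicographic key order,
    so iteration order is canonical regardless of input record order.
    """

    peptides: dict[str, Peptide]
    proteins: dict[str, Protein]
    n_runs: int = 1

    def check_symmetry(self) -> None:
        """Raise :class:`ConsistencyError` unless the bipartite map is symmetric."""
        for seq, pep in self.peptides.items():
            for acc in pep.proteins:
                if acc not in self.proteins or seq not in self.proteins[acc].peptides:
                    raise ConsistencyError(
                        f"asymmetry: peptide {seq!r} lists protein {acc!r} "
                        "but not vice versa"
                    )
        for acc, prot in self.proteins.items():
            for seq in prot.peptides:
                if seq not in self.peptides or acc not in self.peptides[seq].proteins:
                    raise ConsistencyError(
                        f"asymmetry: protein {acc!r} lists peptide {seq!r} "
                        "but not vice versa"
                    )


# --------------------------------------------------------------------------
# Classification output
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinGroup:
    """One output unit: proteins reported together under one category.

    Conclusive and non-conclusive groups are singletons; indistinguishable
    and ambiguous groups have at least two members.
    """

    group_id: int
    category: ProteinCategory
    members: tuple[str, ...]
    peptide_annotations: Mapping[str, PeptideCategory]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("protein group with no members")
        if (
            self.category in (ProteinCategory.CONCLUSIVE, ProteinCategory.NON_CONCLUSIVE)
            and len(self.members) != 1
        ):
            raise ConsistencyError(
                f"{self.category.label} group {self.group_id} must be a singleton"
            )
        if (
            self.category
            in (ProteinCategory.INDISTINGUISHABLE, ProteinCategory.AMBIGUOUS_GROUP)
            and len(self.members) < 2
        ):
            raise ConsistencyError(
                f"{self.category.label} group {self.group_id} must have >= 2 members"
            )


@dataclass
class ClassificationResult:
    """The full partition of proteins into evidence groups.

    ``stats`` maps every :class:`ProteinCategory` to ``(protein count,
    group count)``; filtered proteins have group count 0.  ``graph`` is the
    classified evidence graph the groups were derived from (used by the
    report writers for run occupancy and modification variants).
    """

    groups: list[ProteinGroup]
    stats: dict[ProteinCategory, tuple[int, int]]
    filtered_accessions: frozenset[str]
    graph: EvidenceGraph

    @property
    def n_runs(self) -> int:
        return self.graph.n_runs

    def protein_count(self) -> int:
        """Total proteins accounted for, including the filtered bucket."""
        return sum(n for n, _ in self.stats.values())


# --------------------------------------------------------------------------
# Graph construction
# --------------------------------------------------------------------------


def build_graph(
    records: Sequence[PeptideRecord], n_runs: int | None = None
) -> EvidenceGraph:
    """Build the deduplicated bipartite evidence graph from raw records.

    Peptides are merged by exact sequence: protein sets and run sets are
    unioned and distinct modification variants collected.  Proteins are keyed
    by accession.  Both maps are built in lexicographic key order so the
    graph is identical for any permutation or duplication of ``records``.

    Parameters
    ----------
    records:
        Non-empty list of peptide assignment records.
    n_runs:
        Total number of replicate runs.  Defaults to the largest
        ``run_index`` seen.  Every record's ``run_index`` must be <= n_runs.
    """
    if not records:
        raise ValidationError("no identifications: the record list is empty")
    for rec in records:
        rec.validate()
    if n_runs is None:
        n_runs = max(rec.run_index for rec in records)
    if n_runs < 1:
        raise ValidationError(f"n_runs must be >= 1, got {n_runs}")
    for rec in records:
        if rec.run_index > n_runs:
            raise ValidationError(
                f"record {rec.sequence!r} has run_index {rec.run_index} > "
                f"n_runs {n_runs}"
            )

    # Accumulate, then emit in canonical (lexicographic) order.
    pep_proteins: dict[str, set[str]] = {}
    pep_runs: dict[str, set[int]] = {}
    pep_variants: dict[str, set[ModVariant]] = {}
    descriptions: dict[str, str] = {}
    for rec in records:
        seq = rec.sequence
        pep_proteins.setdefault(seq, set()).update(rec.proteins)
        pep_runs.setdefault(seq, set()).add(rec.run_index)
        pep_variants.setdefault(seq, set()).add(
            tuple(sorted(rec.modifications))
        )
        for acc, desc in rec.protein_descriptions:
            if desc and not descriptions.get(acc):
                descriptions[acc] = desc

    peptides: dict[str, Peptide] = {}
    proteins: dict[str, Protein] = {}
    for seq in sorted(pep_proteins):
        peptides[seq] = Peptide(
            sequence=seq,
            proteins=set(pep_proteins[seq]),
            runs=set(pep_runs[seq]),
            variants=sorted(pep_variants[seq]),
        )
    for acc in sorted({a for accs in pep_proteins.values() for a in accs}):
        proteins[acc] = Protein(accession=acc, description=descriptions.get(acc, ""))
    for seq, pep in peptides.items():
        for acc in pep.proteins:
            proteins[acc].peptides.add(seq)

    graph = EvidenceGraph(peptides=peptides, proteins=proteins, n_runs=n_runs)
    graph.check_symmetry()
    logger.debug(
        "built evidence graph: %d peptides, %d proteins, %d run(s)",
        len(peptides),
        len(proteins),
        n_runs,
    )
    return graph
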