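"""Synthetic evidence fixtures.

Every input this package is tested with is generated here — no external
dataset is required.  Two frozen worked examples and a seeded random
generator are provided, along with writers that serialise any record list
to the PLGS-dialect XML and to minimal mzIdentML, so the file readers can
be exercised end to end.

* :func:`fixture_F1` — a single-run "all scenarios" graph of 9 proteins and
  6 peptides that exhibits all three peptide types and all four protein
  evidence categories at once.
* :func:`fixture_MR1` — a three-run replicate example of 4 proteins whose
  classification flips between the peptide-merging and peptide-voting
  strategies.
* :func:`random_graph` — seeded random bipartite evidence, for property
  tests.

F1 and MR1 are frozen: their maps are part of the package contract and are
golden-tested.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import PeptideRecord, ValidationError
from .io_mzid import write_records_mzid
from .io_plgs import read_plgs_xml  # noqa: F401  (round-trip convenience)

__all__ = [
    "fixture_F1",
    "fixture_MR1",
    "random_graph",
    "write_plgs_file",
    "write_mzid_file",
    "write_mzid_run_files",
]

# Frozen wiring of the all-scenarios example: sequence -> accessions.
# Classification: A conclusive; B, H, I non-conclusive; {C, D}
# indistinguishable; {E, F, G} one ambiguous group.  Peptides: AIDEGLK
# unique; DELTAK, FGHIKK, MNPQRK discriminating; CHEWGR, STVWYK
# non-discriminating.
_F1_MAP: dict[str, tuple[str, ...]] = {
    "AIDEGLK": ("A",),
    "CHEWGR": ("A", "B", "I"),
    "DELTAK": ("C", "D"),
    "FGHIKK": ("E", "F"),
    "MNPQRK": ("F", "G"),
    "STVWYK": ("C", "D", "H"),
}

_F1_SCORES: dict[str, float] = {
    "AIDEGLK": 7.5,
    "CHEWGR": 6.2,
    "DELTAK": 5.8,
    "FGHIKK": 5.1,
    "MNPQRK": 4.2,
    "STVWYK": 3.3,
}


def fixture_F1() -> list[PeptideRecord]:
    """The all-scenarios worked example: 9 proteins, 6 peptides, one run.

    Classifying it yields one conclusive protein (A), three non-conclusive
    proteins (B, H, I), one indistinguishable pair {C, D} and one ambiguous
    group {E, F, G}; the peptides cover all three evidence types.
    """
    return [
        PeptideRecord(
            sequence=seq,
            proteins=set(accs),
            run_index=1,
            score=_F1_SCORES[seq],
            protein_descriptions=tuple((a, f"Protein {a}") for a in accs),
        )
        for seq, accs in _F1_MAP.items()
    ]


# Frozen wiring of the replicate example: sequence -> (accessions, runs).
_MR1_MAP: dict[str, tuple[tuple[str, ...], tuple[int, ...]]] = {
    "AAGILK": (("A",), (1, 2)),
    "CCNGYK": (("A", "B"), (1, 2, 3)),
    "DDFWSK": (("B",), (1, 2, 3)),
    "EEHMTK": (("C",), (2,)),
    "FFQVPR": (("C", "D"), (1, 2, 3)),
    "GGKDER": (("D",), (1, 2, 3)),
}

MR1_N_RUNS = 3


def fixture_MR1() -> list[PeptideRecord]:
    """The replicate-integration worked example: 4 proteins, 3 runs.

    Protein A's unique peptide is seen in runs 1-2 only, so A is conclusive
    in single-run analyses of runs 1 and 2 but non-conclusive in run 3.
    Protein C's unique peptide is seen in run 2 only: peptide merging
    (threshold 1) keeps it and makes C conclusive, while peptide voting
    (threshold 2 of 3) removes it and demotes C to non-conclusive.
    """
    records = []
    for seq, (accs, runs) in _MR1_MAP.items():
        for run in runs:
            records.append(
                PeptideRecord(
                    sequence=seq,
                    proteins=set(accs),
                    run_index=run,
                    score=5.0,
                    protein_descriptions=tuple((a, f"Protein {a}") for a in accs),
                )
            )
    return records


_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def random_graph(
    n_proteins: int = 10,
    n_peptides: int = 15,
    mean_degree: float = 2.0,
    n_runs: int = 1,
    dropout: float = 0.0,
    seed: int = 0,
) -> list[PeptideRecord]:
    """Seeded random bipartite evidence for property testing.

    Each peptide draws a protein set whose size is truncated-Poisson around
    ``mean_degree`` (at least 1, at most ``n_proteins``); each
    ``(peptide, run)`` observation is retained with probability
    ``1 - dropout``, with at least one run guaranteed per peptide.  Output
    is deterministic for a fixed seed and can be serialised with the
    writers in this module.
    """
    if n_proteins < 1 or n_peptides < 1 or n_runs < 1:
        raise ValidationError("n_proteins, n_peptides and n_runs must be >= 1")
    if not (0 <= dropout < 1):
        raise ValidationError(f"dropout must be in [0, 1), got {dropout}")
    if mean_degree < 1:
        raise ValidationError(f"mean_degree must be >= 1, got {mean_degree}")
    rng = np.random.default_rng(seed)

    accessions = [f"P{i:03d}" for i in range(1, n_proteins + 1)]
    sequences: list[str] = []
    seen: set[str] = set()
    while len(sequences) < n_peptides:
        seq = "".join(_ALPHABET[i] for i in rng.integers(0, len(_ALPHABET), size=9))
        if seq not in seen:
            seen.add(seq)
            sequences.append(seq)

    records: list[PeptideRecord] = []
    for seq in sequences:
        degree = int(min(n_proteins, max(1, rng.poisson(mean_degree))))
        proteins = set(rng.choice(accessions, size=degree, replace=False))
        runs = [r for r in range(1, n_runs + 1) if rng.random() >= dropout]
        if not runs:
            runs = [int(rng.integers(1, n_runs + 1))]
        score = float(np.round(rng.uniform(0.0, 10.0), 3))
        for run in runs:
            records.append(
                PeptideRecord(
                    sequence=seq, proteins=proteins, run_index=run, score=score
                )
            )
    return records


# --------------------------------------------------------------------------
# Serialisation of record lists to input files
# --------------------------------------------------------------------------


def write_plgs_file(
    records: list[PeptideRecord], path: str | Path, run_index: int | None = None
) -> None:
    """Write records (optionally one run only) as a PLGS-dialect XML file."""
    from lxml import etree

    selected = [
        r for r in records if run_index is None or r.run_index == run_index
    ]
    root = etree.Element("results")
    descriptions: dict[str, str] = {}
    by_protein: dict[str, list[PeptideRecord]] = {}
    for rec in selected:
        for acc in rec.proteins:
            by_protein.setdefault(acc, []).append(rec)
        for acc, desc in rec.protein_descriptions:
            descriptions.setdefault(acc, desc)
    for acc in sorted(by_protein):
        prot_el = etree.SubElement(root, "protein", accession=acc)
        if descriptions.get(acc):
            prot_el.set("description", descriptions[acc])
        emitted: set[tuple[str, tuple]] = set()
        for rec in sorted(by_protein[acc], key=lambda r: r.sequence):
            key = (rec.sequence, rec.modifications)
            if key in emitted:
                continue
            emitted.add(key)
            pep_el = etree.SubElement(prot_el, "peptide", sequence=rec.sequence)
            if rec.score is not None:
                pep_el.set("score", repr(rec.score))
            for position, name in rec.modifications:
                etree.SubElement(
                    pep_el, "modification", position=str(position), name=name
                )
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def write_mzid_file(
    records: list[PeptideRecord],
    path: str | Path,
    run_index: int | None = None,
    version: str = "1.1.0",
) -> None:
    """Write records (optionally one run only) as a minimal mzIdentML file."""
    selected = [
        r for r in records if run_index is None or r.run_index == run_index
    ]
    write_records_mzid(selected, path, version=version)


def write_mzid_run_files(
    records: list[PeptideRecord], directory: str | Path, stem: str = "run"
) -> list[Path]:
    """Write one mzIdentML file per run; returns the paths in run order."""
    directory = Path(directory)
    runs = sorted({r.run_index for r in records})
    paths = []
    for run in runs:
        path = directory / f"{stem}{run}.mzid"
        write_mzid_file(records, path, run_index=run)
        paths.append(path)
    return paths
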