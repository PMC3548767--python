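"""Replicate-run integration.

When several technical replicates of a sample are analysed together, a
*runs threshold* sets the minimum number of replicate runs in which a
peptide must have been observed to take part in protein inference.  Two
named strategies:

* **peptide merging** — threshold 1: every peptide identified in any run
  counts (least conservative);
* **peptide voting** — threshold ``floor(n/2) + 1``, a strict majority of
  the runs (conservative).

Proteins that lose every peptide to the filter are returned separately so
they can be reported in the *filtered* bucket rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .model import PeptideRecord, ValidationError

logger = logging.getLogger("protinfer")

__all__ = ["RunsThreshold", "voting_threshold", "filter_by_runs"]


@dataclass(frozen=True)
class RunsThreshold:
    """Minimum number of replicate runs a peptide must be observed in.

    A value above the actual number of runs is permitted; it simply filters
    every peptide.
    """

    value: int

    def __post_init__(self) -> None:
        if self.value < 1:
            raise ValidationError(
                f"runs threshold must be >= 1, got {self.value}"
            )


def voting_threshold(n_runs: int) -> int:
    """Strict-majority ("half plus one") runs threshold: ``floor(n/2) + 1``.

    For five replicates this is 3; for three replicates, 2; for a single
    run, 1.
    """
    if n_runs < 1:
        raise ValidationError(f"n_runs must be >= 1, got {n_runs}")
    return n_runs // 2 + 1


def filter_by_runs(
    records: Sequence[PeptideRecord], threshold: RunsThreshold | int
) -> tuple[list[PeptideRecord], frozenset[str]]:
    """Keep peptides observed in at least ``threshold`` distinct runs.

    Returns ``(kept records, filtered accessions)``: the kept records from
    all runs merged into one list, plus the accessions whose every peptide
    was removed.  Kept and filtered accessions are disjoint and together
    cover every accession in the input.
    """
    if isinstance(threshold, int):
        threshold = RunsThreshold(threshold)

    runs_by_seq: dict[str, set[int]] = {}
    for rec in records:
        runs_by_seq.setdefault(rec.sequence, set()).add(rec.run_index)

    kept = [
        rec
        for rec in records
        if len(runs_by_seq[rec.sequence]) >= threshold.value
    ]
    all_accessions = {a for rec in records for a in rec.proteins}
    kept_accessions = {a for rec in kept for a in rec.proteins}
    filtered = frozenset(all_accessions - kept_accessions)
    n_removed = len(runs_by_seq) - len({r.sequence for r in kept})
    if n_removed:
        logger.info(
            "runs threshold %d removed %d peptide(s); %d protein(s) filtered",
            threshold.value,
            n_removed,
            len(filtered),
        )
    return kept, filtered
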