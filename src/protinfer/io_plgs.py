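"""Reader for the documented PLGS-like XML dialect and score-band filtering.

ProteinLynx Global Server (PLGS) is the vendor search engine for MS^E
data-independent acquisition on Waters QTOF instruments.  Its XML schema is
proprietary, so this package defines and documents its own equivalent
dialect (see ``docs/formats.md`` and ``docs/plgs_dialect.xsd``)::

    <results>
      <protein accession="P12345" description="...">
        <peptide sequence="ELVISLIVESK" score="7.2">
          <modification position="3" name="Oxidation"/>
        </peptide>
      </protein>
    </results>

A peptide sequence may appear under several proteins; occurrences are
merged downstream by graph construction.  Each ``<peptide>`` element is one
modification variant.

Peptide confidence bands follow the vendor's traffic-light convention:
**green** (high), **yellow** (medium) and **red** (low confidence).  The two
numeric cutoffs come from a run log file (:func:`read_score_bands`) or from
explicit overrides; filtering at *red* keeps everything.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

from lxml import etree

from .model import ParseError, PeptideRecord, ValidationError

logger = logging.getLogger("protinfer")

__all__ = [
    "ScoreBands",
    "read_plgs_xml",
    "read_score_bands",
    "filter_by_band",
]

BandLevel = Literal["green", "yellow", "red"]


@dataclass(frozen=True)
class ScoreBands:
    """Numeric cutoffs for the green/yellow/red confidence bands.

    ``score >= green_min`` is green (high confidence); ``yellow_min <=
    score < green_min`` is yellow; anything below is red.
    """

    green_min: float
    yellow_min: float

    def __post_init__(self) -> None:
        if self.yellow_min < 0:
            raise ValidationError(
                f"yellow threshold must be >= 0, got {self.yellow_min}"
            )
        if self.green_min < self.yellow_min:
            raise ValidationError(
                f"green threshold ({self.green_min}) must be >= yellow "
                f"threshold ({self.yellow_min})"
            )

    def band_of(self, score: float) -> BandLevel:
        if score >= self.green_min:
            return "green"
        if score >= self.yellow_min:
            return "yellow"
        return "red"


def read_plgs_xml(path: str | Path, run_index: int = 1) -> list[PeptideRecord]:
    """Read one PLGS-dialect XML file into peptide assignment records.

    One record is produced per distinct ``(sequence, protein)`` occurrence;
    shared peptides are merged later by graph construction.  All records are
    tagged with ``run_index``.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "results":
        raise ParseError(
            f"{path}: not a PLGS-dialect file (root element "
            f"{etree.QName(root).localname!r}, expected 'results')"
        )
    records: list[PeptideRecord] = []
    for protein_el in root.iter("protein"):
        accession = protein_el.get("accession")
        if not accession:
            raise ValidationError(
                f"{path}:{protein_el.sourceline}: protein element without "
                "accession attribute"
            )
        description = protein_el.get("description", "")
        for pep_el in protein_el.iter("peptide"):
            sequence = pep_el.get("sequence")
            if not sequence:
                raise ValidationError(
                    f"{path}:{pep_el.sourceline}: peptide element without "
                    "sequence attribute"
                )
            score_attr = pep_el.get("score")
            mods = [
                (int(m.get("position")), m.get("name", ""))
                for m in pep_el.iter("modification")
            ]
            records.append(
                PeptideRecord(
                    sequence=sequence,
                    proteins={accession},
                    run_index=run_index,
                    score=None if score_attr is None else float(score_attr),
                    modifications=mods,
                    protein_descriptions=((accession, description),),
                )
            )
    logger.debug("%s: read %d peptide assignment(s)", path, len(records))
    return records


_GREEN_RE = re.compile(r"green\s*threshold\s*[:=]\s*([0-9]*\.?[0-9]+)", re.IGNORECASE)
_YELLOW_RE = re.compile(r"yellow\s*threshold\s*[:=]\s*([0-9]*\.?[0-9]+)", re.IGNORECASE)


def read_score_bands(log_path: str | Path) -> ScoreBands:
    """Read the green/yellow score cutoffs from a run log file.

    The log grammar (documented in ``docs/formats.md``) requires one line
    matching ``green threshold: <number>`` and one matching ``yellow
    threshold: <number>`` (case-insensitive; ``=`` also accepted).
    """
    log_path = Path(log_path)
    try:
        text = log_path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ParseError(
            f"cannot read score log {log_path}: {exc}; pass explicit "
            "--green/--yellow thresholds instead"
        ) from exc
    green = _GREEN_RE.search(text)
    yellow = _YELLOW_RE.search(text)
    if green is None or yellow is None:
        missing = [
            name
            for name, m in (("green", green), ("yellow", yellow))
            if m is None
        ]
        raise ParseError(
            f"{log_path}: no {' / '.join(missing)} threshold line found; "
            "pass explicit --green/--yellow thresholds instead"
        )
    return ScoreBands(green_min=float(green.group(1)), yellow_min=float(yellow.group(1)))


def filter_by_band(
    records: Sequence[PeptideRecord],
    bands: ScoreBands | None,
    level: BandLevel,
) -> tuple[list[PeptideRecord], frozenset[str]]:
    """Filter records by confidence band.

    ``red`` keeps everything (and needs no cutoffs); ``yellow`` keeps
    records with ``score >= yellow_min``; ``green`` keeps records with
    ``score >= green_min``.  Returns ``(kept records, accessions whose
    every peptide was removed)``.
    """
    if level not in ("green", "yellow", "red"):
        raise ValidationError(f"unknown band level {level!r}")
    if level == "red":
        return list(records), frozenset()
    if bands is None:
        raise ValidationError(
            f"band level {level!r} requires score thresholds (log file or "
            "--green/--yellow)"
        )
    cutoff = bands.green_min if level == "green" else bands.yellow_min
    kept: list[PeptideRecord] = []
    for rec in records:
        if rec.score is None:
            raise ValidationError(
                f"peptide {rec.sequence!r} has no score; cannot filter at "
                f"band level {level!r}"
            )
        if rec.score >= cutoff:
            kept.append(rec)
    all_accessions = {a for rec in records for a in rec.proteins}
    kept_accessions = {a for rec in kept for a in rec.proteins}
    filtered = frozenset(all_accessions - kept_accessions)
    logger.info(
        "band filter %r kept %d of %d record(s); %d protein(s) filtered",
        level,
        len(kept),
        len(records),
        len(filtered),
    )
    return kept, filtered
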