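"""mzIdentML input and output.

mzIdentML is the HUPO-PSI XML standard for peptide and protein
identification results.  This module reads version 1.0.0 and 1.1.0
documents into :class:`~protinfer.model.PeptideRecord` lists, writes an
mzIdentML 1.1.0 document whose ``ProteinDetectionList`` encodes an
inference result as ``ProteinAmbiguityGroup`` entries, and can serialise a
plain record list to a minimal but structurally complete 1.1.0 document
(used for fixtures and round-trip testing).

Reading: one record per accepted ``SpectrumIdentificationItem``.  The
peptide sequence is resolved through the item's peptide reference, protein
accessions through peptide-evidence -> database-sequence references (1.1.0
uses ``PeptideEvidenceRef`` children, 1.0.0 inline ``PeptideEvidence``
elements — both are handled).  Items with ``passThreshold="false"`` are
dropped when requested, and decoy-flagged evidences are always excluded.

Writing: each inferred group becomes one ``ProteinAmbiguityGroup``; every
member protein is carried as a ``ProteinDetectionHypothesis`` annotated
with the PSI-MS controlled-vocabulary term **MS:1001600 "Protein Inference
Confidence Category"**, whose value names the group's evidence category
("conclusive", "non-conclusive", "indistinguishable" or "ambiguous group").
Filtered proteins are omitted from the detection list (logged).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

from .model import (
    ClassificationResult,
    ParseError,
    PeptideRecord,
    ProteinCategory,
    UnsupportedOperationError,
    UnsupportedVersionError,
)

logger = logging.getLogger("protinfer")

__all__ = [
    "MZID_NS_1_0",
    "MZID_NS_1_1",
    "CV_INFERENCE_CATEGORY",
    "read_mzid",
    "write_mzid",
    "write_records_mzid",
    "validate_mzid",
]

MZID_NS_1_0 = "http://psidev.info/psi/pi/mzIdentML/1.0"
MZID_NS_1_1 = "http://psidev.info/psi/pi/mzIdentML/1.1"
_SUPPORTED = {MZID_NS_1_0: "1.0.0", MZID_NS_1_1: "1.1.0"}

#: PSI-MS CV accession for the protein inference confidence category.
CV_INFERENCE_CATEGORY = "MS:1001600"
CV_INFERENCE_CATEGORY_NAME = "Protein Inference Confidence Category"


def _get_attr(el: etree._Element, *names: str) -> str | None:
    """First present attribute among case/spelling variants (1.0 vs 1.1)."""
    for name in names:
        value = el.get(name)
        if value is not None:
            return value
    return None


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------


def read_mzid(
    path: str | Path,
    respect_pass_threshold: bool = True,
    run_index: int = 1,
) -> list[PeptideRecord]:
    """Read an mzIdentML 1.0.0 / 1.1.0 file into peptide assignment records.

    One record per accepted spectrum identification item, carrying every
    non-decoy accession the item's peptide evidences resolve to.  Items
    whose evidences are all decoys yield no record.

    Raises
    ------
    UnsupportedVersionError
        If the root namespace is not a supported mzIdentML version.
    ParseError
        On malformed XML or dangling peptide / evidence / sequence
        references (the message names the offending id).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    ns = etree.QName(root).namespace
    if ns not in _SUPPORTED:
        raise UnsupportedVersionError(
            f"{path}: unsupported root namespace {ns!r}; expected mzIdentML "
            f"1.0.0 ({MZID_NS_1_0}) or 1.1.0 ({MZID_NS_1_1})"
        )
    if etree.QName(root).localname != "MzIdentML":
        raise ParseError(
            f"{path}: root element is {etree.QName(root).localname!r}, "
            "expected 'MzIdentML'"
        )

    def q(local: str) -> str:
        return f"{{{ns}}}{local}"

    peptides = {el.get("id"): el for el in root.iter(q("Peptide"))}
    dbseqs = {el.get("id"): el for el in root.iter(q("DBSequence"))}
    evidences = {el.get("id"): el for el in root.iter(q("PeptideEvidence"))}

    records: list[PeptideRecord] = []
    for sii in root.iter(q("SpectrumIdentificationItem")):
        pass_flag = (sii.get("passThreshold", "true").lower() == "true")
        if respect_pass_threshold and not pass_flag:
            continue
        pep_ref = _get_attr(sii, "peptide_ref", "Peptide_ref")
        if pep_ref is None:
            raise ParseError(
                f"{path}: SpectrumIdentificationItem {sii.get('id')!r} has "
                "no peptide reference"
            )
        pep_el = peptides.get(pep_ref)
        if pep_el is None:
            raise ParseError(f"{path}: dangling peptide reference {pep_ref!r}")
        seq_el = pep_el.find(q("PeptideSequence"))
        if seq_el is None or not (seq_el.text or "").strip():
            raise ParseError(
                f"{path}: Peptide {pep_ref!r} has no PeptideSequence"
            )
        sequence = seq_el.text.strip()
        mods = []
        for mod_el in pep_el.findall(q("Modification")):
            location = int(mod_el.get("location", "0"))
            name = ""
            cv = mod_el.find(q("cvParam"))
            if cv is not None:
                name = cv.get("name", "")
            mods.append((location, name))

        # Evidence elements: referenced (1.1.0) or inline (1.0.0).
        ev_els: list[etree._Element] = []
        for ref_el in sii.findall(q("PeptideEvidenceRef")):
            ev_ref = ref_el.get("peptideEvidence_ref")
            ev_el = evidences.get(ev_ref)
            if ev_el is None:
                raise ParseError(
                    f"{path}: dangling peptide evidence reference {ev_ref!r}"
                )
            ev_els.append(ev_el)
        ev_els.extend(sii.findall(q("PeptideEvidence")))

        accessions: set[str] = set()
        descriptions: list[tuple[str, str]] = []
        for ev_el in ev_els:
            if (ev_el.get("isDecoy", "false").lower()) == "true":
                continue
            db_ref = _get_attr(ev_el, "dBSequence_ref", "DBSequence_Ref", "dBSequence_Ref")
            if db_ref is None:
                raise ParseError(
                    f"{path}: PeptideEvidence {ev_el.get('id')!r} has no "
                    "database sequence reference"
                )
            db_el = dbseqs.get(db_ref)
            if db_el is None:
                raise ParseError(
                    f"{path}: dangling database sequence reference {db_ref!r}"
                )
            accession = db_el.get("accession") or db_ref
            accessions.add(accession)
            desc = _db_description(db_el, q)
            if desc:
                descriptions.append((accession, desc))
        if not accessions:
            continue  # all evidences were decoys

        records.append(
            PeptideRecord(
                sequence=sequence,
                proteins=accessions,
                run_index=run_index,
                score=_item_score(sii, q),
                modifications=mods,
                passes_threshold=pass_flag,
                protein_descriptions=tuple(sorted(set(descriptions))),
            )
        )
    logger.debug(
        "%s: read %d record(s) (mzIdentML %s)", path, len(records), _SUPPORTED[ns]
    )
    return records


def _db_description(db_el: etree._Element, q) -> str:
    for cv in db_el.findall(q("cvParam")):
        if cv.get("accession") == "MS:1001088":  # protein description
            return cv.get("value", "")
    return ""


def _item_score(sii: etree._Element, q) -> float | None:
    """Best-effort peptide score: first cvParam whose name ends in 'score'."""
    for cv in sii.findall(q("cvParam")):
        name = (cv.get("name") or "").lower()
        if name.endswith("score") and cv.get("value") is not None:
            try:
                return float(cv.get("value"))
            except ValueError:
                continue
    return None


# --------------------------------------------------------------------------
# Writing: records -> minimal 1.1.0 document
# --------------------------------------------------------------------------


def _sub(parent, tag, **attrs):
    el = etree.SubElement(parent, f"{{{MZID_NS_1_1}}}{tag}")
    for k, v in attrs.items():
        el.set(k, str(v))
    return el


def _cvparam(parent, accession, name, value=None, cv_ref="PSI-MS"):
    attrs = {"cvRef": cv_ref, "accession": accession, "name": name}
    if value is not None:
        attrs["value"] = str(value)
    return _sub(parent, "cvParam", **attrs)


def _mzid_skeleton() -> etree._Element:
    root = etree.Element(
        f"{{{MZID_NS_1_1}}}MzIdentML",
        nsmap={None: MZID_NS_1_1},
        id="protinfer_output",
        version="1.1.0",
    )
    cv_list = _sub(root, "cvList")
    _sub(
        cv_list,
        "cv",
        id="PSI-MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Vocabularies",
        uri="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    software_list = _sub(root, "AnalysisSoftwareList")
    software = _sub(software_list, "AnalysisSoftware", id="AS_protinfer", name="protinfer")
    name_el = _sub(software, "SoftwareName")
    _sub(name_el, "userParam", name="protinfer")
    return root


def write_records_mzid(
    records: Sequence[PeptideRecord],
    out_path: str | Path,
    version: str = "1.1.0",
    decoy_accessions: Iterable[str] = (),
) -> None:
    """Serialise peptide assignment records to a minimal mzIdentML document.

    One document describes a single run; callers with multi-run record sets
    write one file per run.  ``version`` may be ``"1.1.0"`` (default,
    ``PeptideEvidenceRef`` style) or ``"1.0.0"`` (inline ``PeptideEvidence``
    style) — the latter exists so that readers of legacy documents can be
    exercised.  ``decoy_accessions`` are written with ``isDecoy="true"``.
    """
    if version not in ("1.1.0", "1.0.0"):
        raise UnsupportedVersionError(f"cannot write mzIdentML version {version!r}")
    decoys = frozenset(decoy_accessions)
    root = _mzid_skeleton()

    accessions = sorted({a for rec in records for a in rec.proteins})
    descriptions: dict[str, str] = {}
    for rec in records:
        for acc, desc in rec.protein_descriptions:
            descriptions.setdefault(acc, desc)

    # Distinct peptide variants: (sequence, modifications) -> Peptide id.
    variants: dict[tuple[str, tuple], str] = {}
    for rec in records:
        key = (rec.sequence, tuple(sorted(rec.modifications)))
        if key not in variants:
            variants[key] = f"Pep_{len(variants) + 1}"

    seq_coll = _sub(root, "SequenceCollection")
    for i, acc in enumerate(accessions, start=1):
        db = _sub(
            seq_coll,
            "DBSequence",
            id=f"DBSeq_{i}",
            accession=acc,
            searchDatabase_ref="SDB_1",
        )
        if descriptions.get(acc):
            _cvparam(db, "MS:1001088", "protein description", descriptions[acc])
    dbseq_id = {acc: f"DBSeq_{i}" for i, acc in enumerate(accessions, start=1)}

    for (sequence, mods), pep_id in sorted(variants.items(), key=lambda kv: kv[1]):
        pep = _sub(seq_coll, "Peptide", id=pep_id)
        seq_el = _sub(pep, "PeptideSequence")
        seq_el.text = sequence
        for position, name in mods:
            mod = _sub(pep, "Modification", location=position)
            _cvparam(mod, "MS:1001460", name or "unknown modification")

    # Peptide evidences: (peptide id, accession) -> evidence id.
    evidence_id: dict[tuple[str, str], str] = {}
    ev_records: list[tuple[str, str]] = []
    for rec in records:
        pep_id = variants[(rec.sequence, tuple(sorted(rec.modifications)))]
        for acc in sorted(rec.proteins):
            key = (pep_id, acc)
            if key not in evidence_id:
                evidence_id[key] = f"PE_{len(evidence_id) + 1}"
                ev_records.append(key)
    if version == "1.1.0":
        for pep_id, acc in ev_records:
            _sub(
                seq_coll,
                "PeptideEvidence",
                id=evidence_id[(pep_id, acc)],
                peptide_ref=pep_id,
                dBSequence_ref=dbseq_id[acc],
                isDecoy="true" if acc in decoys else "false",
            )

    coll = _sub(root, "AnalysisCollection")
    si = _sub(
        coll,
        "SpectrumIdentification",
        id="SI_1",
        spectrumIdentificationProtocol_ref="SIP_1",
        spectrumIdentificationList_ref="SIL_1",
    )
    _sub(si, "InputSpectra", spectraData_ref="SD_1")
    _sub(si, "SearchDatabaseRef", searchDatabase_ref="SDB_1")

    prot_coll = _sub(root, "AnalysisProtocolCollection")
    sip = _sub(
        prot_coll,
        "SpectrumIdentificationProtocol",
        id="SIP_1",
        analysisSoftware_ref="AS_protinfer",
    )
    st = _sub(sip, "SearchType")
    _cvparam(st, "MS:1001083", "ms-ms search")
    th = _sub(sip, "Threshold")
    _cvparam(th, "MS:1001494", "no threshold")

    data_coll = _sub(root, "DataCollection")
    inputs = _sub(data_coll, "Inputs")
    sdb = _sub(inputs, "SearchDatabase", id="SDB_1", location="synthetic.fasta")
    dbn = _sub(sdb, "DatabaseName")
    _sub(dbn, "userParam", name="synthetic sequence database")
    sd = _sub(inputs, "SpectraData", id="SD_1", location="synthetic.mzML")
    sid_format = _sub(sd, "SpectrumIDFormat")
    _cvparam(sid_format, "MS:1000774", "multiple peak list nativeID format")

    analysis_data = _sub(data_coll, "AnalysisData")
    sil = _sub(analysis_data, "SpectrumIdentificationList", id="SIL_1")
    for i, rec in enumerate(records, start=1):
        sir = _sub(
            sil,
            "SpectrumIdentificationResult",
            id=f"SIR_{i}",
            spectrumID=f"index={i - 1}",
            spectraData_ref="SD_1",
        )
        pep_id = variants[(rec.sequence, tuple(sorted(rec.modifications)))]
        sii = _sub(
            sir,
            "SpectrumIdentificationItem",
            id=f"SII_{i}",
            rank="1",
            chargeState="2",
            experimentalMassToCharge="500.0",
            passThreshold="true" if rec.passes_threshold else "false",
            peptide_ref=pep_id,
        )
        for acc in sorted(rec.proteins):
            if version == "1.1.0":
                _sub(
                    sii,
                    "PeptideEvidenceRef",
                    peptideEvidence_ref=evidence_id[(pep_id, acc)],
                )
            else:
                # 1.0.0 style: inline evidence with legacy attribute casing.
                ev = etree.SubElement(sii, f"{{{MZID_NS_1_1}}}PeptideEvidence")
                ev.set("id", evidence_id[(pep_id, acc)])
                ev.set("DBSequence_Ref", dbseq_id[acc])
                ev.set("isDecoy", "true" if acc in decoys else "false")
        if rec.score is not None:
            _cvparam(sii, "MS:1001153", "search engine specific score", rec.score)

    if version == "1.0.0":
        root = _retag(root, MZID_NS_1_0)
        root.set("version", "1.0.0")

    tree = etree.ElementTree(root)
    tree.write(
        str(out_path),
        xml_declaration=True,
        encoding="UTF-8",
        pretty_print=True,
    )
    logger.debug("%s: wrote %d record(s) as mzIdentML %s", out_path, len(records), version)


def _retag(el: etree._Element, target_ns: str) -> etree._Element:
    """Recursively rebuild an element tree under a different namespace."""
    new = etree.Element(
        f"{{{target_ns}}}{etree.QName(el).localname}", nsmap={None: target_ns}
    )
    for k, v in el.attrib.items():
        new.set(k, v)
    new.text = el.text
    new.tail = el.tail
    for child in el:
        new.append(_retag(child, target_ns))
    return new


# --------------------------------------------------------------------------
# Writing: inference result -> 1.1.0 document with ProteinDetectionList
# --------------------------------------------------------------------------


def write_mzid(
    source_path: str | Path,
    result: ClassificationResult,
    out_path: str | Path,
) -> None:
    """Write an mzIdentML 1.1.0 document encoding ``result``.

    The source document's sequence collection, inputs and spectrum
    identifications are carried over; the protein detection list is replaced
    by one ``ProteinAmbiguityGroup`` per inferred group, each member as a
    ``ProteinDetectionHypothesis`` annotated with the MS:1001600 category
    param.  Only single-run analyses with an mzIdentML source are supported;
    filtered proteins are omitted from the detection list.
    """
    if result.n_runs > 1:
        raise UnsupportedOperationError(
            "mzIdentML output is only generated for a single-run analysis "
            "with a single mzIdentML input"
        )
    source_path = Path(source_path)
    try:
        src_tree = etree.parse(str(source_path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{source_path}: malformed XML: {exc}") from exc
    src_root = src_tree.getroot()
    src_ns = etree.QName(src_root).namespace
    if src_ns not in _SUPPORTED:
        raise UnsupportedVersionError(
            f"{source_path}: unsupported root namespace {src_ns!r}"
        )
    if src_ns != MZID_NS_1_1:
        src_root = _retag(src_root, MZID_NS_1_1)

    def q(local: str) -> str:
        return f"{{{MZID_NS_1_1}}}{local}"

    root = _mzid_skeleton()

    # Carry over the sequence collection.
    src_seq_coll = src_root.find(q("SequenceCollection"))
    if src_seq_coll is None:
        raise ParseError(f"{source_path}: no SequenceCollection element")
    root.append(_retag(src_seq_coll, MZID_NS_1_1))

    coll = _sub(root, "AnalysisCollection")
    si = _sub(
        coll,
        "SpectrumIdentification",
        id="SI_1",
        spectrumIdentificationProtocol_ref="SIP_1",
        spectrumIdentificationList_ref="SIL_1",
    )
    _sub(si, "InputSpectra", spectraData_ref="SD_1")
    _sub(si, "SearchDatabaseRef", searchDatabase_ref="SDB_1")
    pd = _sub(
        coll,
        "ProteinDetection",
        id="PD_1",
        proteinDetectionProtocol_ref="PDP_1",
        proteinDetectionList_ref="PDL_1",
    )
    _sub(pd, "InputSpectrumIdentifications", spectrumIdentificationList_ref="SIL_1")

    prot_coll = _sub(root, "AnalysisProtocolCollection")
    sip = _sub(
        prot_coll,
        "SpectrumIdentificationProtocol",
        id="SIP_1",
        analysisSoftware_ref="AS_protinfer",
    )
    st = _sub(sip, "SearchType")
    _cvparam(st, "MS:1001083", "ms-ms search")
    th = _sub(sip, "Threshold")
    _cvparam(th, "MS:1001494", "no threshold")
    pdp = _sub(
        prot_coll,
        "ProteinDetectionProtocol",
        id="PDP_1",
        analysisSoftware_ref="AS_protinfer",
    )
    th2 = _sub(pdp, "Threshold")
    _cvparam(th2, "MS:1001494", "no threshold")

    data_coll = _sub(root, "DataCollection")
    src_inputs = src_root.find(f"{q('DataCollection')}/{q('Inputs')}")
    if src_inputs is not None:
        data_coll.append(_retag(src_inputs, MZID_NS_1_1))
    else:
        _sub(data_coll, "Inputs")
    analysis_data = _sub(data_coll, "AnalysisData")
    src_sil = src_root.find(
        f"{q('DataCollection')}/{q('AnalysisData')}/{q('SpectrumIdentificationList')}"
    )
    if src_sil is not None:
        analysis_data.append(_retag(src_sil, MZID_NS_1_1))

    # Index the carried-over document for hypothesis wiring.
    pep_seq: dict[str, str] = {}
    for pep_el in root.iter(q("Peptide")):
        s = pep_el.find(q("PeptideSequence"))
        if s is not None and s.text:
            pep_seq[pep_el.get("id")] = s.text.strip()
    db_accession = {el.get("id"): el.get("accession") for el in root.iter(q("DBSequence"))}
    # evidence id -> (sequence, accession)
    ev_info: dict[str, tuple[str, str]] = {}
    for ev_el in root.iter(q("PeptideEvidence")):
        if (ev_el.get("isDecoy", "false").lower()) == "true":
            continue
        pep_ref = _get_attr(ev_el, "peptide_ref", "Peptide_ref")
        db_ref = _get_attr(ev_el, "dBSequence_ref", "DBSequence_Ref")
        if pep_ref in pep_seq and db_ref in db_accession:
            ev_info[ev_el.get("id")] = (pep_seq[pep_ref], db_accession[db_ref])
    # evidence id -> referencing SII ids
    sii_by_ev: dict[str, list[str]] = {}
    for sii in root.iter(q("SpectrumIdentificationItem")):
        for ref_el in sii.findall(q("PeptideEvidenceRef")):
            sii_by_ev.setdefault(ref_el.get("peptideEvidence_ref"), []).append(
                sii.get("id")
            )
    dbseq_by_accession = {v: k for k, v in db_accession.items() if v}
    # (sequence, accession) -> evidence ids
    ev_by_pair: dict[tuple[str, str], list[str]] = {}
    for ev_id, pair in ev_info.items():
        ev_by_pair.setdefault(pair, []).append(ev_id)

    if result.filtered_accessions:
        logger.info(
            "omitting %d filtered protein(s) from the detection list",
            len(result.filtered_accessions),
        )

    pdl = _sub(analysis_data, "ProteinDetectionList", id="PDL_1")
    for group in result.groups:
        pag = _sub(pdl, "ProteinAmbiguityGroup", id=f"PAG_{group.group_id}")
        for acc in group.members:
            db_ref = dbseq_by_accession.get(acc)
            if db_ref is None:
                raise ParseError(
                    f"{source_path}: no DBSequence for inferred protein {acc!r}"
                )
            pdh = _sub(
                pag,
                "ProteinDetectionHypothesis",
                id=f"PDH_{acc}",
                dBSequence_ref=db_ref,
                passThreshold="true",
            )
            for seq in sorted(result.graph.proteins[acc].peptides):
                for ev_id in sorted(ev_by_pair.get((seq, acc), [])):
                    ph = _sub(pdh, "PeptideHypothesis", peptideEvidence_ref=ev_id)
                    for sii_id in sorted(sii_by_ev.get(ev_id, [])):
                        _sub(ph, "SpectrumIdentificationItemRef",
                             spectrumIdentificationItem_ref=sii_id)
            _cvparam(
                pdh,
                CV_INFERENCE_CATEGORY,
                CV_INFERENCE_CATEGORY_NAME,
                group.category.label,
            )

    etree.ElementTree(root).write(
        str(out_path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    logger.info("%s: wrote %d ambiguity group(s)", out_path, len(result.groups))


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

_REQUIRED_SECTIONS = ("SequenceCollection", "AnalysisCollection", "DataCollection")


def validate_mzid(path: str | Path, schema: str | Path | None = None) -> list[str]:
    """Validate an mzIdentML 1.1.0 document; return a list of problems.

    Without ``schema`` a structural validation is performed: well-formed
    XML, 1.1.0 root namespace and version, required top-level sections,
    every ``*_ref`` attribute resolving to an existing ``id``, and exactly
    one MS:1001600 category param on each ``ProteinDetectionHypothesis``.
    With ``schema`` (a local copy of the official XSD) full schema
    validation is performed instead.  An empty list means the document is
    valid.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        return [f"malformed XML: {exc}"]

    if schema is not None:
        xmlschema = etree.XMLSchema(etree.parse(str(schema)))
        if xmlschema.validate(tree):
            return []
        return [str(e) for e in xmlschema.error_log]

    problems: list[str] = []
    root = tree.getroot()
    qname = etree.QName(root)
    if qname.namespace != MZID_NS_1_1:
        problems.append(f"root namespace is {qname.namespace!r}, expected 1.1.0")
        return problems
    if qname.localname != "MzIdentML":
        problems.append(f"root element is {qname.localname!r}")
    if not (root.get("version") or "").startswith("1.1"):
        problems.append(f"version attribute is {root.get('version')!r}")

    def q(local: str) -> str:
        return f"{{{MZID_NS_1_1}}}{local}"

    for section in _REQUIRED_SECTIONS:
        if root.find(q(section)) is None:
            problems.append(f"missing required section {section}")

    ids = {el.get("id") for el in root.iter() if el.get("id")}
    for el in root.iter():
        for attr, value in el.attrib.items():
            if attr.lower().endswith("_ref") and value not in ids:
                problems.append(
                    f"dangling reference {attr}={value!r} on "
                    f"{etree.QName(el).localname}"
                )

    for pdh in root.iter(q("ProteinDetectionHypothesis")):
        n = sum(
            1
            for cv in pdh.findall(q("cvParam"))
            if cv.get("accession") == CV_INFERENCE_CATEGORY
        )
        if n != 1:
            problems.append(
                f"ProteinDetectionHypothesis {pdh.get('id')!r} carries {n} "
                f"{CV_INFERENCE_CATEGORY} params (expected exactly 1)"
            )
    return problems
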