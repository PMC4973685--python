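"""Reading and writing of mzq-lite XML and of PSM lists.

The mzq-lite dialect mirrors the element names of mzQuantML
(``MzQuantML``, ``AssayList``/``Assay``, ``StudyVariableList``,
``FeatureList``/``Feature``, ``PeptideConsensusList``/``PeptideConsensus``,
``ProteinList``, ``ProteinGroupList``, ``AssayQuantLayer`` with
``DataMatrix``/``Row``) without namespaces or schema validation. Matrix
cells are whitespace-separated tokens within a ``Row``; the tokens
``null`` and ``NaN`` (case-sensitive) denote the two kinds of missing
value. Floats are serialised with ``repr`` so writing is byte-stable and
round trips are exact.

PSM lists come in two dialects: ``mzid_lite`` XML (a minimal
SpectrumIdentificationResult/Item shape with the retention time as cvParam
MS:1000894 on the result) and a TSV with a fixed header. Retention time is
converted to seconds on read when a unit says minutes. All readers accept
gzipped input transparently.
"""

from __future__ import annotations

import gzip
import io as _stdio
import logging
import math
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import IO, Optional, Union

from .model import (
    NULL,
    Assay,
    Cell,
    CvParam,
    Feature,
    FeatureList,
    Level,
    Mode,
    MzqError,
    MzqValidationError,
    PeptideConsensus,
    ProteinGroup,
    ProteinRecord,
    PSMRecord,
    QuantDocument,
    QuantLayer,
    Software,
    StudyVariable,
    format_modifications,
    get_quant_layer,
    is_nan,
    is_null,
    parse_modifications,
)

__all__ = [
    "read_mzq",
    "write_mzq",
    "read_psms",
    "get_quant_layer",
    "MzqFormatError",
]

log = logging.getLogger(__name__)

_KNOWN_MZQ_CHILDREN = {
    "SoftwareList",
    "AssayList",
    "StudyVariableList",
    "FeatureList",
    "PeptideConsensusList",
    "ProteinList",
    "ProteinGroupList",
    "QuantLayerList",
}


class MzqFormatError(MzqError):
    """The file is not parseable in the declared dialect."""


def _open_maybe_gzip(path: Union[str, Path], mode: str = "rt") -> IO:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode, encoding="utf-8" if "t" in mode else None)
    return open(path, mode, encoding="utf-8" if "t" in mode else None)


# ---------------------------------------------------------------------------
# mzq-lite reading


def _parse_xml(path: Union[str, Path]) -> ET.Element:
    try:
        with _open_maybe_gzip(path, "rt") as fh:
            return ET.parse(fh).getroot()
    except ET.ParseError as exc:
        raise MzqFormatError(f"{path}: malformed XML: {exc}") from exc


def _req(elem: ET.Element, attr: str, path) -> str:
    v = elem.get(attr)
    if v is None:
        raise MzqFormatError(
            f"{path}: <{elem.tag}> missing required attribute {attr!r}"
        )
    return v


def _parse_cell(token: str, where: str) -> Cell:
    if token == "null":
        return NULL
    if token == "NaN":
        return float("nan")
    try:
        return float(token)
    except ValueError as exc:
        raise MzqFormatError(f"{where}: bad matrix cell {token!r}") from exc


def _parse_cv(elem: ET.Element) -> CvParam:
    return CvParam(
        accession=elem.get("accession", ""),
        name=elem.get("name", ""),
        value=elem.get("value"),
        unit=elem.get("unit"),
    )


def read_mzq(path: Union[str, Path]) -> QuantDocument:
    """Parse an mzq-lite XML file into a validated :class:`QuantDocument`.

    Unknown top-level elements are ignored with a logged warning. Raises
    :class:`MzqFormatError` for malformed files and the model's
    validation/reference errors for invariant violations.
    """
    root = _parse_xml(path)
    if root.tag != "MzQuantML":
        raise MzqFormatError(f"{path}: root element is <{root.tag}>, not <MzQuantML>")
    doc = QuantDocument(mode=Mode(root.get("mode", "label_free")))

    for child in root:
        if child.tag not in _KNOWN_MZQ_CHILDREN:
            log.warning("%s: ignoring unknown element <%s>", path, child.tag)

    for sw in root.iterfind("SoftwareList/Software"):
        doc.software.append(
            Software(
                name=_req(sw, "name", path),
                version=sw.get("version", ""),
                params=[_parse_cv(cv) for cv in sw.iterfind("CvParam")],
            )
        )

    for a in root.iterfind("AssayList/Assay"):
        doc.assays.append(
            Assay(
                id=_req(a, "id", path),
                name=a.get("name", ""),
                raw_file_ref=a.get("rawFileRef", ""),
            )
        )

    for sv in root.iterfind("StudyVariableList/StudyVariable"):
        doc.study_variables.append(
            StudyVariable(
                id=_req(sv, "id", path),
                name=sv.get("name", ""),
                assay_refs=[_req(r, "ref", path) for r in sv.iterfind("AssayRef")],
            )
        )

    for fl in root.iterfind("FeatureList"):
        features = []
        for f in fl.iterfind("Feature"):
            start = f.get("rtWindowStart")
            end = f.get("rtWindowEnd")
            if (start is None) != (end is None):
                raise MzqFormatError(
                    f"{path}: feature {f.get('id')!r} has half an RT window"
                )
            rt = float(_req(f, "rt", path))
            window = None
            if start is not None:
                window = (float(start), float(end))
            if f.get("rtUnit", "second") == "minute":
                rt *= 60.0
                if window is not None:
                    window = (window[0] * 60.0, window[1] * 60.0)
            charge = f.get("charge")
            features.append(
                Feature(
                    id=_req(f, "id", path),
                    mz=float(_req(f, "mz", path)),
                    rt=rt,
                    rt_window=window,
                    charge=int(charge) if charge is not None else None,
                )
            )
        doc.feature_lists.append(
            FeatureList(
                id=_req(fl, "id", path),
                raw_file_ref=_req(fl, "rawFileRef", path),
                features=features,
            )
        )

    for pc in root.iterfind("PeptideConsensusList/PeptideConsensus"):
        charge = pc.get("charge")
        refs: dict[str, str] = {}
        for fr in pc.iterfind("FeatureRef"):
            fl_id = _req(fr, "featureList", path)
            if fl_id in refs:
                raise MzqValidationError(
                    f"peptide {pc.get('id')!r}: two features from list {fl_id!r}"
                )
            refs[fl_id] = _req(fr, "feature", path)
        doc.peptide_list.append(
            PeptideConsensus(
                id=_req(pc, "id", path),
                sequence=pc.get("sequence"),
                modifications=parse_modifications(pc.get("modifications", "")),
                charge=int(charge) if charge is not None else None,
                feature_refs=refs,
                conflict_flag=pc.get("conflict", "false") == "true",
                user_params=[_parse_cv(up) for up in pc.iterfind("UserParam")],
            )
        )

    for pr in root.iterfind("ProteinList/Protein"):
        doc.protein_list.append(
            ProteinRecord(
                accession=_req(pr, "accession", path),
                peptide_refs=[_req(r, "ref", path) for r in pr.iterfind("PeptideRef")],
            )
        )

    for pg in root.iterfind("ProteinGroupList/ProteinGroup"):
        doc.protein_groups.append(
            ProteinGroup(
                id=_req(pg, "id", path),
                member_accessions=[
                    _req(m, "accession", path) for m in pg.iterfind("Member")
                ],
                anchor_accession=_req(pg, "anchor", path),
                peptide_refs=[_req(r, "ref", path) for r in pg.iterfind("PeptideRef")],
            )
        )

    for ql in root.iterfind("QuantLayerList/AssayQuantLayer"):
        dt = ql.find("DataType")
        if dt is None:
            raise MzqFormatError(f"{path}: quant layer missing <DataType>")
        cols_elem = ql.find("ColumnRefs")
        cols = (cols_elem.text or "").split() if cols_elem is not None else []
        row_refs: list[str] = []
        values: list[list[Cell]] = []
        for row in ql.iterfind("DataMatrix/Row"):
            ref = _req(row, "ref", path)
            row_refs.append(ref)
            tokens = (row.text or "").split()
            values.append(
                [_parse_cell(t, f"{path} row {ref!r}") for t in tokens]
            )
        doc.quant_layers.append(
            QuantLayer(
                id=_req(ql, "id", path),
                level=Level(_req(ql, "level", path)),
                data_type=_parse_cv(dt),
                column_refs=cols,
                row_refs=row_refs,
                values=values,
            )
        )

    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# mzq-lite writing


def _fmt_cell(cell: Cell) -> str:
    if is_null(cell):
        return "null"
    if is_nan(cell):
        return "NaN"
    return repr(float(cell))


def _fmt_float(x: float) -> str:
    return repr(float(x))


def write_mzq(doc: QuantDocument, path: Union[str, Path]) -> None:
    """Serialise a document to mzq-lite XML.

    Validates first (no bytes are written for an invalid document) and
    produces byte-identical output for equal documents: element order
    follows the document's list order and floats use shortest round-trip
    ``repr`` formatting.
    """
    doc.validate()
    buf = _stdio.StringIO()
    w = buf.write
    w('<?xml version="1.0" encoding="UTF-8"?>\n')
    w(f'<MzQuantML mode="{doc.mode.value}">\n')

    if doc.software:
        w("  <SoftwareList>\n")
        for sw in doc.software:
            if sw.params:
                w(f'    <Software name="{_esc(sw.name)}" version="{_esc(sw.version)}">\n')
                for cv in sw.params:
                    w(f"      {_cv_xml(cv, 'CvParam')}\n")
                w("    </Software>\n")
            else:
                w(f'    <Software name="{_esc(sw.name)}" version="{_esc(sw.version)}"/>\n')
        w("  </SoftwareList>\n")

    w("  <AssayList>\n")
    for a in doc.assays:
        w(
            f'    <Assay id="{_esc(a.id)}" name="{_esc(a.name)}" '
            f'rawFileRef="{_esc(a.raw_file_ref)}"/>\n'
        )
    w("  </AssayList>\n")

    if doc.study_variables:
        w("  <StudyVariableList>\n")
        for sv in doc.study_variables:
            w(f'    <StudyVariable id="{_esc(sv.id)}" name="{_esc(sv.name)}">\n')
            for ref in sv.assay_refs:
                w(f'      <AssayRef ref="{_esc(ref)}"/>\n')
            w("    </StudyVariable>\n")
        w("  </StudyVariableList>\n")

    for fl in doc.feature_lists:
        w(f'  <FeatureList id="{_esc(fl.id)}" rawFileRef="{_esc(fl.raw_file_ref)}">\n')
        for f in fl.features:
            attrs = f'id="{_esc(f.id)}" mz="{_fmt_float(f.mz)}" rt="{_fmt_float(f.rt)}"'
            if f.rt_window is not None:
                attrs += (
                    f' rtWindowStart="{_fmt_float(f.rt_window[0])}"'
                    f' rtWindowEnd="{_fmt_float(f.rt_window[1])}"'
                )
            if f.charge is not None:
                attrs += f' charge="{f.charge}"'
            w(f"    <Feature {attrs}/>\n")
        w("  </FeatureList>\n")

    if doc.peptide_list:
        w("  <PeptideConsensusList>\n")
        for pc in doc.peptide_list:
            attrs = f'id="{_esc(pc.id)}"'
            if pc.sequence is not None:
                attrs += f' sequence="{_esc(pc.sequence)}"'
            if pc.modifications:
                attrs += f' modifications="{_esc(format_modifications(pc.modifications))}"'
            if pc.charge is not None:
                attrs += f' charge="{pc.charge}"'
            attrs += f' conflict="{"true" if pc.conflict_flag else "false"}"'
            inner = pc.feature_refs or pc.user_params
            if inner:
                w(f"    <PeptideConsensus {attrs}>\n")
                for fl_id in sorted(pc.feature_refs):
                    w(
                        f'      <FeatureRef featureList="{_esc(fl_id)}" '
                        f'feature="{_esc(pc.feature_refs[fl_id])}"/>\n'
                    )
                for up in pc.user_params:
                    w(f"      {_cv_xml(up, 'UserParam')}\n")
                w("    </PeptideConsensus>\n")
            else:
                w(f"    <PeptideConsensus {attrs}/>\n")
        w("  </PeptideConsensusList>\n")

    if doc.protein_list:
        w("  <ProteinList>\n")
        for pr in doc.protein_list:
            if pr.peptide_refs:
                w(f'    <Protein accession="{_esc(pr.accession)}">\n')
                for ref in pr.peptide_refs:
                    w(f'      <PeptideRef ref="{_esc(ref)}"/>\n')
                w("    </Protein>\n")
            else:
                w(f'    <Protein accession="{_esc(pr.accession)}"/>\n')
        w("  </ProteinList>\n")

    if doc.protein_groups:
        w("  <ProteinGroupList>\n")
        for pg in doc.protein_groups:
            w(f'    <ProteinGroup id="{_esc(pg.id)}" anchor="{_esc(pg.anchor_accession)}">\n')
            for acc in pg.member_accessions:
                w(f'      <Member accession="{_esc(acc)}"/>\n')
            for ref in pg.peptide_refs:
                w(f'      <PeptideRef ref="{_esc(ref)}"/>\n')
            w("    </ProteinGroup>\n")
        w("  </ProteinGroupList>\n")

    if doc.quant_layers:
        w("  <QuantLayerList>\n")
        for ql in doc.quant_layers:
            w(f'    <AssayQuantLayer id="{_esc(ql.id)}" level="{ql.level.value}">\n')
            w(f"      {_cv_xml(ql.data_type, 'DataType')}\n")
            w(f"      <ColumnRefs>{' '.join(_esc(c) for c in ql.column_refs)}</ColumnRefs>\n")
            w("      <DataMatrix>\n")
            for ref, row in zip(ql.row_refs, ql.values):
                cells = " ".join(_fmt_cell(c) for c in row)
                w(f'        <Row ref="{_esc(ref)}">{cells}</Row>\n')
            w("      </DataMatrix>\n")
            w("    </AssayQuantLayer>\n")
        w("  </QuantLayerList>\n")

    w("</MzQuantML>\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _esc(s: str) -> str:
    return (
        s.replace("&", "&amp;")
        .replace("<", "&lt;")
        .replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _cv_xml(cv: CvParam, tag: str) -> str:
    attrs = f'accession="{_esc(cv.accession)}" name="{_esc(cv.name)}"'
    if cv.value is not None:
        attrs += f' value="{_esc(cv.value)}"'
    if cv.unit is not None:
        attrs += f' unit="{_esc(cv.unit)}"'
    return f"<{tag} {attrs}/>"


# ---------------------------------------------------------------------------
# PSM reading

_TSV_COLUMNS = [
    "sequence",
    "modifications",
    "charge",
    "precursor_mz",
    "rt_seconds",
    "score",
    "spectrum_ref",
    "is_decoy",
]

_RT_ACCESSION = "MS:1000894"


def read_psms(path: Union[str, Path], dialect: str = "tsv") -> list[PSMRecord]:
    """Read a PSM list in the ``mzid_lite`` or ``tsv`` dialect.

    Only rank-1 matches are returned. PSMs without a retention time keep
    ``rt=None`` -- absence is representable because mapping is impossible
    without it and must fail loudly rather than silently match at rt 0.
    """
    if dialect == "tsv":
        return _read_psms_tsv(path)
    if dialect == "mzid_lite":
        return _read_psms_mzid(path)
    raise ValueError(f"unknown PSM dialect {dialect!r}")


def _read_psms_tsv(path: Union[str, Path]) -> list[PSMRecord]:
    with _open_maybe_gzip(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _TSV_COLUMNS if c not in header]
        if missing:
            raise MzqFormatError(
                f"{path}: PSM TSV missing mandatory column(s) {', '.join(missing)}"
            )
        idx = {c: header.index(c) for c in _TSV_COLUMNS}
        records: list[PSMRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise MzqFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            rt_s = fields[idx["rt_seconds"]]
            rec = PSMRecord(
                sequence=fields[idx["sequence"]],
                modifications=parse_modifications(fields[idx["modifications"]]),
                charge=int(fields[idx["charge"]]),
                precursor_mz=float(fields[idx["precursor_mz"]]),
                rt=float(rt_s) if rt_s else None,
                score=float(fields[idx["score"]]),
                spectrum_ref=fields[idx["spectrum_ref"]],
                is_decoy=fields[idx["is_decoy"]].lower() in ("true", "1", "yes"),
            )
            try:
                rec.validate()
            except MzqValidationError as exc:
                raise MzqFormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def _read_psms_mzid(path: Union[str, Path]) -> list[PSMRecord]:
    root = _parse_xml(path)
    records: list[PSMRecord] = []
    for result in root.iter("SpectrumIdentificationResult"):
        rt: Optional[float] = None
        for cv in result.iterfind("cvParam"):
            if cv.get("accession") == _RT_ACCESSION:
                rt = float(cv.get("value", "nan"))
                if cv.get("unitName", "second").startswith("minute"):
                    rt *= 60.0
                if math.isnan(rt):
                    rt = None
        spectrum_ref = result.get("spectrumID", "")
        for item in result.iterfind("SpectrumIdentificationItem"):
            if item.get("rank", "1") != "1":
                continue
            mods = [
                (
                    int(m.get("location", "0")),
                    float(m.get("monoisotopicMassDelta"))
                    if m.get("monoisotopicMassDelta") is not None
                    else m.get("name", ""),
                )
                for m in item.iterfind("Modification")
            ]
            rec = PSMRecord(
                sequence=_req(item, "peptideSequence", path),
                modifications=mods,
                charge=int(item.get("chargeState", "1")),
                precursor_mz=float(_req(item, "experimentalMassToCharge", path)),
                rt=rt,
                score=float(item.get("score", "0")),
                spectrum_ref=spectrum_ref,
                is_decoy=item.get("isDecoy", "false") == "true",
            )
            try:
                rec.validate()
            except MzqValidationError as exc:
                raise MzqFormatError(f"{path}: {exc}") from exc
            records.append(rec)
    return records
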