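"""In-memory document model for the mzq-lite dialect.

The model mirrors the structures of the mzQuantML standard that matter for
post-processing label-free LC-MS quantification: assays (one quantified
run/sample each), study variables (groups of replicate assays), per-run
feature lists with m/z x retention-time coordinates, run-aligned
``PeptideConsensus`` elements, a protein list mapping peptides to
accessions, derived protein groups, and quant layers -- labelled numeric
matrices (rows = entities, columns = assays) typed by a PSI-MS controlled
vocabulary term.

Missing values are three-way: a finite number, ``NaN`` (a computed
not-a-number), and ``Null`` (a value never measured). The distinction is
preserved on disk and matters downstream: normalisation ignores both for
factor estimation but retains them, protein inference replaces both with
zero, and the ANOVA routine turns a row containing either into a NaN
p-value. ``Null`` is the :data:`NULL` singleton; ``NaN`` is an ordinary
float nan.

Retention time is always stored in seconds.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union


class MzqError(Exception):
    """Base class for all mzqpost errors."""


class MzqValidationError(MzqError):
    """A document or element violates a model invariant."""


class DanglingReferenceError(MzqValidationError):
    """A cross-reference does not resolve within the document."""


class LayerLookupError(MzqError):
    """Zero or multiple quant layers matched a (level, accession) query."""


class _Null:
    """Singleton marker for a never-measured ('Null') cell."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "Null"

    def __reduce__(self):
        return (_Null, ())


#: The unique Null cell value, distinct from float('nan') and from 0.
NULL = _Null()

#: A quant-matrix cell: finite float, nan, or NULL.
Cell = Union[float, _Null]


def is_null(x: Cell) -> bool:
    return x is NULL or isinstance(x, _Null)


def is_nan(x: Cell) -> bool:
    return isinstance(x, float) and math.isnan(x)


def is_missing(x: Cell) -> bool:
    """True for Null or NaN (but not for zero)."""
    return is_null(x) or is_nan(x)


def cells_equal(a: Cell, b: Cell) -> bool:
    """Cell equality with Null==Null and NaN==NaN."""
    if is_null(a) or is_null(b):
        return is_null(a) and is_null(b)
    if is_nan(a) or is_nan(b):
        return is_nan(a) and is_nan(b)
    return a == b


_CV_ACCESSION_RE = re.compile(r"^[A-Za-z]+:\d+$")


class Level(str, Enum):
    """Entity level of a quant layer."""

    feature = "feature"
    peptide = "peptide"
    protein = "protein"
    protein_group = "protein_group"


class Mode(str, Enum):
    """Quantification technique of the document."""

    ms1_label_based = "ms1_label_based"
    ms2_tag_based = "ms2_tag_based"
    label_free = "label_free"
    spectral_counting = "spectral_counting"
    srm = "srm"


@dataclass
class CvParam:
    """A controlled-vocabulary (or user) parameter.

    ``accession`` is a PSI-MS style ``PREFIX:digits`` identifier, or the
    empty string for a free-text user param.
    """

    accession: str
    name: str
    value: Optional[str] = None
    unit: Optional[str] = None

    def validate(self) -> None:
        if self.accession and not _CV_ACCESSION_RE.match(self.accession):
            raise MzqValidationError(
                f"CV accession {self.accession!r} does not match PREFIX:digits"
            )
        if not self.name:
            raise MzqValidationError("CV param name must be non-empty")


@dataclass
class Assay:
    id: str
    name: str = ""
    raw_file_ref: str = ""

    def validate(self) -> None:
        if not self.id:
            raise MzqValidationError("Assay id must be non-empty")


@dataclass
class StudyVariable:
    id: str
    name: str = ""
    assay_refs: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not self.id:
            raise MzqValidationError("StudyVariable id must be non-empty")
        if not self.assay_refs:
            raise MzqValidationError(
                f"StudyVariable {self.id!r} has no assay_refs"
            )


@dataclass
class Feature:
    """A quantified 2-D LC-MS signal at (m/z, retention time)."""

    id: str
    mz: float
    rt: float
    rt_window: Optional[tuple[float, float]] = None
    charge: Optional[int] = None

    def validate(self) -> None:
        if not self.id:
            raise MzqValidationError("Feature id must be non-empty")
        if not self.mz > 0:
            raise MzqValidationError(f"Feature {self.id!r}: mz must be > 0")
        if self.rt < 0:
            raise MzqValidationError(f"Feature {self.id!r}: rt must be >= 0")
        if self.rt_window is not None:
            start, end = self.rt_window
            if start > end:
                raise MzqValidationError(
                    f"Feature {self.id!r}: rt window start {start} > end {end}"
                )
            if not (start <= self.rt <= end):
                raise MzqValidationError(
                    f"Feature {self.id!r}: rt {self.rt} outside window"
                )
        if self.charge is not None and self.charge < 1:
            raise MzqValidationError(f"Feature {self.id!r}: charge must be >= 1")


@dataclass
class FeatureList:
    """All features detected in one raw file."""

    id: str
    raw_file_ref: str
    features: list[Feature] = field(default_factory=list)

    def validate(self) -> None:
        if not self.id:
            raise MzqValidationError("FeatureList id must be non-empty")
        seen: set[str] = set()
        for f in self.features:
            f.validate()
            if f.id in seen:
                raise MzqValidationError(
                    f"FeatureList {self.id!r}: duplicate feature id {f.id!r}"
                )
            seen.add(f.id)


#: One modification: (position, mass delta in Da) or (position, name).
Modification = tuple[int, Union[float, str]]


def format_modifications(mods: list[Modification]) -> str:
    """Canonical text form, e.g. ``'3:15.9949;7:Oxidation'``."""
    return ";".join(f"{pos}:{delta}" for pos, delta in sorted(mods, key=lambda m: (m[0], str(m[1]))))


def parse_modifications(text: str) -> list[Modification]:
    mods: list[Modification] = []
    if not text:
        return mods
    for part in text.split(";"):
        pos_s, _, delta_s = part.partition(":")
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise MzqValidationError(f"bad modification position in {part!r}") from exc
        try:
            delta: Union[float, str] = float(delta_s)
        except ValueError:
            delta = delta_s
        mods.append((pos, delta))
    return mods


@dataclass
class PeptideConsensus:
    """A peptide aligned across runs, linking at most one feature per run.

    ``feature_refs`` maps feature-list id -> feature id. A consensus with
    no ``sequence`` is unidentified; ``conflict_flag`` marks disagreement
    between the identifications carried by the referenced features, and
    the losing candidates are kept in ``user_params``.
    """

    id: str
    sequence: Optional[str] = None
    modifications: list[Modification] = field(default_factory=list)
    charge: Optional[int] = None
    feature_refs: dict[str, str] = field(default_factory=dict)
    conflict_flag: bool = False
    user_params: list[CvParam] = field(default_factory=list)

    def validate(self) -> None:
        if not self.id:
            raise MzqValidationError("PeptideConsensus id must be non-empty")
        if self.sequence is None and self.conflict_flag:
            raise MzqValidationError(
                f"PeptideConsensus {self.id!r}: conflict_flag set without sequence"
            )

    def identity_key(self) -> tuple[Optional[str], str]:
        """Equality of identifications: (sequence, canonical modification string)."""
        return (self.sequence, format_modifications(self.modifications))


@dataclass
class ProteinRecord:
    accession: str
    peptide_refs: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not self.accession:
            raise MzqValidationError("Protein accession must be non-empty")


@dataclass
class ProteinGroup:
    """A set of indistinguishable/subsumed protein accessions.

    The anchor is the representative ("group leader") accession, flagged
    with the CV term "anchor protein" on output.
    """

    id: str
    member_accessions: list[str]
    anchor_accession: str
    peptide_refs: list[str]

    def validate(self) -> None:
        if not self.member_accessions:
            raise MzqValidationError(f"ProteinGroup {self.id!r}: no members")
        if self.anchor_accession not in self.member_accessions:
            raise MzqValidationError(
                f"ProteinGroup {self.id!r}: anchor {self.anchor_accession!r} "
                "not among members"
            )
        if not self.peptide_refs:
            raise MzqValidationError(f"ProteinGroup {self.id!r}: no peptides")


@dataclass
class QuantLayer:
    """A labelled matrix of quantitative values at one entity level.

    ``column_refs`` is the ordered list of assay ids; an empty list means
    a single unnamed column (used for p-value layers). ``row_refs`` are
    entity ids of the stated ``level``. ``data_type`` is the CV term
    identifying what the numbers are; its accession is the lookup key and
    must be unique among layers of the same level.
    """

    id: str
    level: Level
    data_type: CvParam
    column_refs: list[str]
    row_refs: list[str]
    values: list[list[Cell]]

    @property
    def n_columns(self) -> int:
        return len(self.column_refs) if self.column_refs else 1

    def validate(self) -> None:
        if not self.id:
            raise MzqValidationError("QuantLayer id must be non-empty")
        self.data_type.validate()
        if len(self.values) != len(self.row_refs):
            raise MzqValidationError(
                f"QuantLayer {self.id!r}: {len(self.row_refs)} row refs but "
                f"{len(self.values)} matrix rows"
            )
        ncol = self.n_columns
        for ref, row in zip(self.row_refs, self.values):
            if len(row) != ncol:
                raise MzqValidationError(
                    f"QuantLayer {self.id!r}: row {ref!r} has {len(row)} cells, "
                    f"expected {ncol}"
                )

    def column_index(self, assay_id: str) -> int:
        try:
            return self.column_refs.index(assay_id)
        except ValueError as exc:
            raise DanglingReferenceError(
                f"assay {assay_id!r} is not a column of layer {self.id!r}"
            ) from exc

    def row_index(self, entity_id: str) -> int:
        try:
            return self.row_refs.index(entity_id)
        except ValueError as exc:
            raise DanglingReferenceError(
                f"row {entity_id!r} not in layer {self.id!r}"
            ) from exc


@dataclass
class Software:
    name: str
    version: str
    params: list[CvParam] = field(default_factory=list)


@dataclass
class PSMRecord:
    """One rank-1 peptide-spectrum match with mapping coordinates.

    ``rt`` may be None: identification software does not always carry the
    retention time, and its absence must be representable (mapping onto
    features is then impossible and is reported as such, rather than
    silently treating the RT as zero).
    """

    sequence: str
    modifications: list[Modification] = field(default_factory=list)
    charge: int = 1
    precursor_mz: float = 0.0
    rt: Optional[float] = None
    score: float = 0.0
    spectrum_ref: str = ""
    is_decoy: bool = False

    def validate(self) -> None:
        if not self.sequence:
            raise MzqValidationError("PSM sequence must be non-empty")
        if not self.precursor_mz > 0:
            raise MzqValidationError(
                f"PSM {self.spectrum_ref!r}: precursor_mz must be > 0"
            )
        if self.charge < 1:
            raise MzqValidationError(f"PSM {self.spectrum_ref!r}: charge must be >= 1")

    def identity_key(self) -> tuple[str, str]:
        return (self.sequence, format_modifications(self.modifications))


@dataclass
class QuantDocument:
    """A complete mzq-lite document."""

    assays: list[Assay] = field(default_factory=list)
    study_variables: list[StudyVariable] = field(default_factory=list)
    feature_lists: list[FeatureList] = field(default_factory=list)
    peptide_list: list[PeptideConsensus] = field(default_factory=list)
    protein_list: list[ProteinRecord] = field(default_factory=list)
    protein_groups: list[ProteinGroup] = field(default_factory=list)
    quant_layers: list[QuantLayer] = field(default_factory=list)
    software: list[Software] = field(default_factory=list)
    mode: Mode = Mode.label_free

    # -- lookups ---------------------------------------------------------

    def assay_ids(self) -> list[str]:
        return [a.id for a in self.assays]

    def get_assay(self, assay_id: str) -> Assay:
        for a in self.assays:
            if a.id == assay_id:
                return a
        raise DanglingReferenceError(f"assay {assay_id!r} not in document")

    def get_peptide(self, pep_id: str) -> PeptideConsensus:
        for p in self.peptide_list:
            if p.id == pep_id:
                return p
        raise DanglingReferenceError(f"peptide consensus {pep_id!r} not in document")

    def get_feature_list(self, fl_id: str) -> FeatureList:
        for fl in self.feature_lists:
            if fl.id == fl_id:
                return fl
        raise DanglingReferenceError(f"feature list {fl_id!r} not in document")

    def entity_ids(self, level: Level) -> set[str]:
        if level == Level.feature:
            return {f.id for fl in self.feature_lists for f in fl.features}
        if level == Level.peptide:
            return {p.id for p in self.peptide_list}
        if level == Level.protein:
            return {p.accession for p in self.protein_list}
        return {g.id for g in self.protein_groups}

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Check every model invariant; raise on the first violation."""
        _check_unique([a.id for a in self.assays], "assay id")
        for a in self.assays:
            a.validate()
        assay_ids = set(self.assay_ids())

        _check_unique([sv.id for sv in self.study_variables], "study variable id")
        for sv in self.study_variables:
            sv.validate()
            for ref in sv.assay_refs:
                if ref not in assay_ids:
                    raise DanglingReferenceError(
                        f"study variable {sv.id!r} references unknown assay {ref!r}"
                    )

        _check_unique([fl.id for fl in self.feature_lists], "feature list id")
        _check_unique(
            [fl.raw_file_ref for fl in self.feature_lists],
            "feature list raw_file_ref",
        )
        for fl in self.feature_lists:
            fl.validate()
        features_by_list = {
            fl.id: {f.id for f in fl.features} for fl in self.feature_lists
        }

        _check_unique([p.id for p in self.peptide_list], "peptide consensus id")
        for pep in self.peptide_list:
            pep.validate()
            for fl_id, f_id in pep.feature_refs.items():
                if fl_id not in features_by_list:
                    raise DanglingReferenceError(
                        f"peptide {pep.id!r} references unknown feature list {fl_id!r}"
                    )
                if f_id not in features_by_list[fl_id]:
                    raise DanglingReferenceError(
                        f"peptide {pep.id!r} references unknown feature {f_id!r} "
                        f"in list {fl_id!r}"
                    )
        pep_ids = {p.id for p in self.peptide_list}

        _check_unique([p.accession for p in self.protein_list], "protein accession")
        for prot in self.protein_list:
            prot.validate()
            for ref in prot.peptide_refs:
                if ref not in pep_ids:
                    raise DanglingReferenceError(
                        f"protein {prot.accession!r} references unknown peptide {ref!r}"
                    )
        accessions = {p.accession for p in self.protein_list}

        _check_unique([g.id for g in self.protein_groups], "protein group id")
        for grp in self.protein_groups:
            grp.validate()
            for acc in grp.member_accessions:
                if acc not in accessions:
                    raise DanglingReferenceError(
                        f"protein group {grp.id!r} member {acc!r} not in protein list"
                    )
            for ref in grp.peptide_refs:
                if ref not in pep_ids:
                    raise DanglingReferenceError(
                        f"protein group {grp.id!r} references unknown peptide {ref!r}"
                    )

        _check_unique([q.id for q in self.quant_layers], "quant layer id")
        seen_keys: set[tuple[Level, str]] = set()
        for layer in self.quant_layers:
            layer.validate()
            key = (layer.level, layer.data_type.accession)
            if key in seen_keys:
                raise MzqValidationError(
                    f"duplicate quant layer data type {layer.data_type.accession!r} "
                    f"at level {layer.level.value}"
                )
            seen_keys.add(key)
            for col in layer.column_refs:
                if col not in assay_ids:
                    raise DanglingReferenceError(
                        f"quant layer {layer.id!r} column {col!r} is not an assay"
                    )
            valid_rows = self.entity_ids(layer.level)
            for ref in layer.row_refs:
                if ref not in valid_rows:
                    raise DanglingReferenceError(
                        f"quant layer {layer.id!r} row {ref!r} is not a "
                        f"{layer.level.value} entity"
                    )


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise MzqValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


def get_quant_layer(doc: QuantDocument, level: Level, accession: str) -> QuantLayer:
    """Return the unique quant layer at ``level`` with the given CV accession.

    Raises :class:`LayerLookupError` when zero or several layers match.
    """
    level = Level(level)
    matches = [
        q
        for q in doc.quant_layers
        if q.level == level and q.data_type.accession == accession
    ]
    if len(matches) != 1:
        raise LayerLookupError(
            f"{len(matches)} quant layers at level {level.value!r} with "
            f"accession {accession!r} (expected exactly 1)"
        )
    return matches[0]


# -- structural equality (NaN- and Null-aware) ---------------------------


def layers_equal(a: QuantLayer, b: QuantLayer) -> bool:
    if (
        a.id != b.id
        or a.level != b.level
        or a.data_type != b.data_type
        or a.column_refs != b.column_refs
        or a.row_refs != b.row_refs
        or len(a.values) != len(b.values)
    ):
        return False
    for ra, rb in zip(a.values, b.values):
        if len(ra) != len(rb) or not all(cells_equal(x, y) for x, y in zip(ra, rb)):
            return False
    return True


def documents_equal(a: QuantDocument, b: QuantDocument) -> bool:
    """Field-by-field equality treating NaN cells as equal to NaN."""
    if (
        a.assays != b.assays
        or a.study_variables != b.study_variables
        or a.feature_lists != b.feature_lists
        or a.peptide_list != b.peptide_list
        or a.protein_list != b.protein_list
        or a.protein_groups != b.protein_groups
        or a.software != b.software
        or a.mode != b.mode
        or len(a.quant_layers) != len(b.quant_layers)
    ):
        return False
    return all(layers_equal(x, y) for x, y in zip(a.quant_layers, b.quant_layers))
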