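"""Protein grouping and peptide-to-protein abundance aggregation.

Shared (degenerate) peptides make protein-level quantification ambiguous,
so proteins are grouped before aggregation:

* a peptide mapping to a single accession is **unique**;
* a peptide mapping to several accessions of which at least two have
  their own unique peptides is **conflicted** and is dropped from
  quantification entirely;
* every other multi-protein peptide is **common** (it maps within one
  same-set or sub-set group).

Groups are seeded from the proteins carrying unique peptides and from
maximal same-set classes (proteins with identical peptide sets, none
unique); proteins whose peptide set is contained in another's are merged
into the superset's group. Each group gets an anchor ("group leader")
protein: the single member of a singleton group, the first (lexicographic)
member of a same-set group, or the member with the most peptides in a
sub-set group.

Aggregation applies sum, mean or median over each group's peptide rows,
with Null/NaN replaced by zero first; for label-free data sum is the
recommended operator (for which the replacement is a no-op).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from statistics import median

from .model import (
    Cell,
    CvParam,
    Level,
    MzqError,
    ProteinGroup,
    ProteinRecord,
    QuantDocument,
    QuantLayer,
    get_quant_layer,
    is_missing,
)

__all__ = [
    "PeptideClass",
    "PeptideKlass",
    "InferenceParams",
    "classify_peptides",
    "build_protein_groups",
    "select_anchor",
    "infer_protein_abundance",
    "ANCHOR_PROTEIN_PARAM",
]

log = logging.getLogger(__name__)

ANCHOR_PROTEIN_PARAM = CvParam("MS:1001591", "anchor protein")


class PeptideKlass(str, Enum):
    unique = "unique"
    common = "common"
    conflicted = "conflicted"


@dataclass(frozen=True)
class PeptideClass:
    peptide_ref: str
    klass: PeptideKlass
    protein_accessions: tuple[str, ...]


@dataclass
class InferenceParams:
    """Which peptide layers to aggregate into which group layers.

    ``input_accessions``/``output_accessions`` are parallel lists of
    (accession, name) pairs -- typically the raw and the normalised
    peptide layer. ``operator`` is sum, mean or median.
    """

    input_accessions: list[tuple[str, str]]
    output_accessions: list[tuple[str, str]]
    operator: str = "sum"

    def __post_init__(self) -> None:
        if len(self.input_accessions) != len(self.output_accessions):
            raise ValueError("input and output accession lists differ in length")
        if self.operator not in ("sum", "mean", "median"):
            raise ValueError(f"unknown operator {self.operator!r}")


def _peptide_to_proteins(protein_list: list[ProteinRecord]) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    for prot in protein_list:
        for pep in prot.peptide_refs:
            mapping.setdefault(pep, set()).add(prot.accession)
    return mapping


def classify_peptides(protein_list: list[ProteinRecord]) -> list[PeptideClass]:
    """Partition all referenced peptides into unique/common/conflicted.

    Let U be the set of proteins owning at least one unique peptide. A
    multi-protein peptide is conflicted iff two or more of its proteins
    are in U; with at most one such protein it is common.
    """
    pep2prot = _peptide_to_proteins(protein_list)
    proteins_with_unique = {
        next(iter(accs)) for accs in pep2prot.values() if len(accs) == 1
    }
    classes = []
    for pep in sorted(pep2prot):
        accs = pep2prot[pep]
        if len(accs) == 1:
            klass = PeptideKlass.unique
        elif len(accs & proteins_with_unique) >= 2:
            klass = PeptideKlass.conflicted
        else:
            klass = PeptideKlass.common
        classes.append(PeptideClass(pep, klass, tuple(sorted(accs))))
    return classes


def build_protein_groups(
    protein_list: list[ProteinRecord],
    classes: list[PeptideClass] | None = None,
) -> list[ProteinGroup]:
    """Build same-set/sub-set protein groups over non-conflicted peptides.

    Conflicted peptides are removed before any set comparison, so one
    consistent peptide universe underlies classification, grouping and
    quantification. Proteins left with no peptides are dropped. Group ids
    are ``PG_<n>`` with n following lexicographic anchor order.
    """
    if classes is None:
        classes = classify_peptides(protein_list)
    conflicted = {c.peptide_ref for c in classes if c.klass == PeptideKlass.conflicted}
    pepsets: dict[str, frozenset[str]] = {}
    for prot in protein_list:
        s = frozenset(p for p in prot.peptide_refs if p not in conflicted)
        if s:
            pepsets[prot.accession] = s

    # same-set classes: proteins with identical surviving peptide sets
    by_set: dict[frozenset[str], list[str]] = {}
    for acc in sorted(pepsets):
        by_set.setdefault(pepsets[acc], []).append(acc)

    sets = list(by_set)
    # merge each non-maximal set into its superset's class
    maximal = [s for s in sets if not any(s < t for t in sets)]
    members: dict[frozenset[str], list[str]] = {
        s: list(by_set[s]) for s in maximal
    }
    for s in sets:
        if s in members:
            continue
        supersets = [t for t in maximal if s < t]
        # deterministic choice when several maximal supersets exist
        target = min(supersets, key=lambda t: sorted(by_set[t])[0])
        members[target].extend(by_set[s])

    groups: list[ProteinGroup] = []
    drafts = []
    for s, accs in members.items():
        accs = sorted(accs)
        anchor = _anchor_for(accs, pepsets)
        drafts.append((anchor, accs, s))
    drafts.sort(key=lambda d: d[0])

    # a common peptide can sit in two disjoint groups when neither group
    # has a unique-peptide protein; keep the partition by assigning it to
    # the group with the smallest anchor
    claimed: set[str] = set()
    for n, (anchor, accs, s) in enumerate(drafts, start=1):
        peps = sorted(p for p in s if p not in claimed)
        claimed.update(peps)
        if not peps:
            continue
        groups.append(
            ProteinGroup(
                id=f"PG_{n}",
                member_accessions=accs,
                anchor_accession=anchor,
                peptide_refs=peps,
            )
        )
    # renumber after possible drops so ids stay dense
    for n, g in enumerate(groups, start=1):
        g.id = f"PG_{n}"
    return groups


def _anchor_for(accs: list[str], pepsets: dict[str, frozenset[str]]) -> str:
    """Most peptides wins; ties (incl. same-set groups) break lexicographically."""
    return min(accs, key=lambda a: (-len(pepsets[a]), a))


def select_anchor(
    group: ProteinGroup, protein_list: list[ProteinRecord]
) -> str:
    """Anchor of an existing group, recomputed from the protein list."""
    classes = classify_peptides(protein_list)
    conflicted = {c.peptide_ref for c in classes if c.klass == PeptideKlass.conflicted}
    pepsets = {
        p.accession: frozenset(x for x in p.peptide_refs if x not in conflicted)
        for p in protein_list
        if p.accession in group.member_accessions
    }
    return _anchor_for(sorted(group.member_accessions), pepsets)


def _aggregate(values: list[float], operator: str) -> float:
    if operator == "sum":
        return float(sum(values))
    if operator == "mean":
        return float(sum(values) / len(values))
    return float(median(values))


def infer_protein_abundance(
    doc: QuantDocument, params: InferenceParams
) -> QuantDocument:
    """Attach protein groups and group-level quant layers to the document.

    For every input peptide layer, emits a protein-group layer where a
    group's value in an assay is the operator applied over its peptides'
    values with Null/NaN replaced by zero. Peptides without a sequence
    (unidentified consensus rows) never participate. Modifies the
    document in place and returns it.
    """
    identified = {p.id for p in doc.peptide_list if p.sequence is not None}
    usable_protein_list = [
        ProteinRecord(
            accession=p.accession,
            peptide_refs=[r for r in p.peptide_refs if r in identified],
        )
        for p in doc.protein_list
    ]
    usable_protein_list = [p for p in usable_protein_list if p.peptide_refs]
    groups = build_protein_groups(usable_protein_list)
    doc.protein_groups = groups
    if params.operator != "sum":
        log.warning(
            "operator %r selected; for label-free quantification the sum "
            "operation is strongly recommended",
            params.operator,
        )

    for (in_acc, _in_name), (out_acc, out_name) in zip(
        params.input_accessions, params.output_accessions
    ):
        layer = get_quant_layer(doc, Level.peptide, in_acc)
        for q in doc.quant_layers:
            if q.level == Level.protein_group and q.data_type.accession == out_acc:
                raise MzqError(
                    f"output layer accession {out_acc!r} already present at "
                    "protein_group level"
                )
        row_index = {r: i for i, r in enumerate(layer.row_refs)}
        values: list[list[Cell]] = []
        row_refs: list[str] = []
        for g in groups:
            peps = [p for p in g.peptide_refs if p in row_index]
            if not peps:
                continue
            row: list[Cell] = []
            for j in range(layer.n_columns):
                vals = [
                    0.0
                    if is_missing(layer.values[row_index[p]][j])
                    else float(layer.values[row_index[p]][j])
                    for p in peps
                ]
                row.append(_aggregate(vals, params.operator))
            values.append(row)
            row_refs.append(g.id)
        out = QuantLayer(
            id=f"pg_{out_acc.replace(':', '_')}",
            level=Level.protein_group,
            data_type=CvParam(out_acc, out_name),
            column_refs=list(layer.column_refs),
            row_refs=row_refs,
            values=values,
        )
        doc.quant_layers.append(out)
        log.info(
            "inferred %d protein groups from %d peptides (layer %s -> %s)",
            len(row_refs),
            len(layer.row_refs),
            in_acc,
            out_acc,
        )
    doc.validate()
    return doc
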