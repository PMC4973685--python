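"""Export of a quant document to mzTab-lite and CSV.

The mzTab exporter targets the tabular shape of mzTab 1.0 -- an MTD
metadata block, then PRH/PRT protein(-group) rows and PEH/PEP peptide
rows with one ``*_abundance_assay[n]`` column per assay per quant layer.
It aims at structural fidelity (every value of the selected layers
appears exactly once, missing values as the literal ``null``), not
repository-grade metadata completeness; unknown metadata slots are filled
with ``null`` per the mzTab convention. The CSV exporter writes one quant
layer as an RFC-4180 table: an id column plus one column per assay.
Both outputs are deterministic byte-for-byte.
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass, field

from .model import (
    Cell,
    Level,
    MzqError,
    QuantDocument,
    QuantLayer,
    get_quant_layer,
    is_missing,
)

__all__ = ["ExportOptions", "export_mztab", "export_csv"]


@dataclass
class ExportOptions:
    include_levels: set[Level] = field(
        default_factory=lambda: {Level.peptide, Level.protein_group}
    )
    layer_accessions: list[str] | None = None

    def __post_init__(self) -> None:
        self.include_levels = {Level(lv) for lv in self.include_levels}
        if not self.include_levels:
            raise ValueError("include_levels must be non-empty")


def _cell_token(cell: Cell) -> str:
    if is_missing(cell):
        return "null"
    return repr(float(cell))


def _layers_at(doc: QuantDocument, level: Level, opts: ExportOptions) -> list[QuantLayer]:
    layers = [
        q
        for q in doc.quant_layers
        if q.level == level and q.column_refs  # per-assay layers only
    ]
    if opts.layer_accessions is not None:
        layers = [q for q in layers if q.data_type.accession in opts.layer_accessions]
    return layers


def export_mztab(doc: QuantDocument, opts: ExportOptions | None = None) -> str:
    """Render the document as an mzTab-lite string."""
    opts = opts or ExportOptions()
    lines: list[str] = []
    add = lines.append
    add("MTD\tmzTab-version\t1.0.0")
    add("MTD\tmzTab-mode\tSummary")
    add("MTD\tmzTab-type\tQuantification")
    add(f"MTD\tdescription\tExported by mzqpost ({doc.mode.value})")
    for i, a in enumerate(doc.assays, start=1):
        add(f"MTD\tassay[{i}]-description\t{a.name or a.id}")
        add(f"MTD\tassay[{i}]-ms_run_ref\t{a.raw_file_ref or 'null'}")
    for i, sv in enumerate(doc.study_variables, start=1):
        add(f"MTD\tstudy_variable[{i}]-description\t{sv.name or sv.id}")
        refs = ",".join(sv.assay_refs)
        add(f"MTD\tstudy_variable[{i}]-assay_refs\t{refs}")
    add("")

    assay_order = doc.assay_ids()

    if Level.protein_group in opts.include_levels or Level.protein in opts.include_levels:
        level = (
            Level.protein_group
            if Level.protein_group in opts.include_levels
            else Level.protein
        )
        layers = _layers_at(doc, level, opts)
        if not layers:
            raise MzqError(f"no exportable quant layer at level {level.value}")
        pvalue_layers = [
            q for q in doc.quant_layers if q.level == level and not q.column_refs
        ]
        header = ["PRH", "accession", "description", "ambiguity_members", "anchor_protein"]
        for q in layers:
            for n, _a in enumerate(assay_order, start=1):
                header.append(f"protein_abundance_assay[{n}]:{q.data_type.accession}")
        for q in pvalue_layers:
            header.append(f"opt_global_{q.data_type.accession.replace(':', '_')}")
        add("\t".join(header))
        groups = {g.id: g for g in doc.protein_groups}
        row_ids = layers[0].row_refs
        for rid in row_ids:
            g = groups.get(rid)
            acc = g.anchor_accession if g else rid
            members = ",".join(g.member_accessions) if g else rid
            row = ["PRT", acc, "null", members, acc if g else "null"]
            for q in layers:
                i = q.row_refs.index(rid) if rid in q.row_refs else None
                cols = {a: j for j, a in enumerate(q.column_refs)}
                for a in assay_order:
                    if i is None or a not in cols:
                        row.append("null")
                    else:
                        row.append(_cell_token(q.values[i][cols[a]]))
            for q in pvalue_layers:
                if rid in q.row_refs:
                    row.append(_cell_token(q.values[q.row_refs.index(rid)][0]))
                else:
                    row.append("null")
            add("\t".join(row))
        add("")

    if Level.peptide in opts.include_levels:
        layers = _layers_at(doc, Level.peptide, opts)
        if not layers:
            raise MzqError("no exportable quant layer at level peptide")
        header = ["PEH", "sequence", "accession", "charge", "modifications"]
        for q in layers:
            for n, _a in enumerate(assay_order, start=1):
                header.append(f"peptide_abundance_assay[{n}]:{q.data_type.accession}")
        add("\t".join(header))
        pep_prot: dict[str, list[str]] = {}
        for prot in doc.protein_list:
            for ref in prot.peptide_refs:
                pep_prot.setdefault(ref, []).append(prot.accession)
        peptides = {p.id: p for p in doc.peptide_list}
        for rid in layers[0].row_refs:
            pep = peptides.get(rid)
            row = [
                "PEP",
                (pep.sequence if pep and pep.sequence else "null"),
                ",".join(sorted(pep_prot.get(rid, []))) or "null",
                str(pep.charge) if pep and pep.charge is not None else "null",
                "null",
            ]
            for q in layers:
                i = q.row_refs.index(rid) if rid in q.row_refs else None
                cols = {a: j for j, a in enumerate(q.column_refs)}
                for a in assay_order:
                    if i is None or a not in cols:
                        row.append("null")
                    else:
                        row.append(_cell_token(q.values[i][cols[a]]))
            add("\t".join(row))
        add("")

    return "\n".join(lines) + "\n"


def export_csv(doc: QuantDocument, level: Level, accession: str) -> str:
    """Render one quant layer as an RFC-4180 CSV string.

    Header: entity id column (named after the layer's data type) plus one
    column per assay (assay names); one row per entity. Missing cells are
    the bare tokens ``null``/``NaN`` so the matrix reparses exactly.
    """
    layer = get_quant_layer(doc, Level(level), accession)
    buf = _stdio.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    names = {a.id: (a.name or a.id) for a in doc.assays}
    header = [layer.data_type.name] + [names[c] for c in layer.column_refs]
    writer.writerow(header)
    for rid, row in zip(layer.row_refs, layer.values):
        writer.writerow([rid] + [_csv_token(c) for c in row])
    return buf.getvalue()


def _csv_token(cell: Cell) -> str:
    from .model import is_nan, is_null

    if is_null(cell):
        return "null"
    if is_nan(cell):
        return "NaN"
    return repr(float(cell))
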