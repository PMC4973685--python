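"""Per-row one-way ANOVA across assay groups and Bonferroni helper.

Differential expression between two or more conditions (groups of
replicate assays) is tested row by row with a fixed-effects one-way ANOVA
on log10 abundances. Missing-value conventions: a row with any Null or
NaN in the tested columns gets p = NaN; zeros are replaced by 0.5 before
the log (the conventional pseudo-value, since log(0) is undefined);
negative values are invalid at this stage and also yield NaN. The p-value
is the upper tail of the F distribution with (k-1, N-k) degrees of
freedom. The choice of log base is immaterial to F and p.

The Bonferroni helper divides the significance threshold by the number of
tests; it is applied by the caller, not inside the ANOVA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .model import (
    Cell,
    CvParam,
    Level,
    MzqError,
    QuantDocument,
    QuantLayer,
    get_quant_layer,
    is_missing,
)

__all__ = [
    "GroupSpec",
    "GroupSpecError",
    "parse_group_spec",
    "anova_pvalues",
    "attach_pvalue_layer",
    "bonferroni_threshold",
]

log = logging.getLogger(__name__)

ZERO_REPLACEMENT = 0.5


class GroupSpecError(MzqError):
    """Malformed or unresolvable assay-grouping specification."""


@dataclass(frozen=True)
class GroupSpec:
    """Assay ids grouped into conditions."""

    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise GroupSpecError("need at least two groups of assays")
        seen: set[str] = set()
        for g in self.groups:
            if not g:
                raise GroupSpecError("empty assay group")
            for a in g:
                if a in seen:
                    raise GroupSpecError(f"assay {a!r} appears in two groups")
                seen.add(a)

    @property
    def all_assays(self) -> list[str]:
        return [a for g in self.groups for a in g]


def parse_group_spec(spec: str, known_assays: list[str] | None = None) -> GroupSpec:
    """Parse ``"a1,a2;a3,a4"``: commas separate assays, semicolons groups."""
    if not spec.strip():
        raise GroupSpecError("empty group specification")
    groups = []
    for part in spec.split(";"):
        assays = tuple(a.strip() for a in part.split(",") if a.strip())
        groups.append(assays)
    gs = GroupSpec(tuple(groups))
    if known_assays is not None:
        unknown = [a for a in gs.all_assays if a not in known_assays]
        if unknown:
            raise GroupSpecError(f"unknown assay id(s): {', '.join(unknown)}")
    return gs


def _row_pvalue(groups: list[list[float]]) -> float:
    """One-way fixed-effects ANOVA p on already-logged values."""
    k = len(groups)
    all_vals = [v for g in groups for v in g]
    n = len(all_vals)
    if n - k <= 0:
        return float("nan")
    grand = sum(all_vals) / n
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    dfb, dfw = k - 1, n - k
    if ssw == 0.0:
        return 1.0 if ssb == 0.0 else 0.0
    f = (ssb / dfb) / (ssw / dfw)
    return float(_sps.f.sf(f, dfb, dfw))


def anova_pvalues(layer: QuantLayer, spec: GroupSpec, log_base: float = 10.0) -> list[float]:
    """Per-row ANOVA p-values over the spec'd assay columns.

    Cells of assays outside the spec are ignored. Returns one p in [0, 1]
    (or NaN) per row of the layer.
    """
    col_idx = {}
    for g in spec.groups:
        for a in g:
            col_idx[a] = layer.column_index(a)
    n = sum(len(g) for g in spec.groups)
    k = len(spec.groups)
    if n - k <= 0:
        log.warning(
            "insufficient replicates for ANOVA (%d observations, %d groups); "
            "all p-values set to NaN",
            n,
            k,
        )
        return [float("nan")] * len(layer.row_refs)
    lb = math.log(log_base)
    pvals: list[float] = []
    n_invalid = 0
    for row in layer.values:
        cells = [[row[col_idx[a]] for a in g] for g in spec.groups]
        flat = [c for g in cells for c in g]
        if any(is_missing(c) for c in flat):
            pvals.append(float("nan"))
            continue
        if any(c < 0 for c in flat):
            n_invalid += 1
            pvals.append(float("nan"))
            continue
        logged = [
            [math.log(ZERO_REPLACEMENT if c == 0 else float(c)) / lb for c in g]
            for g in cells
        ]
        pvals.append(_row_pvalue(logged))
    if n_invalid:
        log.warning("%d row(s) contained negative abundances; p set to NaN", n_invalid)
    return pvals


def attach_pvalue_layer(
    doc: QuantDocument,
    layer_accession: str,
    spec: GroupSpec,
    out_accession: str,
    out_name: str = "ANOVA p-value",
    level: Level = Level.protein_group,
) -> QuantDocument:
    """Compute per-row p-values and append them as a one-column layer.

    Only protein and protein-group layers are eligible. The p-value layer
    has an empty ``column_refs`` list (a single unnamed column), mirroring
    a global, per-row quantity rather than a per-assay one.
    """
    level = Level(level)
    if level not in (Level.protein, Level.protein_group):
        raise MzqError(
            f"ANOVA applies to protein or protein_group layers, not {level.value}"
        )
    layer = get_quant_layer(doc, level, layer_accession)
    for q in doc.quant_layers:
        if q.level == level and q.data_type.accession == out_accession:
            raise MzqError(
                f"output accession {out_accession!r} already present at level "
                f"{level.value}"
            )
    unknown = [a for a in spec.all_assays if a not in layer.column_refs]
    if unknown:
        raise GroupSpecError(f"unknown assay id(s): {', '.join(unknown)}")
    pvals = anova_pvalues(layer, spec)
    out = QuantLayer(
        id=f"pv_{out_accession.replace(':', '_')}",
        level=level,
        data_type=CvParam(out_accession, out_name),
        column_refs=[],
        row_refs=list(layer.row_refs),
        values=[[p] for p in pvals],
    )
    doc.quant_layers.append(out)
    log.info(
        "ANOVA on layer %s: %d rows, %d groups -> %s",
        layer_accession,
        len(layer.row_refs),
        len(spec.groups),
        out_accession,
    )
    doc.validate()
    return doc


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be a positive integer")
    return alpha / n_tests
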