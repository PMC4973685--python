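"""Global intensity normalisation against a reference run.

Label-free LC-MS runs differ in overall signal (loading, ionisation,
instrument drift). Under the assumption that most peptides are not
differentially abundant, the log ratios between a reference run and any
other run should centre on zero; the systematic offset from zero is the
run's scaling error. Per non-reference assay ``A_n`` the routine:

1. forms ``log10(A_r / A_n)`` over all usable rows (``Null``, ``NaN`` and
   values <= 0 are excluded from estimation but retained in the data);
2. computes the median and the median absolute deviation (MAD), scaled by
   1.4826 to estimate sigma under normality;
3. removes rows outside the 95% interval ``median +/- 2*sigma`` and
   repeats 2-3 until no row is removed (or MAD hits 0, or an iteration
   cap);
4. anti-logs the mean of the surviving ratios to obtain the scaling
   factor, which multiplies every value of ``A_n``.

If no reference is given, each assay is tried as the reference in turn;
the assay whose scaling-factor vector has the standard deviation closest
to the median of all such deviations is chosen -- a reference that is
central rather than an outlier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    Cell,
    CvParam,
    Level,
    MzqError,
    QuantDocument,
    QuantLayer,
    get_quant_layer,
    is_missing,
    is_null,
)

__all__ = [
    "NormalisationParams",
    "ScalingResult",
    "IterationTrace",
    "DegenerateInputError",
    "compute_scaling_factor",
    "select_reference_assay",
    "normalise_layer",
]

log = logging.getLogger(__name__)

MAD_SIGMA_COEFF = 1.4826  # MAD -> sigma under normality
CI_SIGMA_MULTIPLE = 2.0  # ~95% interval half-width in sigmas
MAX_ITERATIONS = 100


class DegenerateInputError(MzqError):
    """Too few usable rows to estimate a scaling factor."""


@dataclass
class NormalisationParams:
    """Configuration of one normalisation run.

    ``input_accession``/``output_accession`` are the CV accessions naming
    the raw and normalised quant layers; ``decoy_tag`` excludes rows whose
    id or accession contains it from factor estimation; with
    ``processing_level='identified_only'`` (peptide level) unidentified
    consensus rows are likewise excluded. Excluded rows still appear,
    scaled, in the output layer.
    """

    level: Level = Level.peptide
    input_accession: str = "MS:1001893"
    input_name: str = "raw abundance"
    output_accession: str = "MS:1001891"
    output_name: str = "normalised abundance"
    reference_assay: Optional[str] = None
    decoy_tag: Optional[str] = None
    processing_level: str = "identified_only"

    def __post_init__(self) -> None:
        self.level = Level(self.level)
        if self.input_accession == self.output_accession:
            raise ValueError("input and output layer accessions must differ")
        if self.processing_level not in ("identified_only", "all"):
            raise ValueError(f"bad processing_level {self.processing_level!r}")


@dataclass
class IterationTrace:
    median_log_ratio: float
    mad: float
    sigma: float  # always MAD_SIGMA_COEFF * mad
    removed_row_ids: list[str]


@dataclass
class ScalingResult:
    reference_assay: str
    factors: dict[str, float] = field(default_factory=dict)
    traces: dict[str, list[IterationTrace]] = field(default_factory=dict)
    used_rows: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _usable_pairs(
    ref_values: list[Cell], target_values: list[Cell], row_ids: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Log10 ratios over rows where both cells are finite and positive."""
    ratios = []
    ids = []
    for r, t, rid in zip(ref_values, target_values, row_ids):
        if is_missing(r) or is_missing(t):
            continue
        if r <= 0 or t <= 0:
            continue
        ratios.append(math.log10(r / t))
        ids.append(rid)
    return np.asarray(ratios, dtype=float), ids


def compute_scaling_factor(
    ref_values: list[Cell],
    target_values: list[Cell],
    row_ids: Optional[list[str]] = None,
) -> tuple[float, list[IterationTrace], list[str]]:
    """Iterative MAD-filtered scaling factor for one assay pair.

    Returns ``(factor, trace, warnings)`` where ``factor = 10**mean`` of
    the log10(ref/target) ratios surviving the outlier loop. Rows where
    either value is Null, NaN or <= 0 are excluded up front. Raises
    :class:`DegenerateInputError` when fewer than two usable rows exist.
    """
    if len(ref_values) != len(target_values):
        raise ValueError("ref and target vectors differ in length")
    if row_ids is None:
        row_ids = [str(i) for i in range(len(ref_values))]
    ratios, ids = _usable_pairs(ref_values, target_values, row_ids)
    if ratios.size < 2:
        raise DegenerateInputError(
            f"only {ratios.size} usable row(s); scaling factor undefined"
        )
    trace: list[IterationTrace] = []
    warnings: list[str] = []
    for _ in range(MAX_ITERATIONS):
        med = float(np.median(ratios))
        mad = float(np.median(np.abs(ratios - med)))
        sigma = MAD_SIGMA_COEFF * mad
        keep = np.abs(ratios - med) <= CI_SIGMA_MULTIPLE * sigma
        removed = [i for i, k in zip(ids, keep) if not k]
        trace.append(IterationTrace(med, mad, sigma, removed))
        if mad == 0.0 or not removed:
            break
        ratios = ratios[keep]
        ids = [i for i, k in zip(ids, keep) if k]
        if ratios.size == 0:
            warnings.append("all rows removed as outliers; factor defaults to 1")
            return 1.0, trace, warnings
    factor = float(10.0 ** np.mean(ratios))
    return factor, trace, warnings


def _layer_estimation_rows(
    layer: QuantLayer,
    params: NormalisationParams,
    doc: Optional[QuantDocument] = None,
) -> list[int]:
    """Row indices entering factor estimation (decoys/unidentified out)."""
    identified: Optional[set[str]] = None
    if (
        doc is not None
        and params.level == Level.peptide
        and params.processing_level == "identified_only"
    ):
        identified = {p.id for p in doc.peptide_list if p.sequence is not None}
    rows = []
    for i, rid in enumerate(layer.row_refs):
        if params.decoy_tag and params.decoy_tag in rid:
            continue
        if identified is not None and rid not in identified:
            continue
        rows.append(i)
    return rows


def compute_scaling_result(
    layer: QuantLayer,
    reference: str,
    row_indices: Optional[list[int]] = None,
) -> ScalingResult:
    """Scaling factors of every assay column against ``reference``."""
    if row_indices is None:
        row_indices = list(range(len(layer.row_refs)))
    ref_col = layer.column_index(reference)
    res = ScalingResult(reference_assay=reference)
    ids = [layer.row_refs[i] for i in row_indices]
    ref_vals = [layer.values[i][ref_col] for i in row_indices]
    for j, assay_id in enumerate(layer.column_refs):
        if assay_id == reference:
            res.factors[assay_id] = 1.0
            res.traces[assay_id] = []
            res.used_rows[assay_id] = len(
                _usable_pairs(ref_vals, ref_vals, ids)[0]
            )
            continue
        target_vals = [layer.values[i][j] for i in row_indices]
        factor, trace, warns = compute_scaling_factor(ref_vals, target_vals, ids)
        res.factors[assay_id] = factor
        res.traces[assay_id] = trace
        n_usable = len(_usable_pairs(ref_vals, target_vals, ids)[1])
        res.used_rows[assay_id] = n_usable - sum(len(t.removed_row_ids) for t in trace)
        res.warnings.extend(f"{assay_id}: {wmsg}" for wmsg in warns)
    return res


def select_reference_assay(
    layer: QuantLayer,
    params: NormalisationParams,
    row_indices: Optional[list[int]] = None,
) -> str:
    """Pick the reference run automatically (or honour the user's choice).

    Every assay is used as the candidate reference; for each, the vector
    of per-assay scaling factors is computed and its sample standard
    deviation taken. The assay whose stdev is closest to the median stdev
    wins (ties: lowest assay id), i.e. a run central among the candidates.
    """
    if params.reference_assay is not None:
        layer.column_index(params.reference_assay)  # must resolve
        return params.reference_assay
    if len(layer.column_refs) < 2:
        raise DegenerateInputError("reference selection needs >= 2 assays")
    if row_indices is None:
        row_indices = _layer_estimation_rows(layer, params)
    candidates = sorted(layer.column_refs)
    stdevs: dict[str, float] = {}
    for cand in candidates:
        res = compute_scaling_result(layer, cand, row_indices)
        vec = np.array([res.factors[a] for a in layer.column_refs])
        stdevs[cand] = float(np.std(vec, ddof=1))
    median_sd = float(np.median(list(stdevs.values())))
    # distances can be mathematically equal (e.g. the two middle stdevs of
    # an even-length list); compare with a relative tolerance so the
    # lowest-id tie-break is not decided by rounding noise
    dists = {a: abs(stdevs[a] - median_sd) for a in candidates}
    best = min(dists.values())
    tol = 1e-9 * max(best, 1.0) + 1e-12
    return min(a for a in candidates if dists[a] <= best + tol)


def normalise_layer(
    doc: QuantDocument, params: NormalisationParams
) -> tuple[QuantDocument, ScalingResult]:
    """Append a normalised quant layer to the document.

    Factor estimation runs on the estimation row set (no decoys; at
    peptide level optionally identified rows only); the output layer
    covers ALL rows, with each assay column multiplied by its factor.
    Null, NaN and zero cells pass through unchanged. The input layer is
    kept; returns the document and the :class:`ScalingResult`.
    """
    layer = get_quant_layer(doc, params.level, params.input_accession)
    for q in doc.quant_layers:
        if q.level == params.level and q.data_type.accession == params.output_accession:
            raise MzqError(
                f"output layer accession {params.output_accession!r} already "
                f"present at level {params.level.value}"
            )
    rows = _layer_estimation_rows(layer, params, doc)
    reference = select_reference_assay(layer, params, rows)
    result = compute_scaling_result(layer, reference, rows)
    for msg in result.warnings:
        log.warning("normalisation: %s", msg)

    new_values: list[list[Cell]] = []
    factors = [result.factors[a] for a in layer.column_refs]
    for row in layer.values:
        new_row: list[Cell] = []
        for cell, f in zip(row, factors):
            if is_null(cell):
                new_row.append(cell)
            elif isinstance(cell, float) and math.isnan(cell):
                new_row.append(cell)
            elif cell == 0:
                new_row.append(0.0)
            else:
                new_row.append(f * cell)
        new_values.append(new_row)
    out = QuantLayer(
        id=f"{layer.id}_norm",
        level=layer.level,
        data_type=CvParam(params.output_accession, params.output_name),
        column_refs=list(layer.column_refs),
        row_refs=list(layer.row_refs),
        values=new_values,
    )
    doc.quant_layers.append(out)
    log.info(
        "normalised layer %s -> %s (%d rows x %d assays, reference %s)",
        params.input_accession,
        params.output_accession,
        len(out.row_refs),
        len(out.column_refs),
        reference,
    )
    doc.validate()
    return doc, result
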