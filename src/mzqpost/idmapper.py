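"""Mapping of PSM identifications onto quantified LC-MS features.

Quantification software (feature detection on the MS1 map) and
identification software (database search of MS2 spectra) are usually
different tools, so the identifications have to be transferred onto the
quantified features afterwards. The transfer runs in two steps:

1. per run, each rank-1 PSM is matched against the features of that run's
   feature list using an m/z tolerance and either the feature's reported
   retention-time window or, when only a centroid is present, a symmetric
   RT tolerance (defaults: +/-0.05 Da and +/-10 s);
2. identifications are propagated up to the run-aligned
   ``PeptideConsensus`` elements; when the referenced features disagree,
   the identification carried by the largest number of feature lists
   wins and the conflict is flagged with user params recording the losers.

A PSM that matches several features is assigned only to its best match
(smallest |dm/z|, then smallest |dRT| to the centroid, then lexicographic
feature id); a feature may accumulate several PSMs, of which the
best-scoring one provides the feature's identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    CvParam,
    FeatureList,
    MzqError,
    PSMRecord,
    QuantDocument,
    format_modifications,
)

__all__ = [
    "ToleranceWindow",
    "MappingReport",
    "MissingRetentionTimeError",
    "match_psms_to_features",
    "resolve_consensus_identifications",
    "map_identifications",
]

CONFLICT_PARAM_NAME = "conflicting identification"


class MissingRetentionTimeError(MzqError):
    """A PSM lacks a retention time, so feature mapping cannot run."""


@dataclass(frozen=True)
class ToleranceWindow:
    """Match tolerances: absolute m/z in Da, RT in seconds."""

    mz_tol: float = 0.05
    rt_tol: float = 10.0

    def __post_init__(self) -> None:
        if not (self.mz_tol > 0 and self.rt_tol > 0):
            raise ValueError("tolerances must be strictly positive")


@dataclass
class MappingReport:
    """Bookkeeping of one mapping run."""

    feature_assignments: dict[str, dict[str, list[PSMRecord]]] = field(
        default_factory=dict
    )  # feature-list id -> feature id -> PSMs
    consensus_identifications: dict[str, tuple[str, str]] = field(default_factory=dict)
    unmatched_psms: list[PSMRecord] = field(default_factory=list)
    conflicted_consensus_ids: list[str] = field(default_factory=list)

    @property
    def n_features_matched(self) -> int:
        return sum(len(m) for m in self.feature_assignments.values())

    @property
    def n_psms_unmatched(self) -> int:
        return len(self.unmatched_psms)

    @property
    def n_conflicts(self) -> int:
        return len(self.conflicted_consensus_ids)


def _psm_matches_feature(
    psm: PSMRecord, feature, tol: ToleranceWindow, require_charge_match: bool
) -> bool:
    if abs(psm.precursor_mz - feature.mz) > tol.mz_tol:
        return False
    if feature.rt_window is not None:
        start, end = feature.rt_window
        if not (start <= psm.rt <= end):
            return False
    elif abs(psm.rt - feature.rt) > tol.rt_tol:
        return False
    if (
        require_charge_match
        and feature.charge is not None
        and psm.charge is not None
        and feature.charge != psm.charge
    ):
        return False
    return True


def match_psms_to_features(
    psms: list[PSMRecord],
    flist: FeatureList,
    tol: ToleranceWindow = ToleranceWindow(),
    require_charge_match: bool = True,
    include_decoys: bool = False,
) -> dict[str, list[PSMRecord]]:
    """Assign each PSM to its single best-matching feature of one run.

    The match predicate: |precursor m/z - feature m/z| <= ``mz_tol``, RT
    inside the feature's reported window when one exists (else within
    ``rt_tol`` of the centroid), and equal charge when both sides carry
    one and ``require_charge_match`` is set. Among several matching
    features the PSM goes to the one with the smallest |dm/z|, ties broken
    by |dRT| to the centroid, then by feature id; the result is therefore
    independent of input ordering.

    Decoy PSMs are skipped unless ``include_decoys`` is set. Every PSM
    must carry a retention time; without RT values mapping is impossible
    (they must be recovered upstream from the spectrum files) and a
    :class:`MissingRetentionTimeError` is raised.
    """
    usable = [p for p in psms if include_decoys or not p.is_decoy]
    for p in usable:
        if p.rt is None:
            raise MissingRetentionTimeError(
                f"PSM {p.spectrum_ref!r} has no retention time; recover RT values "
                "from the source spectra (AddRetentionTimeToMzid-style "
                "preprocessing) before mapping"
            )
    assignments: dict[str, list[PSMRecord]] = {}
    for psm in usable:
        best = None
        best_key = None
        for feat in flist.features:
            if not _psm_matches_feature(psm, feat, tol, require_charge_match):
                continue
            key = (abs(psm.precursor_mz - feat.mz), abs(psm.rt - feat.rt), feat.id)
            if best_key is None or key < best_key:
                best, best_key = feat, key
        if best is not None:
            assignments.setdefault(best.id, []).append(psm)
    for lst in assignments.values():
        # stable per-feature order regardless of input order
        lst.sort(key=lambda p: (-p.score, p.spectrum_ref, p.sequence))
    return assignments


def _feature_identification(
    psms: list[PSMRecord], higher_score_better: bool
) -> PSMRecord:
    sign = -1.0 if higher_score_better else 1.0
    return min(psms, key=lambda p: (sign * p.score, p.sequence, p.spectrum_ref))


def resolve_consensus_identifications(
    doc: QuantDocument,
    feature_assignments: dict[str, dict[str, list[PSMRecord]]],
    higher_score_better: bool = True,
    report: MappingReport | None = None,
) -> QuantDocument:
    """Propagate per-feature identifications to ``PeptideConsensus`` elements.

    A consensus gets an identification when at least one of its referenced
    features has one. If features from different runs disagree, the
    identification seen in the most feature lists wins (ties: the
    lexicographically smallest (sequence, modification-string) pair) and
    the consensus is flagged as conflicted, with each losing candidate
    recorded as a user param. The document is modified in place and
    returned.
    """
    for pc in doc.peptide_list:
        # candidate identification per referencing feature list
        per_list: dict[str, tuple[str, str, list] ] = {}
        for fl_id, f_id in pc.feature_refs.items():
            psms = feature_assignments.get(fl_id, {}).get(f_id)
            if not psms:
                continue
            best = _feature_identification(psms, higher_score_better)
            per_list[fl_id] = (best.sequence, format_modifications(best.modifications), best.modifications)
        if not per_list:
            continue
        votes: dict[tuple[str, str], int] = {}
        mods_by_key: dict[tuple[str, str], list] = {}
        for seq, mod_str, mods in per_list.values():
            key = (seq, mod_str)
            votes[key] = votes.get(key, 0) + 1
            mods_by_key[key] = mods
        winner = min(votes, key=lambda k: (-votes[k], k))
        pc.sequence = winner[0]
        pc.modifications = list(mods_by_key[winner])
        if len(votes) > 1:
            pc.conflict_flag = True
            for key in sorted(k for k in votes if k != winner):
                pc.user_params.append(
                    CvParam(
                        accession="",
                        name=CONFLICT_PARAM_NAME,
                        value=f"{key[0]}|{key[1]}|lists={votes[key]}",
                    )
                )
            if report is not None:
                report.conflicted_consensus_ids.append(pc.id)
        if report is not None:
            report.consensus_identifications[pc.id] = winner
    return doc


def map_identifications(
    doc: QuantDocument,
    psms_by_feature_list: dict[str, list[PSMRecord]],
    tol: ToleranceWindow = ToleranceWindow(),
    require_charge_match: bool = True,
    include_decoys: bool = False,
    higher_score_better: bool = True,
) -> tuple[QuantDocument, MappingReport]:
    """Run both mapping steps over a whole document.

    ``psms_by_feature_list`` pairs each feature-list id with the PSMs of
    the corresponding run (one identification file per raw file).
    """
    report = MappingReport()
    for fl_id, psms in psms_by_feature_list.items():
        flist = doc.get_feature_list(fl_id)
        assigned = match_psms_to_features(
            psms, flist, tol, require_charge_match, include_decoys
        )
        report.feature_assignments[fl_id] = assigned
        matched = {id(p) for lst in assigned.values() for p in lst}
        report.unmatched_psms.extend(
            p
            for p in psms
            if id(p) not in matched and (include_decoys or not p.is_decoy)
        )
    resolve_consensus_identifications(
        doc, report.feature_assignments, higher_score_better, report
    )
    return doc, report
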