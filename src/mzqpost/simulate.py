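"""Synthetic label-free studies with known ground truth.

The generator emulates the statistical structure the post-processing
routines assume: most peptide rows are non-differential, so between any
two runs the log10 ratios centre on zero apart from a per-run scaling
factor; measurement noise is multiplicative log-normal; a configurable
fraction of proteins is differentially expressed by a known fold change
in one condition; cells go missing completely at random; a small fraction
of rows is perturbed into outliers that robust normalisation should
reject. The peptide-protein graph plants unique peptides, same-set/
sub-set companion proteins (no unique peptides of their own) and,
optionally, conflicted edges between proteins that both own unique
peptides -- so the expected classification and grouping are known
exactly.

Assay ``a``'s column is divided by its true factor ``s_a``; normalising
against a reference with ``s_r = 1`` should therefore recover ``s_a``.

One pseudo-random generator is seeded once per run; everything is drawn
from it, so a fixed seed reproduces the study byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .model import (
    NULL,
    Assay,
    Cell,
    CvParam,
    Feature,
    FeatureList,
    Level,
    PeptideConsensus,
    ProteinRecord,
    PSMRecord,
    QuantDocument,
    QuantLayer,
    Software,
    StudyVariable,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PSMSet",
    "generate_study",
    "generate_psm_set",
    "RAW_PEPTIDE_ACCESSION",
]

RAW_PEPTIDE_ACCESSION = "MS:1001893"
RAW_PEPTIDE_NAME = "peptide raw abundance"

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    """Study-design knobs of the generator.

    Defaults describe a modest label-free experiment: 100 proteins of
    4-10 quantified peptides, two conditions of three replicate runs,
    run-level scaling spread of 0.15 log10 units, 10% of proteins
    differential at 2-fold, log-normal measurement noise of 0.1 log10
    units per peptide cell, 5% missing cells and 2% outlier rows; feature
    coordinates span typical LC-MS ranges. Peptide abundances are
    hierarchical: a protein-level loading (log10 sd 0.8 across proteins)
    plus a per-peptide ionisation-efficiency offset (log10 sd 0.15), so
    peptides of one protein are correlated, as in real LC-MS data.
    """

    n_proteins: int = 100
    peptides_per_protein: tuple[int, int] = (4, 10)
    shared_peptide_fraction: float = 0.1
    conflicted_edge_fraction: float = 0.0
    n_assays: int = 6
    groups: tuple[int, ...] = (3, 3)
    true_scaling_factors: Optional[tuple[float, ...]] = None
    scaling_log_sd: float = 0.15
    de_fraction: float = 0.1
    de_fold_change: float = 2.0
    noise_log_sd: float = 0.1
    protein_log_mean: float = 6.0
    protein_log_sd: float = 0.8
    ionization_log_sd: float = 0.15
    missing_rate: float = 0.05
    outlier_row_fraction: float = 0.02
    mz_range: tuple[float, float] = (300.0, 1500.0)
    rt_range: tuple[float, float] = (600.0, 3600.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "shared_peptide_fraction",
            "conflicted_edge_fraction",
            "de_fraction",
            "missing_rate",
            "outlier_row_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_assays < 2:
            raise ValueError("n_assays must be >= 2")
        if sum(self.groups) != self.n_assays:
            raise ValueError("group sizes must sum to n_assays")
        if self.true_scaling_factors is not None and len(
            self.true_scaling_factors
        ) != self.n_assays:
            raise ValueError("true_scaling_factors must have one entry per assay")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("bad peptides_per_protein range")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    """Everything the generator planted, for comparing recoveries."""

    true_factors: dict[str, float] = field(default_factory=dict)
    peptide_proteins: dict[str, tuple[str, ...]] = field(default_factory=dict)
    peptide_labels: dict[str, str] = field(default_factory=dict)
    groups: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=list
    )  # (anchor, members, peptides)
    de_proteins: dict[str, float] = field(default_factory=dict)
    de_peptides: set[str] = field(default_factory=set)
    missing_cells: list[tuple[str, str]] = field(default_factory=list)
    outlier_peptides: set[str] = field(default_factory=set)

    def to_json_dict(self) -> dict:
        return {
            "true_factors": self.true_factors,
            "peptide_proteins": {k: list(v) for k, v in self.peptide_proteins.items()},
            "peptide_labels": self.peptide_labels,
            "groups": [
                {"anchor": a, "members": list(m), "peptides": list(p)}
                for a, m, p in self.groups
            ],
            "de_proteins": self.de_proteins,
            "de_peptides": sorted(self.de_peptides),
            "missing_cells": [list(c) for c in self.missing_cells],
            "outlier_peptides": sorted(self.outlier_peptides),
        }


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AMINO_ACIDS, size=length))


def generate_study(config: SimulationConfig) -> tuple[QuantDocument, GroundTruth]:
    """Generate one study and its ground truth; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    # ---- peptide-protein graph ----------------------------------------
    lo, hi = config.peptides_per_protein
    protein_peps: dict[str, list[str]] = {}
    pep_seqs: dict[str, str] = {}
    pep_creator: dict[str, str] = {}
    k = 0
    seed_accessions = [f"P{i:04d}" for i in range(config.n_proteins)]
    for acc in seed_accessions:
        n_pep = int(rng.integers(lo, hi + 1))
        peps = []
        for _ in range(n_pep):
            pid = f"pep_{k:05d}"
            k += 1
            peps.append(pid)
            pep_seqs[pid] = _random_sequence(rng, int(rng.integers(8, 21)))
            pep_creator[pid] = acc
        protein_peps[acc] = peps

    # subset companions: share part of a seed's peptides, no unique ones
    n_companion = int(round(config.shared_peptide_fraction * config.n_proteins))
    eligible = [a for a in seed_accessions if len(protein_peps[a]) >= 2]
    companion_of: dict[str, str] = {}
    if n_companion and eligible:
        hosts = rng.choice(eligible, size=min(n_companion, len(eligible)), replace=False)
        for host in (str(h) for h in hosts):
            comp = f"{host}s"  # sorts after its host
            n_share = int(rng.integers(1, len(protein_peps[host])))
            shared = list(rng.choice(protein_peps[host], size=n_share, replace=False))
            protein_peps[comp] = sorted(shared)
            companion_of[comp] = host

    # conflicted edges between two unique-owning seed proteins
    n_peptides = k
    n_conflict = int(round(config.conflicted_edge_fraction * n_peptides))
    conflicted: set[str] = set()
    if n_conflict:
        shared_peps = {p for comp in companion_of for p in protein_peps[comp]}
        donors = [
            a
            for a in seed_accessions
            if sum(1 for p in protein_peps[a] if p not in shared_peps) >= 2
        ]
        for _ in range(n_conflict):
            if len(donors) < 2:
                break
            a, b = (str(x) for x in rng.choice(donors, size=2, replace=False))
            cands = [
                p
                for p in protein_peps[a]
                if p not in shared_peps
                and p not in conflicted
                and sum(
                    1
                    for q in protein_peps[a]
                    if q not in shared_peps and q not in conflicted
                )
                >= 2
            ]
            if not cands:
                continue
            p = str(rng.choice(cands))
            protein_peps[b] = protein_peps[b] + [p]
            conflicted.add(p)

    pep2prot: dict[str, list[str]] = {}
    for acc, peps in protein_peps.items():
        for p in peps:
            pep2prot.setdefault(p, []).append(acc)
    for p, accs in pep2prot.items():
        truth.peptide_proteins[p] = tuple(sorted(accs))
        if p in conflicted:
            truth.peptide_labels[p] = "conflicted"
        elif len(accs) == 1:
            truth.peptide_labels[p] = "unique"
        else:
            truth.peptide_labels[p] = "common"

    # planted groups: each seed protein plus its companions
    host_groups: dict[str, list[str]] = {a: [a] for a in seed_accessions}
    for comp, host in companion_of.items():
        host_groups[host].append(comp)
    for host in sorted(host_groups):
        members = tuple(sorted(host_groups[host]))
        peps = tuple(
            sorted(p for p in protein_peps[host] if p not in conflicted)
        )
        if peps:
            truth.groups.append((host, members, peps))

    # ---- abundances ----------------------------------------------------
    assay_ids = [f"ass_{j}" for j in range(config.n_assays)]
    if config.true_scaling_factors is not None:
        factors = [float(f) for f in config.true_scaling_factors]
    else:
        factors = [
            float(f)
            for f in 10.0 ** rng.normal(0.0, config.scaling_log_sd, config.n_assays)
        ]
    truth.true_factors = dict(zip(assay_ids, factors))

    group_assays: list[list[str]] = []
    start = 0
    for size in config.groups:
        group_assays.append(assay_ids[start : start + size])
        start += size

    n_de = int(round(config.de_fraction * config.n_proteins))
    de_accs = (
        list(rng.choice(seed_accessions, size=n_de, replace=False)) if n_de else []
    )
    for acc in de_accs:
        truth.de_proteins[acc] = config.de_fold_change
        truth.de_peptides.update(protein_peps[acc])

    pep_ids = sorted(pep_seqs)
    # hierarchical abundances: shared protein loading + per-peptide
    # ionisation efficiency, so sibling peptides are correlated
    protein_level = dict(
        zip(
            seed_accessions,
            rng.normal(config.protein_log_mean, config.protein_log_sd,
                       len(seed_accessions)),
        )
    )
    offsets = rng.normal(0.0, config.ionization_log_sd, len(pep_ids))
    base = 10.0 ** np.array(
        [protein_level[pep_creator[p]] + o for p, o in zip(pep_ids, offsets)]
    )
    de_mask = np.array([p in truth.de_peptides for p in pep_ids])
    de_cols = np.array([a in set(group_assays[1]) for a in assay_ids])

    noise = 10.0 ** rng.normal(0.0, config.noise_log_sd, (len(pep_ids), config.n_assays))
    values = base[:, None] * noise
    if de_mask.any() and de_cols.any():
        values[np.ix_(de_mask, de_cols)] *= config.de_fold_change
    values = values / np.asarray(factors)[None, :]

    n_outlier = int(round(config.outlier_row_fraction * len(pep_ids)))
    if n_outlier:
        rows = rng.choice(len(pep_ids), size=n_outlier, replace=False)
        for i in rows:
            j = int(rng.integers(config.n_assays))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            values[i, j] *= 10.0 ** (sign * rng.uniform(1.0, 2.0))
            truth.outlier_peptides.add(pep_ids[i])

    missing = rng.random(values.shape) < config.missing_rate

    # ---- document ------------------------------------------------------
    doc = QuantDocument()
    doc.software.append(Software("mzqpost.simulate", "0.1.0"))
    for j, aid in enumerate(assay_ids):
        doc.assays.append(Assay(id=aid, name=f"run {j}", raw_file_ref=f"run_{j}.raw"))
    for gi, assays in enumerate(group_assays, start=1):
        doc.study_variables.append(
            StudyVariable(id=f"sv_{gi}", name=f"condition_{gi}", assay_refs=list(assays))
        )

    pep_mz = dict(zip(pep_ids, rng.uniform(*config.mz_range, len(pep_ids))))
    pep_rt = dict(zip(pep_ids, rng.uniform(*config.rt_range, len(pep_ids))))
    pep_charge = dict(
        zip(pep_ids, (int(c) for c in rng.integers(2, 4, len(pep_ids))))
    )
    fl_ids = [f"fl_{j}" for j in range(config.n_assays)]
    for j, (aid, fl_id) in enumerate(zip(assay_ids, fl_ids)):
        features = []
        for p in pep_ids:
            rt = float(pep_rt[p] + rng.normal(0.0, 3.0))
            rt = max(rt, 0.0)
            features.append(
                Feature(
                    id=f"ft_{j}_{p}",
                    mz=float(pep_mz[p]),
                    rt=rt,
                    rt_window=(rt - 15.0, rt + 15.0),
                    charge=pep_charge[p],
                )
            )
        doc.feature_lists.append(
            FeatureList(id=fl_id, raw_file_ref=f"run_{j}.raw", features=features)
        )

    for p in pep_ids:
        doc.peptide_list.append(
            PeptideConsensus(
                id=p,
                sequence=pep_seqs[p],
                charge=pep_charge[p],
                feature_refs={fl: f"ft_{j}_{p}" for j, fl in enumerate(fl_ids)},
            )
        )

    for acc in sorted(protein_peps):
        doc.protein_list.append(
            ProteinRecord(accession=acc, peptide_refs=sorted(protein_peps[acc]))
        )

    matrix: list[list[Cell]] = []
    for i, p in enumerate(pep_ids):
        row: list[Cell] = []
        for j, aid in enumerate(assay_ids):
            if missing[i, j]:
                row.append(NULL)
                truth.missing_cells.append((p, aid))
            else:
                row.append(float(values[i, j]))
        matrix.append(row)
    doc.quant_layers.append(
        QuantLayer(
            id="ql_raw_pep",
            level=Level.peptide,
            data_type=CvParam(RAW_PEPTIDE_ACCESSION, RAW_PEPTIDE_NAME),
            column_refs=list(assay_ids),
            row_refs=list(pep_ids),
            values=matrix,
        )
    )
    doc.validate()
    return doc, truth


class PSMSet(NamedTuple):
    """PSMs per feature list plus the planted feature assignment."""

    psms_by_feature_list: dict[str, list[PSMRecord]]
    true_assignments: dict[str, dict[str, str]]  # fl id -> spectrum_ref -> feature id
    conflicted_consensus: set[str]

    @property
    def all_psms(self) -> list[PSMRecord]:
        return [p for lst in self.psms_by_feature_list.values() for p in lst]


def generate_psm_set(
    doc: QuantDocument,
    id_rate: float = 1.0,
    decoy_rate: float = 0.0,
    jitter_mz: float = 0.0,
    jitter_rt: float = 0.0,
    seed: int = 0,
    conflict_rate: float = 0.0,
) -> PSMSet:
    """Emit PSMs at (possibly jittered) feature coordinates.

    Per feature list, each feature of an identified consensus yields one
    rank-1 PSM with probability ``id_rate``, at the feature's coordinates
    plus uniform jitter of half-width ``jitter_mz`` Da / ``jitter_rt`` s.
    ``decoy_rate`` adds that fraction of decoy PSMs at random coordinates.
    ``conflict_rate`` swaps, for that fraction of consensus elements, the
    sequence reported in one feature list -- planting identification
    conflicts whose count downstream resolution should reproduce.
    """
    rng = np.random.default_rng(seed)
    feat_owner: dict[tuple[str, str], PeptideConsensus] = {}
    for pc in doc.peptide_list:
        for fl_id, f_id in pc.feature_refs.items():
            feat_owner[(fl_id, f_id)] = pc

    identified = [pc for pc in doc.peptide_list if pc.sequence is not None]
    n_conf = int(round(conflict_rate * len(identified)))
    conflict_peps: dict[str, str] = {}
    if n_conf:
        chosen_idx = rng.choice(len(identified), size=n_conf, replace=False)
        for pc in (identified[int(i)] for i in chosen_idx):
            fls = sorted(pc.feature_refs)
            if len(fls) < 2:
                continue
            conflict_peps[pc.id] = fls[0]  # this list reports a wrong sequence

    out: dict[str, list[PSMRecord]] = {}
    assignments: dict[str, dict[str, str]] = {}
    planted_conflicts: set[str] = set()
    for fl in doc.feature_lists:
        psms: list[PSMRecord] = []
        amap: dict[str, str] = {}
        for feat in fl.features:
            pc = feat_owner.get((fl.id, feat.id))
            if pc is None or pc.sequence is None:
                continue
            if rng.random() > id_rate:
                continue
            seq = pc.sequence
            if conflict_peps.get(pc.id) == fl.id:
                seq = pc.sequence[::-1]  # reversed sequence = disagreement
                planted_conflicts.add(pc.id)
            ref = f"spec_{fl.id}_{feat.id}"
            psms.append(
                PSMRecord(
                    sequence=seq,
                    modifications=list(pc.modifications),
                    charge=feat.charge or 2,
                    precursor_mz=float(
                        feat.mz + rng.uniform(-jitter_mz, jitter_mz)
                    ) if jitter_mz else float(feat.mz),
                    rt=float(feat.rt + rng.uniform(-jitter_rt, jitter_rt))
                    if jitter_rt
                    else float(feat.rt),
                    score=float(rng.uniform(20.0, 60.0)),
                    spectrum_ref=ref,
                    is_decoy=False,
                )
            )
            amap[ref] = feat.id
        n_decoys = int(round(decoy_rate * len(psms)))
        for d in range(n_decoys):
            psms.append(
                PSMRecord(
                    sequence=_random_sequence(rng, 12),
                    charge=2,
                    precursor_mz=float(rng.uniform(300.0, 1500.0)),
                    rt=float(rng.uniform(0.0, 4000.0)),
                    score=float(rng.uniform(1.0, 15.0)),
                    spectrum_ref=f"decoy_{fl.id}_{d}",
                    is_decoy=True,
                )
            )
        out[fl.id] = psms
        assignments[fl.id] = amap
    return PSMSet(out, assignments, planted_conflicts)
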