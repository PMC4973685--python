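"""Peptide classification and protein grouping against a set-algebra oracle."""

import math
import random

import pytest

from mzqpost.inference import (
    InferenceParams,
    PeptideKlass,
    build_protein_groups,
    classify_peptides,
    infer_protein_abundance,
    select_anchor,
)
from mzqpost.model import (
    NULL,
    Level,
    PeptideConsensus,
    ProteinRecord,
    get_quant_layer,
    is_missing,
)
from mzqpost.simulate import SimulationConfig, generate_study

from conftest import assay_matrix_doc


def proteins(mapping):
    return [ProteinRecord(accession=a, peptide_refs=sorted(p)) for a, p in sorted(mapping.items())]


# ---------------------------------------------------------------------------
# independent set-algebra oracle


def oracle_classify(mapping):
    """Direct evaluation of the unique/common/conflicted definitions."""
    pep2prot = {}
    for acc, peps in mapping.items():
        for p in peps:
            pep2prot.setdefault(p, set()).add(acc)
    unique_owner = {
        acc
        for p, accs in pep2prot.items()
        if len(accs) == 1
        for acc in accs
    }
    labels = {}
    for p, accs in pep2prot.items():
        if len(accs) == 1:
            labels[p] = "unique"
        elif len(accs & unique_owner) >= 2:
            labels[p] = "conflicted"
        else:
            labels[p] = "common"
    return labels


def oracle_groups(mapping):
    """Exhaustive enumeration of same-set/sub-set relations.

    Works directly on peptide sets (conflicted peptides removed): each
    maximal set seeds a group holding its exact owners plus every protein
    whose set is strictly contained in it (a strict subset of several
    maximal sets joins the one whose exact owners contain the smallest
    accession); a peptide claimed by several groups goes to the one with
    the smallest anchor. Returns {anchor: (members, peptides)}.
    """
    labels = oracle_classify(mapping)
    conflicted = {p for p, l in labels.items() if l == "conflicted"}
    pepsets = {
        acc: frozenset(p for p in peps if p not in conflicted)
        for acc, peps in mapping.items()
    }
    pepsets = {a: s for a, s in pepsets.items() if s}
    all_sets = set(pepsets.values())
    maximal = [s for s in all_sets if not any(s < t for t in all_sets)]

    def exact_owners(s):
        return sorted(a for a, t in pepsets.items() if t == s)

    members_of = {s: list(exact_owners(s)) for s in maximal}
    for a, t in pepsets.items():
        if t in members_of:
            continue
        supers = [u for u in maximal if t < u]
        home = min(supers, key=lambda u: exact_owners(u)[0])
        members_of[home].append(a)

    drafts = []
    for s, members in members_of.items():
        anchor = min(members, key=lambda a: (-len(pepsets[a]), a))
        drafts.append((anchor, tuple(sorted(members)), s))
    drafts.sort()

    claimed = set()
    final = {}
    for anchor, members, s in drafts:
        peps = tuple(sorted(p for p in s if p not in claimed))
        claimed.update(peps)
        if peps:
            final[anchor] = (members, peps)
    return final


def groups_as_dict(groups):
    return {
        g.anchor_accession: (tuple(g.member_accessions), tuple(g.peptide_refs))
        for g in groups
    }


class TestClassification:
    def test_shared_peptide_between_two_unique_owners_is_conflicted(self):
        mapping = {"A": {"p1", "p2"}, "B": {"p3", "p2"}}
        classes = {c.peptide_ref: c.klass for c in classify_peptides(proteins(mapping))}
        assert classes["p1"] == PeptideKlass.unique
        assert classes["p3"] == PeptideKlass.unique
        assert classes["p2"] == PeptideKlass.conflicted

    def test_no_unique_owner_means_common(self):
        mapping = {"A": {"p1", "p2"}, "B": {"p1", "p2"}}
        classes = {c.peptide_ref: c.klass for c in classify_peptides(proteins(mapping))}
        assert classes == {"p1": PeptideKlass.common, "p2": PeptideKlass.common}

    def test_single_unique_owner_keeps_shared_peptide_common(self):
        mapping = {"A": {"p1", "p2"}, "B": {"p2"}}
        classes = {c.peptide_ref: c.klass for c in classify_peptides(proteins(mapping))}
        assert classes["p1"] == PeptideKlass.unique
        assert classes["p2"] == PeptideKlass.common


class TestGrouping:
    def test_same_set_proteins_merge(self):
        # B carries an identical surviving peptide set to A
        mapping = {"A": {"p1", "p2"}, "B": {"p2"}, "C": {"p3"}}
        groups = build_protein_groups(proteins(mapping))
        got = groups_as_dict(groups)
        assert got == {
            "A": (("A", "B"), ("p1", "p2")),
            "C": (("C",), ("p3",)),
        }

    def test_subset_protein_merged_into_superset(self):
        mapping = {"A": {"p1", "p2"}, "B": {"p2"}}
        (g,) = build_protein_groups(proteins(mapping))
        assert g.member_accessions == ["A", "B"]
        assert g.anchor_accession == "A"

    def test_disjoint_proteins_stay_separate(self):
        mapping = {"A": {"p1"}, "B": {"p2"}}
        groups = build_protein_groups(proteins(mapping))
        assert len(groups) == 2

    def test_conflicted_peptides_in_no_group(self):
        mapping = {"A": {"p1", "p2"}, "B": {"p3", "p2"}}
        groups = build_protein_groups(proteins(mapping))
        all_peps = {p for g in groups for p in g.peptide_refs}
        assert "p2" not in all_peps

    def test_group_ids_follow_anchor_order(self):
        mapping = {"Z": {"p1"}, "A": {"p2"}}
        groups = build_protein_groups(proteins(mapping))
        assert [(g.id, g.anchor_accession) for g in groups] == [
            ("PG_1", "A"),
            ("PG_2", "Z"),
        ]

    @pytest.mark.parametrize("seed", range(60))
    def test_random_bipartite_graphs_match_oracle(self, seed):
        rng = random.Random(seed)
        n_prot = rng.randint(1, 8)
        n_pep = rng.randint(1, 15)
        accs = [f"P{i}" for i in range(n_prot)]
        mapping = {a: set() for a in accs}
        for j in range(n_pep):
            owners = rng.sample(accs, k=min(n_prot, 1 + int(rng.random() * rng.random() * 4)))
            for a in owners:
                mapping[a].add(f"p{j:02d}")
        mapping = {a: s for a, s in mapping.items() if s}
        if not mapping:
            pytest.skip("empty graph draw")
        got = groups_as_dict(build_protein_groups(proteins(mapping)))
        assert got == oracle_groups(mapping)

    def test_partition_property_on_random_graphs(self):
        rng = random.Random(123)
        for _ in range(40):
            accs = [f"P{i}" for i in range(rng.randint(2, 8))]
            mapping = {a: set() for a in accs}
            for j in range(rng.randint(2, 15)):
                for a in rng.sample(accs, k=rng.randint(1, min(3, len(accs)))):
                    mapping[a].add(f"p{j:02d}")
            mapping = {a: s for a, s in mapping.items() if s}
            protein_list = proteins(mapping)
            labels = {c.peptide_ref: c.klass for c in classify_peptides(protein_list)}
            groups = build_protein_groups(protein_list)
            seen = {}
            for g in groups:
                for p in g.peptide_refs:
                    assert p not in seen, "peptide in two groups"
                    seen[p] = g.id
            for p, kl in labels.items():
                if kl == PeptideKlass.conflicted:
                    assert p not in seen
                else:
                    assert p in seen


class TestAnchorSelection:
    def test_singleton_group_anchor(self):
        mapping = {"A": {"p1"}}
        (g,) = build_protein_groups(proteins(mapping))
        assert g.anchor_accession == "A"
        assert select_anchor(g, proteins(mapping)) == "A"

    def test_same_set_anchor_is_lexicographically_first(self):
        mapping = {"B": {"p1", "p2"}, "A": {"p1", "p2"}}
        (g,) = build_protein_groups(proteins(mapping))
        assert g.anchor_accession == "A"

    def test_subset_anchor_has_most_peptides(self):
        mapping = {"B": {"p1", "p2", "p3"}, "A": {"p1"}}
        (g,) = build_protein_groups(proteins(mapping))
        assert g.anchor_accession == "B"
        assert select_anchor(g, proteins(mapping)) == "B"


def _doc_with_proteins(values, mapping):
    doc = assay_matrix_doc(values, row_prefix="pep")
    doc.protein_list = [
        ProteinRecord(accession=a, peptide_refs=sorted(p))
        for a, p in sorted(mapping.items())
    ]
    return doc


PARAMS = InferenceParams(
    input_accessions=[("MS:1001893", "raw")],
    output_accessions=[("MS:1002518", "protein group raw")],
)


class TestAbundanceAggregation:
    def test_sum_of_two_peptides(self):
        doc = _doc_with_proteins([[2.0], [3.0]], {"A": {"pep0", "pep1"}})
        doc = infer_protein_abundance(doc, PARAMS)
        out = get_quant_layer(doc, Level.protein_group, "MS:1002518")
        assert out.values == [[5.0]]

    def test_null_replaced_by_zero_for_sum(self):
        doc = _doc_with_proteins(
            [[2.0], [NULL], [3.0]], {"A": {"pep0", "pep1", "pep2"}}
        )
        doc = infer_protein_abundance(doc, PARAMS)
        out = get_quant_layer(doc, Level.protein_group, "MS:1002518")
        assert out.values == [[5.0]]

    def test_null_counts_as_zero_for_mean(self):
        doc = _doc_with_proteins(
            [[2.0], [NULL], [4.0]], {"A": {"pep0", "pep1", "pep2"}}
        )
        params = InferenceParams(PARAMS.input_accessions, PARAMS.output_accessions, "mean")
        doc = infer_protein_abundance(doc, params)
        out = get_quant_layer(doc, Level.protein_group, "MS:1002518")
        assert out.values == [[2.0]]  # mean of {2, 0, 4}

    def test_median_operator(self):
        doc = _doc_with_proteins(
            [[1.0], [9.0], [4.0]], {"A": {"pep0", "pep1", "pep2"}}
        )
        params = InferenceParams(PARAMS.input_accessions, PARAMS.output_accessions, "median")
        doc = infer_protein_abundance(doc, params)
        out = get_quant_layer(doc, Level.protein_group, "MS:1002518")
        assert out.values == [[4.0]]

    def test_unidentified_peptides_never_aggregate(self):
        doc = _doc_with_proteins([[2.0], [7.0]], {"A": {"pep0", "pep1"}})
        doc.peptide_list[1].sequence = None
        doc = infer_protein_abundance(doc, PARAMS)
        out = get_quant_layer(doc, Level.protein_group, "MS:1002518")
        assert out.values == [[2.0]]

    def test_sum_conservation_on_simulated_study(self):
        doc, _ = generate_study(
            SimulationConfig(n_proteins=40, missing_rate=0.1,
                             conflicted_edge_fraction=0.03, seed=17)
        )
        raw = get_quant_layer(doc, Level.peptide, "MS:1001893")
        doc = infer_protein_abundance(doc, PARAMS)
        out = get_quant_layer(doc, Level.protein_group, "MS:1002518")
        labels = {c.peptide_ref: c.klass for c in classify_peptides(doc.protein_list)}
        idx = {r: i for i, r in enumerate(raw.row_refs)}
        for j in range(len(raw.column_refs)):
            total_pep = sum(
                0.0 if is_missing(raw.values[idx[p]][j]) else raw.values[idx[p]][j]
                for p, kl in labels.items()
                if kl != PeptideKlass.conflicted and p in idx
            )
            total_grp = sum(row[j] for row in out.values)
            assert math.isclose(total_grp, total_pep, rel_tol=1e-9)

    def test_planted_groups_recovered_exactly(self):
        doc, truth = generate_study(
            SimulationConfig(n_proteins=50, shared_peptide_fraction=0.3,
                             conflicted_edge_fraction=0.0, seed=23)
        )
        doc = infer_protein_abundance(doc, PARAMS)
        got = {
            g.anchor_accession: (tuple(g.member_accessions), tuple(g.peptide_refs))
            for g in doc.protein_groups
        }
        expected = {a: (m, p) for a, m, p in truth.groups}
        assert got == expected
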