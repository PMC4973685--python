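"""Scaling-factor estimation against an independent step-by-step oracle."""

import math
import random
import statistics

import numpy as np
import pytest

from mzqpost.model import NULL, Level, get_quant_layer, is_nan, is_null
from mzqpost.normalise import (
    DegenerateInputError,
    NormalisationParams,
    compute_scaling_factor,
    compute_scaling_result,
    normalise_layer,
    select_reference_assay,
)
from mzqpost.simulate import SimulationConfig, generate_study

from conftest import assay_matrix_doc


def oracle_factor(ref, target):
    """Independent re-derivation of the scaling factor.

    Pairwise log10 ratios (skipping missing and non-positive values),
    then repeated median/MAD (x1.4826) computation removing everything
    outside median +/- 2 sigma until nothing moves, then 10**mean.
    """
    ratios = []
    for r, t in zip(ref, target):
        if is_null(r) or is_null(t) or is_nan(r) or is_nan(t):
            continue
        if r <= 0 or t <= 0:
            continue
        ratios.append(math.log10(r / t))
    assert len(ratios) >= 2
    while True:
        med = statistics.median(ratios)
        mad = statistics.median(abs(x - med) for x in ratios)
        sigma = 1.4826 * mad
        kept = [x for x in ratios if abs(x - med) <= 2 * sigma]
        if mad == 0 or len(kept) == len(ratios):
            break
        ratios = kept
    return 10 ** (sum(ratios) / len(ratios))


class TestScalingFactor:
    def test_constant_half_ratio_gives_exactly_two(self):
        ref = [10.0, 20.0, 30.0, 40.0]
        target = [5.0, 10.0, 15.0, 20.0]
        factor, trace, _ = compute_scaling_factor(ref, target)
        assert factor == 2.0
        assert trace[-1].mad == 0.0  # MAD = 0 short-circuit

    def test_identity_gives_one(self):
        vals = [3.0, 7.0, 11.0]
        factor, _, _ = compute_scaling_factor(vals, list(vals))
        assert factor == 1.0

    def test_outlier_row_removed_via_mad_loop(self):
        # log10 ratios {0.01, -0.02, 0.00, 0.02, 1.00}: the 1.00 row must go
        ratios = [0.01, -0.02, 0.00, 0.02, 1.00]
        ref = [10 ** r for r in ratios]
        target = [1.0] * 5
        factor, trace, _ = compute_scaling_factor(ref, target)
        removed = {rid for t in trace for rid in t.removed_row_ids}
        assert "4" in removed  # index of the 1.00 ratio
        assert 0.9 < factor < 1.1
        assert factor == pytest.approx(oracle_factor(ref, target), rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_on_random_vectors(self, seed):
        rng = random.Random(seed)
        n = rng.randint(5, 60)
        ref = [10 ** rng.gauss(5, 0.8) for _ in range(n)]
        target = [
            r / 10 ** rng.gauss(0.2, 0.1 if rng.random() < 0.9 else 1.0) for r in ref
        ]
        # sprinkle missing/zero cells
        for i in range(n):
            if rng.random() < 0.1:
                target[i] = rng.choice([NULL, float("nan"), 0.0])
        try:
            factor, _, _ = compute_scaling_factor(ref, target)
        except DegenerateInputError:
            pytest.skip("degenerate draw")
        assert factor == pytest.approx(oracle_factor(ref, target), rel=1e-12)

    def test_sigma_is_always_mad_times_coefficient(self):
        rng = random.Random(1)
        ref = [10 ** rng.gauss(5, 1) for _ in range(40)]
        target = [r / 10 ** rng.gauss(0, 0.3) for r in ref]
        _, trace, _ = compute_scaling_factor(ref, target)
        for t in trace:
            assert t.sigma == pytest.approx(1.4826 * t.mad, abs=0.0)

    def test_fewer_than_two_usable_rows_errors(self):
        with pytest.raises(DegenerateInputError):
            compute_scaling_factor([1.0, NULL, 0.0], [2.0, 3.0, 4.0])

    def test_nonpositive_rows_excluded(self):
        # the zero/negative rows must not disturb the constant-ratio path
        ref = [10.0, 20.0, 0.0, 30.0, -5.0]
        target = [5.0, 10.0, 7.0, 15.0, 3.0]
        factor, _, _ = compute_scaling_factor(ref, target)
        assert factor == 2.0


def oracle_reference(layer_values, assay_ids):
    """Brute-force enumeration of every candidate reference."""
    stdevs = {}
    for r, ref_assay in enumerate(assay_ids):
        factors = []
        for c, assay in enumerate(assay_ids):
            if c == r:
                factors.append(1.0)
            else:
                factors.append(
                    oracle_factor(
                        [row[r] for row in layer_values],
                        [row[c] for row in layer_values],
                    )
                )
        stdevs[ref_assay] = statistics.stdev(factors)
    med = statistics.median(stdevs.values())
    dists = {a: abs(stdevs[a] - med) for a in assay_ids}
    best = min(dists.values())
    tol = 1e-9 * max(best, 1.0) + 1e-12  # equal distances must tie, not race
    return min(a for a in assay_ids if dists[a] <= best + tol)


class TestReferenceSelection:
    def test_identical_assays_tie_broken_by_lowest_id(self):
        doc = assay_matrix_doc([[5.0, 5.0, 5.0]] * 4)
        layer = doc.quant_layers[0]
        ref = select_reference_assay(layer, NormalisationParams())
        assert ref == "a0"

    def test_scaled_profiles_match_brute_force(self):
        rng = random.Random(0)
        base = [10 ** rng.gauss(5, 0.7) for _ in range(30)]
        # B = 1.0x, A = 0.5x, C = 4.0x of a common profile
        rows = [[0.5 * b, 1.0 * b, 4.0 * b] for b in base]
        doc = assay_matrix_doc(rows)
        layer = doc.quant_layers[0]
        got = select_reference_assay(layer, NormalisationParams())
        assert got == oracle_reference(rows, ["a0", "a1", "a2"])

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances_match_brute_force(self, seed):
        rng = random.Random(seed)
        n_rows = rng.randint(8, 25)
        scales = [10 ** rng.gauss(0, 0.4) for _ in range(4)]
        rows = []
        for _ in range(n_rows):
            b = 10 ** rng.gauss(5, 0.6)
            rows.append([b * s * 10 ** rng.gauss(0, 0.05) for s in scales])
        doc = assay_matrix_doc(rows)
        got = select_reference_assay(doc.quant_layers[0], NormalisationParams())
        assert got == oracle_reference(rows, ["a0", "a1", "a2", "a3"])

    def test_user_supplied_reference_respected(self):
        doc = assay_matrix_doc([[1.0, 2.0], [3.0, 6.0], [2.0, 4.0]])
        params = NormalisationParams(reference_assay="a1")
        assert select_reference_assay(doc.quant_layers[0], params) == "a1"

    def test_single_assay_errors(self):
        doc = assay_matrix_doc([[1.0], [2.0]])
        with pytest.raises(DegenerateInputError):
            select_reference_assay(doc.quant_layers[0], NormalisationParams())


class TestNormaliseLayer:
    def test_factor_two_column_becomes_reference_copy(self):
        rows = [[10.0, 5.0], [20.0, 10.0], [40.0, 20.0]]
        doc = assay_matrix_doc(rows)
        params = NormalisationParams(reference_assay="a0")
        doc, result = normalise_layer(doc, params)
        out = get_quant_layer(doc, Level.peptide, params.output_accession)
        assert result.factors == {"a0": 1.0, "a1": 2.0}
        for row in out.values:
            assert row[1] == pytest.approx(row[0])

    def test_null_nan_zero_cells_pass_through(self):
        rows = [[10.0, 5.0], [20.0, 10.0], [NULL, float("nan")], [30.0, 0.0]]
        doc = assay_matrix_doc(rows)
        doc, _ = normalise_layer(doc, NormalisationParams(reference_assay="a0"))
        out = get_quant_layer(doc, Level.peptide, "MS:1001891")
        assert is_null(out.values[2][0])
        assert is_nan(out.values[2][1])
        assert out.values[3][1] == 0.0

    def test_decoy_rows_do_not_move_factors(self):
        rng = random.Random(3)
        clean_rows = []
        for i in range(25):
            b = 10 ** rng.gauss(5, 0.5)
            clean_rows.append([b, b / 3.0])
        doc_clean = assay_matrix_doc(clean_rows)
        # same matrix plus decoy rows with a wildly different ratio
        doc_decoy = assay_matrix_doc(
            clean_rows + [[1e6, 1e6], [2e6, 2e6], [5e5, 5e5]]
        )
        for i in (25, 26, 27):
            old = doc_decoy.quant_layers[0].row_refs[i]
            doc_decoy.quant_layers[0].row_refs[i] = f"DECOY_{old}"
            doc_decoy.peptide_list[i].id = f"DECOY_{old}"
        _, res_clean = normalise_layer(
            doc_clean, NormalisationParams(reference_assay="a0")
        )
        _, res_decoy = normalise_layer(
            doc_decoy,
            NormalisationParams(reference_assay="a0", decoy_tag="DECOY_"),
        )
        assert res_decoy.factors["a1"] == pytest.approx(res_clean.factors["a1"])

    def test_unidentified_rows_excluded_when_identified_only(self):
        rows = [[10.0, 5.0], [20.0, 10.0], [30.0, 3.0]]
        doc = assay_matrix_doc(rows)
        doc.peptide_list[2].sequence = None  # the discordant row is unidentified
        params = NormalisationParams(reference_assay="a0")
        _, res = normalise_layer(doc, params)
        assert res.factors["a1"] == 2.0
        # with processing_level='all' the discordant row participates
        doc2 = assay_matrix_doc(rows)
        doc2.peptide_list[2].sequence = None
        _, res_all = normalise_layer(
            doc2,
            NormalisationParams(reference_assay="a0", processing_level="all"),
        )
        assert res_all.factors["a1"] != 2.0

    def test_scale_equivariance(self):
        rng = random.Random(7)
        rows = []
        for _ in range(30):
            b = 10 ** rng.gauss(5, 0.5)
            rows.append([b * 10 ** rng.gauss(0, 0.02), b * 10 ** rng.gauss(0, 0.02)])
        doc_a = assay_matrix_doc(rows)
        c = 3.7
        doc_b = assay_matrix_doc([[r0, r1 * c] for r0, r1 in rows])
        _, res_a = normalise_layer(doc_a, NormalisationParams(reference_assay="a0"))
        _, res_b = normalise_layer(doc_b, NormalisationParams(reference_assay="a0"))
        assert res_b.factors["a1"] == pytest.approx(res_a.factors["a1"] / c, rel=1e-9)
        out_a = get_quant_layer(doc_a, Level.peptide, "MS:1001891")
        out_b = get_quant_layer(doc_b, Level.peptide, "MS:1001891")
        for ra, rb in zip(out_a.values, out_b.values):
            assert rb[1] == pytest.approx(ra[1], rel=1e-9)

    def test_reference_column_unchanged(self):
        doc = assay_matrix_doc([[5.0, 2.0], [6.0, 3.0], [9.0, 4.0]])
        doc, res = normalise_layer(doc, NormalisationParams(reference_assay="a0"))
        raw = get_quant_layer(doc, Level.peptide, "MS:1001893")
        out = get_quant_layer(doc, Level.peptide, "MS:1001891")
        for r_raw, r_out in zip(raw.values, out.values):
            assert r_out[0] == r_raw[0]

    def test_duplicate_output_accession_rejected(self):
        doc = assay_matrix_doc([[5.0, 2.0], [6.0, 3.0]])
        params = NormalisationParams(reference_assay="a0")
        doc, _ = normalise_layer(doc, params)
        with pytest.raises(Exception, match="already present"):
            normalise_layer(doc, params)


class TestPlantedFactorRecovery:
    def test_planted_factors_recovered_within_two_percent(self):
        cfg = SimulationConfig(
            n_proteins=500,
            true_scaling_factors=(1.0, 0.5, 2.0, 1.5, 0.8, 1.2),
            de_fraction=0.0,
            missing_rate=0.1,
            outlier_row_fraction=0.05,
            seed=42,
        )
        doc, truth = generate_study(cfg)
        params = NormalisationParams(reference_assay="ass_0")
        _, res = normalise_layer(doc, params)
        for assay, s in truth.true_factors.items():
            assert res.factors[assay] == pytest.approx(s, rel=0.02)

    def test_outlier_loop_terminates_and_counts_decrease(self):
        rng = random.Random(13)
        ref = [10 ** rng.gauss(5, 0.6) for _ in range(200)]
        target = [
            r / 10 ** (rng.gauss(0, 0.05) + (2 if rng.random() < 0.1 else 0))
            for r in ref
        ]
        _, trace, _ = compute_scaling_factor(ref, target)
        assert len(trace) <= 100
        sizes = [len(t.removed_row_ids) for t in trace]
        assert sizes[-1] == 0 or trace[-1].mad == 0
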