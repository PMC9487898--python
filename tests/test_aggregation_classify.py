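from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from structannot.aggregation_classify import (
    aggregate_rsa,
    classify_position,
    evidence_features,
    quality_score,
    select_recommended,
    weighted_aggregate,
)
from structannot.registry import EVIDENCE_NAMES, FEATURE_NAMES, INTERFACE_TYPES
from structannot.residue_analysis.features import ResidueFeatures
from structannot.search_align.gotoh import AlignmentResult
from structannot.search_align.mapping import SeqToStructAnnotation


def _features(**overrides) -> dict:
    base = dict.fromkeys(FEATURE_NAMES, 0.0)
    base.update(overrides)
    return base


def _annotation(entry="E1", chain="A", identity=1.0, coverage=1.0, resolution=2.0):
    aln = AlignmentResult("A", "A", 4.0, 0, 1, identity)
    aln.identity = identity
    return SeqToStructAnnotation(
        query_id="Q", entry_id=entry, chain_id=chain, alignment=aln,
        resolution=resolution, position_map={1: (1, "")}, coverage=coverage,
        quality=quality_score(identity, coverage, resolution),
    )


def _residue_features(entry="E1", chain="A", resnum=1, **overrides) -> ResidueFeatures:
    return ResidueFeatures(entry, chain, resnum, "", _features(**overrides))


class TestQualityScore:
    def test_perfect_annotation(self):
        assert quality_score(1.0, 1.0, 1.5) == pytest.approx(1.0)

    def test_resolution_clamped(self):
        assert quality_score(1.0, 1.0, 0.5) == pytest.approx(1.0)
        assert quality_score(1.0, 1.0, 9.0) == pytest.approx(0.1)

    def test_undefined_resolution_counts_as_3_5(self):
        assert quality_score(1.0, 1.0, None) == pytest.approx(quality_score(1.0, 1.0, 3.5))


class TestWeightedAggregate:
    def test_equal_weights_mean(self):
        assert weighted_aggregate([0.2, 0.4], [1.0, 1.0]) == pytest.approx(0.3)

    def test_weighting(self):
        assert weighted_aggregate([0.0, 0.4], [3.0, 1.0]) == pytest.approx(0.1)

    def test_sparsity_rule(self):
        assert weighted_aggregate([0.7, None], [2.0, 5.0]) == pytest.approx(0.7)

    def test_all_undefined(self):
        assert weighted_aggregate([None, None], [1.0, 1.0]) is None

    def test_negative_quality_rejected(self):
        with pytest.raises(ValueError):
            weighted_aggregate([0.5], [-1.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_aggregate([0.5], [1.0, 2.0])

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=8),
           st.lists(st.floats(0.01, 5), min_size=8, max_size=8),
           st.floats(0.1, 10))
    @settings(max_examples=200, deadline=None)
    def test_invariants(self, values, qualities, scale):
        qualities = qualities[: len(values)]
        w = weighted_aggregate(values, qualities)
        # bounded by [min, max] of inputs
        assert min(values) - 1e-9 <= w <= max(values) + 1e-9
        # scale invariance of the weights
        scaled = weighted_aggregate(values, [q * scale for q in qualities])
        assert scaled == pytest.approx(w, rel=1e-9, abs=1e-9)
        # single-input identity
        assert weighted_aggregate([values[0]], [qualities[0]]) == pytest.approx(values[0])
        # equal weights reduce to the arithmetic mean
        assert weighted_aggregate(values, [1.0] * len(values)) == pytest.approx(
            sum(values) / len(values))


class TestAggregateRsa:
    def test_squared_coverage_bias(self):
        result = aggregate_rsa([0.1, 0.9], [1.0, 1.0], [1.0, 0.5])
        assert result == pytest.approx((0.1 * 1 + 0.9 * 0.25) / 1.25)
        assert result == pytest.approx(0.26)

    def test_single_annotation(self):
        assert aggregate_rsa([0.42], [0.7], [0.8]) == pytest.approx(0.42)

    def test_equal_coverages_reduce_to_plain(self):
        values, qualities = [0.1, 0.5, 0.9], [1.0, 2.0, 0.5]
        assert aggregate_rsa(values, qualities, [0.7] * 3) == pytest.approx(
            weighted_aggregate(values, qualities))


class TestClassify:
    def test_surface(self):
        labels = classify_position(_features(rsa_all=0.50))
        assert labels["structural_class"] == "Surface"
        assert labels["simple_class"] == "Surface"

    def test_core(self):
        labels = classify_position(_features(rsa_all=0.10))
        assert labels["structural_class"] == "Core"

    def test_boundary_is_core(self):
        assert classify_position(_features(rsa_all=0.16))["structural_class"] == "Core"
        assert classify_position(_features(rsa_all=0.1600001))["structural_class"] == "Surface"

    def test_no_structure(self):
        labels = classify_position(None)
        assert labels["structural_class"] == "No structure"
        assert labels["simple_class"] == "No structure"

    def test_multiple_interactions_string(self):
        labels = classify_position(_features(
            rsa_all=0.5, sidechain_ligand_degree=1.0, sidechain_protein_degree=1.0))
        assert labels["rin_class"] == ("Multiple interactions: sidechain contact "
                                       "with a ligand and sidechain contact with a protein")
        assert labels["rin_simple_class"] == "Multiple interactions"
        assert labels["structural_class"] == "Ligand interaction"

    def test_single_interaction_string(self):
        labels = classify_position(_features(rsa_all=0.5, sidechain_dna_degree=0.5))
        assert labels["rin_class"] == "Sidechain contact with a DNA"
        assert labels["structural_class"] == "DNA interaction"

    def test_truth_table_exhaustive(self):
        """Every combination of RSA below/at/above threshold and each single
        interaction type present/absent maps to the expected class."""
        for rsa, itype, present in itertools.product(
                (0.10, 0.16, 0.22), INTERFACE_TYPES, (False, True)):
            degree = 1.0 if present else 0.0
            labels = classify_position(_features(
                rsa_all=rsa, **{f"sidechain_{itype}_degree": degree}))
            if present:
                assert labels["simple_class"] == "Interaction", (rsa, itype)
                assert itype.upper() in labels["structural_class"].upper()
            else:
                expected = "Surface" if rsa > 0.16 else "Core"
                assert labels["structural_class"] == expected, (rsa, itype)

    def test_priority_order(self):
        labels = classify_position(_features(
            rsa_all=0.5, sidechain_protein_degree=5.0, mainchain_metal_degree=0.2))
        assert labels["structural_class"] == "Metal interaction"

    def test_degree_below_eps_ignored(self):
        labels = classify_position(_features(rsa_all=0.5, sidechain_ligand_degree=0.05))
        assert labels["structural_class"] == "Surface"

    def test_mainchain_sidechain_locations(self):
        labels = classify_position(_features(
            rsa_all=0.2, rsa_mainchain=0.1, rsa_sidechain=0.4))
        assert labels["mainchain_location"] == "Core"
        assert labels["sidechain_location"] == "Surface"


class TestSelectRecommended:
    def test_single_annotation_both_same(self):
        ann = _annotation()
        rf = _residue_features()
        max_id, rec = select_recommended([ann], [rf])
        assert max_id is ann and rec is ann

    def test_ligand_contact_wins_at_equal_quality(self):
        a = _annotation(entry="E1")
        b = _annotation(entry="E2")
        rf_plain = _residue_features(entry="E1")
        rf_ligand = _residue_features(entry="E2", contact_count_ligand=3.0)
        _, rec = select_recommended([a, b], [rf_plain, rf_ligand])
        assert rec is b

    def test_identity_tie_broken_by_coverage(self):
        a = _annotation(entry="E1", identity=0.8, coverage=0.6)
        b = _annotation(entry="E2", identity=0.8, coverage=0.9)
        max_id, _ = select_recommended([a, b], [_residue_features(entry="E1"),
                                                _residue_features(entry="E2")])
        assert max_id is b

    def test_permutation_invariant(self):
        anns = [_annotation(entry=f"E{i}", identity=0.5 + 0.1 * i) for i in range(4)]
        rfs = [_residue_features(entry=f"E{i}") for i in range(4)]
        ref = select_recommended(anns, rfs)
        flipped = select_recommended(anns[::-1], rfs[::-1])
        assert (ref[0].entry_id, ref[1].entry_id) == (
            flipped[0].entry_id, flipped[1].entry_id)

    def test_zero_annotations(self):
        assert select_recommended([], []) == (None, None)


class TestEvidence:
    def test_count(self):
        anns = [_annotation(entry=f"E{i}") for i in range(3)]
        rfs = [_residue_features(entry=f"E{i}") for i in range(3)]
        ev = evidence_features(anns, rfs)
        assert ev["n_mapped_structures"] == 3.0
        assert ev["n_distinct_entries"] == 3.0

    def test_zero_annotations(self):
        ev = evidence_features([], [])
        assert ev["n_mapped_structures"] == 0.0
        assert ev["max_identity"] is None
        assert set(ev) == set(EVIDENCE_NAMES)

    def test_max_identity(self):
        anns = [_annotation(identity=0.4), _annotation(identity=0.9)]
        rfs = [_residue_features(), _residue_features()]
        assert evidence_features(anns, rfs)["max_identity"] == pytest.approx(0.9)

    def test_location_codes(self):
        ev = evidence_features([_annotation()], [_residue_features()],
                               labels={"location": "Surface",
                                       "mainchain_location": "Core",
                                       "sidechain_location": None})
        assert ev["location_code"] == 1.0
        assert ev["mainchain_location_code"] == 0.0
        assert ev["sidechain_location_code"] is None
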