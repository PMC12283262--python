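"""Alignment, signature extraction, domain scanning and elongation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stachelhaus import (
    AlignmentParams,
    ReferenceProfile,
    extract_signature,
    global_align,
    measure_elongation,
    plant_code,
    random_peptide,
    scan_protein,
)
from stachelhaus.reference import (
    AlignmentInputError,
    ExtractionError,
    default_reference_profile,
)
from stachelhaus.synthetic import ModuleSpec, build_assembly_line

from oracles import blosum62_dict, gotoh_global_score

PARAMS = AlignmentParams()


class TestAlignmentParams:
    def test_gap_cost_is_affine(self):
        assert PARAMS.gap_cost(1) == 11
        assert PARAMS.gap_cost(50) == 11 + 49

    def test_rejects_extend_above_open(self):
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=1, gap_extend=5)


class TestReferenceProfileInvariants:
    def test_default_packaged_profile_is_consistent(self):
        prof = default_reference_profile()
        assert len(prof.sequence) == 530
        assert prof.signature_positions == (235, 236, 239, 278, 299, 301,
                                            322, 330, 331, 517)
        # canonical Phe-activating code planted in the synthetic stand-in
        assert prof.signature_residues == "DAWTIAAICK"

    def test_positions_must_be_increasing_and_in_range(self, scaffold):
        seq, _ = scaffold
        with pytest.raises(ValueError):
            ReferenceProfile(seq, signature_positions=(235, 235, 239, 278, 299,
                                                       301, 322, 330, 331, 517))
        with pytest.raises(ValueError):
            ReferenceProfile(seq, signature_positions=(235, 236, 239, 278, 299,
                                                       301, 322, 330, 331, 999))

    def test_a8_a9_interval_must_sit_between_ninth_and_tenth_positions(self, scaffold):
        seq, _ = scaffold
        with pytest.raises(ValueError):
            ReferenceProfile(seq, a8_a9_interval=(300, 510))
        with pytest.raises(ValueError):
            ReferenceProfile(seq, a8_a9_interval=(340, 520))


class TestGlobalAlign:
    def test_self_alignment_has_no_gaps(self, profile):
        aln = global_align(profile.sequence, profile, PARAMS)
        q, r = aln.aligned_strings
        assert q == r == profile.sequence

    def test_single_internal_deletion_gives_one_gap_of_length_one(self, profile):
        truncated = profile.sequence[:260] + profile.sequence[261:]
        aln = global_align(truncated, profile, PARAMS)
        q, _ = aln.aligned_strings
        assert q.count("-") == 1
        # oracle score on a 30-residue window around the deletion
        a = profile.sequence[:30]
        b = a[:15] + a[16:]
        expected = gotoh_global_score(b, a, blosum62_dict(), 11, 1)
        assert global_align(b, a, PARAMS).score == expected

    def test_insertion_score_matches_closed_form_affine_arithmetic(self, profile):
        # planting a 50-residue insertion costs exactly one affine gap
        seq = profile.sequence
        ins = random_peptide(50, seed=11)
        mid = sum(profile.a8_a9_interval) // 2
        query = seq[:mid] + ins + seq[mid:]
        self_score = global_align(seq, profile, PARAMS).score
        assert global_align(query, profile, PARAMS).score == \
            self_score - PARAMS.gap_cost(50)

    def test_scores_match_exhaustive_dp_oracle_on_short_sequences(self):
        mat = blosum62_dict()
        rng = np.random.default_rng(42)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(aas, size=rng.integers(5, 41)))
            b = "".join(rng.choice(aas, size=rng.integers(5, 41)))
            assert global_align(a, b, PARAMS).score == \
                gotoh_global_score(a, b, mat, 11, 1)

    def test_non_amino_acid_character_is_an_input_error(self, profile):
        with pytest.raises(AlignmentInputError):
            global_align("ACDEF*GHIK", profile, PARAMS)
        with pytest.raises(AlignmentInputError):
            global_align("", profile, PARAMS)


class TestExtractSignature:
    def test_self_extraction_returns_the_reference_signature(self, profile):
        code, gaps = extract_signature(profile.sequence, profile)
        assert code == profile.signature_residues
        assert gaps == ()

    def test_planted_code_round_trip(self, scaffold):
        seq, profile = scaffold
        planted = plant_code(seq, profile, "DAWFLGNVVK")
        code, gaps = extract_signature(planted, profile)
        assert code == "DAWFLGNVVK"
        assert gaps == ()

    def test_code_survives_a_342_residue_tailoring_insertion(self, scaffold):
        seq, profile = scaffold
        planted = plant_code(seq, profile, "DAWFLGNVVK")
        mid = sum(profile.a8_a9_interval) // 2
        query = planted[:mid] + random_peptide(342, seed=5) + planted[mid:]
        code, gaps = extract_signature(query, profile)
        assert code == "DAWFLGNVVK"
        assert gaps == ()

    def test_deleted_signature_region_yields_x_and_records_the_slot(self, scaffold):
        seq, profile = scaffold
        planted = plant_code(seq, profile, "DAWFLGNVVK")
        # remove residues 271..286 (1-based), spanning signature position 278
        query = planted[:270] + planted[286:]
        code, gaps = extract_signature(query, profile)
        assert code[3] == "X"
        assert gaps == (3,)
        assert code[0] == "D" and code[9] == "K"

    def test_truncated_query_fails_with_uncovered_positions(self, scaffold):
        seq, profile = scaffold
        with pytest.raises(ExtractionError, match="517"):
            extract_signature(seq[:400], profile)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(gap_index=st.sampled_from([2, 8]), length=st.integers(1, 400),
           seed=st.integers(0, 2**16))
    def test_insertions_between_signature_positions_leave_code_unchanged(
            self, gap_index, length, seed):
        # Sites keep a 15-residue margin from the flanking signature
        # positions (only the 239-278 and 331-517 gaps have the room): an
        # insertion abutting a signature residue can legally reassign its
        # column when the planted residue mismatches the reference
        # background, which is a property of alignment-based extraction,
        # not an extraction defect.
        from stachelhaus import ScaffoldSpec, make_scaffold
        seq, profile = make_scaffold(ScaffoldSpec(seed=7))
        planted = plant_code(seq, profile, "DAQDLGVVDK")
        pos = profile.signature_positions
        rng = np.random.default_rng(seed)
        site = int(rng.integers(pos[gap_index] + 15, pos[gap_index + 1] - 15))
        query = planted[:site] + random_peptide(length, seed) + planted[site:]
        code, _ = extract_signature(query, profile)
        assert code == "DAQDLGVVDK"

    def test_point_mutations_are_local_to_their_slot(self, scaffold):
        seq, profile = scaffold
        planted = plant_code(seq, profile, "DAWFLGNVVK")
        base, _ = extract_signature(planted, profile)
        # mutating signature position k changes slot k only
        for slot, pos in enumerate(profile.signature_positions):
            old = planted[pos - 1]
            new = "W" if old != "W" else "F"
            mutant = planted[:pos - 1] + new + planted[pos:]
            code, _ = extract_signature(mutant, profile)
            assert code[slot] == new
            assert all(code[i] == base[i] for i in range(10) if i != slot)
        # mutating non-signature residues changes no slot
        sig = set(profile.signature_positions)
        for pos in (10, 150, 260, 400, 529):
            assert pos not in sig
            old = planted[pos - 1]
            new = "A" if old != "A" else "G"
            mutant = planted[:pos - 1] + new + planted[pos:]
            code, _ = extract_signature(mutant, profile)
            assert code == base


class TestMeasureElongation:
    def _aligned(self, query, profile):
        return global_align(query, profile, PARAMS)

    def test_unmodified_domain_has_no_insertion(self, scaffold):
        seq, profile = scaffold
        ins, flag = measure_elongation(self._aligned(seq, profile), profile)
        assert (ins, flag) == (0, False)

    @pytest.mark.parametrize("length,expect_flag", [
        (342, True),   # the largest characterised tailoring insertion
        (50, True),    # at the default threshold
        (49, False),   # one below the default threshold
    ])
    def test_insertion_measured_exactly_and_flagged_at_threshold(
            self, scaffold, length, expect_flag):
        seq, profile = scaffold
        mid = sum(profile.a8_a9_interval) // 2
        query = seq[:mid] + random_peptide(length, seed=3) + seq[mid:]
        ins, flag = measure_elongation(self._aligned(query, profile), profile)
        assert ins == length
        assert flag is expect_flag

    def test_insertion_outside_the_interval_is_not_counted(self, scaffold):
        seq, profile = scaffold
        query = seq[:100] + random_peptide(60, seed=4) + seq[100:]
        ins, flag = measure_elongation(self._aligned(query, profile), profile)
        assert (ins, flag) == (0, False)


class TestScanProtein:
    def test_single_planted_domain_gives_one_spanning_hit(self):
        line = build_assembly_line([ModuleSpec("DAWFLGNVVK", "Leu")], seed=5)
        hits = scan_protein(line.sequence, line.profile)
        assert len(hits) == 1
        mod = line.manifest.modules[0]
        assert hits[0].start == mod.start and hits[0].end == mod.end
        assert hits[0].code == "DAWFLGNVVK"

    def test_three_module_line_recovers_manifest_codes_in_order(self):
        specs = [ModuleSpec("DAWFLGNVVK", "Leu", mutation_rate=0.05),
                 ModuleSpec("DAQDLGVVDK", "Glu", mutation_rate=0.05),
                 ModuleSpec("DVSAIGCVTK", "Tyr", mutation_rate=0.05)]
        line = build_assembly_line(specs, seed=13)
        hits = scan_protein(line.sequence, line.profile)
        assert [h.code for h in hits] == [m.code for m in line.manifest.modules]
        starts = [h.start for h in hits]
        assert starts == sorted(starts)
        # non-overlap
        for a, b in zip(hits, hits[1:]):
            assert a.end <= b.start

    def test_random_sequence_has_no_hits(self, profile):
        assert scan_protein(random_peptide(200, seed=21), profile) == []
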