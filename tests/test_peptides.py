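"""Zone scanning, mutants, scramble controls, alignment and polarity."""

import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from rinscan.peptides import (
    CD44V3_SEQUENCE,
    alignment_score,
    apply_point_mutation,
    classify_polarity,
    delete_zone,
    global_align,
    percent_identity,
    read_fasta,
    residue_at,
    scramble_peptide,
    split_zones,
    write_zones_fasta,
)

ZONES = ["STSSNTISAG", "WEPNEENEDE", "RDRHLSFSGSG", "IDDDEDFISST"]


class TestZones:
    def test_published_four_zone_split(self):
        zones = split_zones(CD44V3_SEQUENCE, 4)
        assert [z.sequence for z in zones] == ZONES
        assert [len(z.sequence) for z in zones] == [10, 10, 11, 11]
        assert [(z.start, z.end) for z in zones] == [(1, 10), (11, 20), (21, 31), (32, 42)]

    def test_single_zone_is_whole_sequence(self):
        (zone,) = split_zones("ACDEFG", 1)
        assert zone.sequence == "ACDEFG"
        assert (zone.start, zone.end) == (1, 6)

    def test_remainder_goes_to_last_zone(self):
        zones = split_zones("A" * 10 + "C" * 11, 2)
        assert [len(z.sequence) for z in zones] == [10, 11]

    def test_too_many_zones_rejected(self):
        with pytest.raises(ValueError):
            split_zones("ACD", 4)

    @given(
        seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60),
        n=st.integers(min_value=1, max_value=8),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_zone_tiling_reconstructs_parent(self, seq, n):
        if n > len(seq):
            n = len(seq)
        zones = split_zones(seq, n)
        assert "".join(z.sequence for z in zones) == seq
        lengths = [len(z.sequence) for z in zones]
        assert max(lengths) - min(lengths) <= 1
        # spans are contiguous and 1-based
        assert zones[0].start == 1 and zones[-1].end == len(seq)
        for prev, cur in zip(zones, zones[1:]):
            assert cur.start == prev.end + 1


class TestResidueLookupAndMutants:
    def test_exon_coordinates_of_key_residues(self):
        assert residue_at(CD44V3_SEQUENCE, 34) == "D"
        assert residue_at(CD44V3_SEQUENCE, 38) == "F"

    @pytest.mark.parametrize("pos", [0, 43])
    def test_out_of_range_rejected(self, pos):
        with pytest.raises(ValueError):
            residue_at(CD44V3_SEQUENCE, pos)

    def test_delete_c_terminal_zone(self):
        zones = split_zones(CD44V3_SEQUENCE, 4)
        truncated = delete_zone(CD44V3_SEQUENCE, zones, "zone 4")
        assert len(truncated) == 31
        assert truncated.endswith("SGSG")

    def test_delete_internal_zone_joins_flanks(self):
        zones = split_zones(CD44V3_SEQUENCE, 4)
        truncated = delete_zone(CD44V3_SEQUENCE, zones, "zone 3")
        assert truncated == ZONES[0] + ZONES[1] + ZONES[3]

    def test_delete_then_reinsert_round_trip(self):
        zones = split_zones(CD44V3_SEQUENCE, 4)
        zone = zones[2]
        truncated = delete_zone(CD44V3_SEQUENCE, zones, zone.label)
        rebuilt = truncated[: zone.start - 1] + zone.sequence + truncated[zone.start - 1 :]
        assert rebuilt == CD44V3_SEQUENCE

    def test_unknown_zone_label(self):
        zones = split_zones(CD44V3_SEQUENCE, 4)
        with pytest.raises(KeyError):
            delete_zone(CD44V3_SEQUENCE, zones, "zone 9")

    def test_point_mutation(self):
        assert apply_point_mutation("AHC", 2, "H", "A") == "AAC"

    def test_mutation_involution(self):
        mutated = apply_point_mutation("AHC", 2, "H", "A")
        assert apply_point_mutation(mutated, 2, "A", "H") == "AHC"

    def test_wild_type_mismatch_reports_actual(self):
        with pytest.raises(ValueError, match="has H"):
            apply_point_mutation("AHC", 2, "K", "A")


class TestScramble:
    def test_multiset_preserved(self):
        out = scramble_peptide("IDDDEDFISST", seed=11)
        assert sorted(out) == sorted("IDDDEDFISST")
        assert out != "IDDDEDFISST"

    def test_seed_determinism(self):
        assert scramble_peptide("IDDDEDFISST", 7) == scramble_peptide("IDDDEDFISST", 7)

    def test_homopolymer_unchanged(self):
        assert scramble_peptide("AAAA", 0) == "AAAA"

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_always_differs_when_possible(self, seed):
        out = scramble_peptide("ACDE", seed)
        assert out != "ACDE" and sorted(out) == sorted("ACDE")


def _enumerate_alignments(a, b):
    """All global alignments as gapped row pairs (no gap-gap columns)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in _enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in _enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in _enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def _score_alignment(ra, rb, matrix, gap_open, gap_extend):
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(ra, rb):
        if x == "-":
            score -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= gap_extend if in_gap_b else gap_open
            in_gap_a, in_gap_b = False, True
        else:
            score += matrix[x, y]
            in_gap_a = in_gap_b = False
    return score


class TestAlignment:
    def test_self_alignment_has_no_gaps(self):
        a, b = global_align("IDDDEDFISST", "IDDDEDFISST")
        assert a == b == "IDDDEDFISST"

    def test_gap_opposite_mismatched_residue(self):
        a, b = global_align("ACD", "AD")
        assert (a, b) == ("ACD", "A-D")

    def test_swap_symmetry(self):
        a1, b1 = global_align("ACDEF", "ACF")
        b2, a2 = global_align("ACF", "ACDEF")
        assert alignment_score("ACDEF", "ACF") == alignment_score("ACF", "ACDEF")
        assert (a1, b1) == (a2, b2)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACD")

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            global_align("ACX1", "ACD")

    @pytest.mark.parametrize(
        "a,b",
        [("ACD", "AD"), ("WGH", "WH"), ("ACDE", "ACE"), ("AC", "CA"), ("KLM", "KLMN")],
    )
    def test_score_matches_exhaustive_enumeration(self, a, b):
        matrix = substitution_matrices.load("BLOSUM62")
        best = max(
            _score_alignment(ra, rb, matrix, 10.0, 1.0)
            for ra, rb in _enumerate_alignments(a, b)
        )
        assert alignment_score(a, b) == pytest.approx(best)


class TestPercentIdentity:
    def test_identical_rows(self):
        assert percent_identity("IDDDEDFISST", "IDDDEDFISST") == 100.0

    def test_single_substitution_over_eleven(self):
        assert percent_identity("IDDDEDFISST", "IDDDEDFISSA") == pytest.approx(
            100 * 10 / 11
        )

    def test_symmetry(self):
        a, b = global_align("ACDEF", "ADF")
        assert percent_identity(a, b) == percent_identity(b, a)

    def test_gap_columns_counted_not_identical(self):
        assert percent_identity("ACD", "A-D") == pytest.approx(100 * 2 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("ACD", "AC")

    def test_hundred_percent_iff_identical_on_non_gap_columns(self):
        assert percent_identity("AC-D", "AC-D") == 100.0
        assert percent_identity("ACD", "ACE") < 100.0


class TestPolarity:
    @pytest.mark.parametrize("residue", ["H", "K", "Q", "G"])
    def test_published_polar_calls(self, residue):
        assert classify_polarity(residue, "published") == "polar"

    @pytest.mark.parametrize("residue", ["L", "A"])
    def test_published_nonpolar_calls(self, residue):
        assert classify_polarity(residue, "published") == "nonpolar"

    def test_glycine_divergence_between_tables(self):
        assert classify_polarity("G", "published") == "polar"
        assert classify_polarity("G", "standard") == "nonpolar"

    def test_unknown_residue(self):
        with pytest.raises(KeyError):
            classify_polarity("X", "published")

    def test_tables_cover_all_twenty(self):
        from rinscan.peptides import AMINO_ACIDS, POLARITY_PUBLISHED, POLARITY_STANDARD

        assert set(POLARITY_PUBLISHED) == set(POLARITY_STANDARD) == set(AMINO_ACIDS)


def test_zone_fasta_round_trip(tmp_path):
    zones = split_zones(CD44V3_SEQUENCE, 4)
    path = tmp_path / "zones.fasta"
    write_zones_fasta(zones, "CD44v3", path)
    records = read_fasta(path)
    assert len(records) == 4
    assert records["CD44v3|zone4|32-42"] == "IDDDEDFISST"
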