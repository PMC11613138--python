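"""Sequence model, fold enumeration and molecular weights."""

import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

from meltfold import oligo
from meltfold.oligo import (
    MASS_OFFSET,
    OligoSequence,
    build_sre_segment,
    enumerate_hairpin_fold,
    enumerate_homoduplex_fold,
    index_to_position,
    molecular_weight,
    position_to_index,
    positions_for_length,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestSequences:
    def test_sreseg16_sequence_and_numbering(self, sreseg16):
        assert sreseg16.bases == "TGTCCATATTAGGACA"
        assert sreseg16.positions == tuple(range(-8, 0)) + tuple(range(1, 9))
        assert sreseg16.base_at(-8) == "T"
        assert sreseg16.base_at(8) == "A"

    def test_sreseg20_has_full_ir_arms(self):
        s = build_sre_segment(20)
        assert s.bases == "GATGTCCATATTAGGACATC"
        assert s.bases[:7] == "GATGTCC" and s.bases[-7:] == "GGACATC"

    def test_sreseg12(self):
        assert build_sre_segment(12).bases == "TCCATATTAGGA"

    @pytest.mark.parametrize("bad_n", [13, 17, 22, 40, 10])
    def test_unsupported_length_names_supported(self, bad_n):
        with pytest.raises(ValueError, match="supported"):
            build_sre_segment(bad_n)

    @pytest.mark.parametrize("n", [28, 36])
    def test_long_segments_need_flank_table(self, n):
        with pytest.raises(ValueError, match="flank sequence unavailable"):
            build_sre_segment(n)

    def test_position_index_round_trip(self):
        for n in (12, 16, 20):
            for i in range(n):
                assert position_to_index(index_to_position(i, n), n) == i
        with pytest.raises(ValueError):
            position_to_index(0, 16)

    def test_invalid_sequences_rejected(self):
        with pytest.raises(ValueError):
            OligoSequence("x", "ACGU")
        with pytest.raises(ValueError):
            OligoSequence("x", "ACGT", positions=(1, 2, 3))  # length mismatch
        with pytest.raises(ValueError):
            OligoSequence("x", "ACGT", positions=(-1, 0, 1, 2))


class TestHairpinFold:
    @pytest.mark.parametrize(
        "n,expected_wc", [(12, 3), (14, 4), (16, 5), (18, 6), (20, 7)]
    )
    def test_stem_wc_counts_across_lengths(self, n, expected_wc):
        fold = enumerate_hairpin_fold(build_sre_segment(n))
        assert fold.n_wc == expected_wc
        assert fold.molecularity == 1

    def test_sreseg16_stem_and_loop(self, sreseg16):
        fold = enumerate_hairpin_fold(sreseg16)
        assert fold.pairs == (
            (-8, 8, True), (-7, 7, True), (-6, 6, True), (-5, 5, True), (-4, 4, True),
        )
        assert fold.loop_positions == (-3, -2, -1, 1, 2, 3)
        loop_seq = "".join(sreseg16.base_at(p) for p in fold.loop_positions)
        assert loop_seq == "ATATTA"
        labels = [oligo.pair_label(sreseg16, a, b) for a, b, _ in fold.pairs]
        assert labels == ["AT_8", "CG_7", "AT_6", "GC_5", "GC_4"]

    def test_no_complementary_ends_gives_all_loop(self):
        fold = enumerate_hairpin_fold(OligoSequence("polyA", "AAAAAAAAAA"))
        assert fold.n_wc == 0
        assert len(fold.loop_positions) == 10

    def test_stem_stops_at_first_mismatch(self):
        # ends pair GC twice, then an A.A mismatch interrupts the stem
        fold = enumerate_hairpin_fold(OligoSequence("x", "GGATTTTTTACC"))
        assert fold.n_wc == 2

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            enumerate_hairpin_fold(OligoSequence("x", "ACGT"), min_loop=3)

    @given(dna.filter(lambda s: len(s) >= 5))
    def test_stem_bound(self, bases):
        fold = enumerate_hairpin_fold(OligoSequence("h", bases))
        assert fold.n_wc <= (len(bases) - 3) // 2


class TestHomoduplexFold:
    def test_sreseg16_mismatched_duplex(self, sreseg16):
        fold = enumerate_homoduplex_fold(sreseg16)
        assert fold.n_wc == 12
        assert fold.molecularity == 2
        assert set(fold.mismatch_positions) == {-3, -2, 2, 3}

    def test_perfect_palindrome_control(self):
        fold = enumerate_homoduplex_fold(OligoSequence("control", "CTGACGTCAG"))
        assert fold.n_wc == 10
        assert fold.mismatch_positions == ()

    def test_polya_never_pairs(self):
        assert enumerate_homoduplex_fold(OligoSequence("a4", "AAAA")).n_wc == 0

    @given(dna.filter(lambda s: len(s) % 2 == 0 and len(s) >= 2))
    def test_pairing_symmetry(self, bases):
        fold = enumerate_homoduplex_fold(OligoSequence("s", bases))
        wc = {(a, b): f for a, b, f in fold.pairs}
        for (a, b), f in wc.items():
            assert wc[(b, a)] == f


class TestMolecularWeight:
    def test_published_masses(self):
        assert molecular_weight(build_sre_segment(16)) == pytest.approx(4880.26)
        assert molecular_weight(build_sre_segment(20)) == pytest.approx(6116.06)
        assert round(molecular_weight(build_sre_segment(16))) == 4880
        assert round(molecular_weight(build_sre_segment(20))) == 6116

    def test_twelve_mer_mass_from_formula(self):
        # the convention formula applied to TCCATATTAGGA
        assert molecular_weight(build_sre_segment(12)) == pytest.approx(3644.46)

    def test_single_base(self):
        assert molecular_weight("A") == pytest.approx(313.21 - MASS_OFFSET)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            molecular_weight("")

    @given(dna, dna)
    def test_additivity(self, a, b):
        assert molecular_weight(a + b) == pytest.approx(
            molecular_weight(a) + molecular_weight(b) + MASS_OFFSET
        )


class TestIO:
    def test_fasta_round_trip(self, sreseg16, tmp_path):
        path = tmp_path / "seqs.fasta"
        oligo.write_fasta([sreseg16, build_sre_segment(12)], str(path))
        back = oligo.read_fasta(str(path))
        assert [s.bases for s in back] == [sreseg16.bases, "TCCATATTAGGA"]
        assert back[0].positions == sreseg16.positions

    def test_fold_report_and_diagram(self, sreseg16):
        fold = enumerate_hairpin_fold(sreseg16)
        tsv = oligo.fold_report_tsv(fold)
        assert tsv.splitlines()[0] == "pair_a\tpair_b\twc_flag"
        assert len(tsv.splitlines()) == 1 + len(fold.pairs)
        diagram = oligo.fold_diagram(sreseg16, fold)
        assert "ATATTA" in diagram
        dup = oligo.fold_diagram(sreseg16, enumerate_homoduplex_fold(sreseg16))
        assert dup.count(".") == 4  # the two tandem mismatch pairs
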