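"""CIGAR walking, target-window calling, and mosaicism tallies."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kovalid.gene_model import GenomicInterval
from kovalid.indel_caller import (
    AlignedRead,
    CigarError,
    IndelCall,
    TargetSite,
    call_indels_at_site,
    genotypable_reads,
    left_normalize,
    parse_cigar,
    parse_cigar_indels,
    reference_span,
    tally_alleles,
)


def read(cigar, pos=1, read_id="r1", seq=None, flag=0):
    return AlignedRead(read_id, "ind1", "chr1", pos, cigar, sequence=seq, flag=flag)


# ---------------------------------------------------------------------------
# Brute-force oracle: expand the CIGAR to single-base ops and read gaps off
# the expanded string, counting reference consumption per base.


def oracle_indels(r: AlignedRead):
    expanded = "".join(op * n for n, op in parse_cigar(r.cigar))
    out = []
    ref = r.pos  # 1-based next reference base
    i = 0
    while i < len(expanded):
        op = expanded[i]
        j = i
        while j < len(expanded) and expanded[j] == op:
            j += 1
        run = j - i
        if op == "D":
            out.append(("del", ref - 1, run))
        elif op == "I":
            out.append(("ins", ref - 1, run))
        if op in "MDN=X":
            ref += run
        i = j
    return out


def random_read(rng: random.Random, idx: int) -> AlignedRead:
    """A read with 0-3 indels separated by match blocks."""
    parts = []
    if rng.random() < 0.3:
        parts.append(f"{rng.randint(1, 10)}S")
    parts.append(f"{rng.randint(5, 40)}M")
    for _ in range(rng.randint(0, 3)):
        kind = rng.choice("ID")
        parts.append(f"{rng.randint(1, 12)}{kind}")
        parts.append(f"{rng.randint(5, 40)}M")
    if rng.random() < 0.3:
        parts.append(f"{rng.randint(1, 10)}S")
    return read("".join(parts), pos=rng.randint(1, 5000), read_id=f"r{idx}")


class TestParseCigarIndels:
    def test_deletion_position(self):
        calls = parse_cigar_indels(read("10M2D15M", pos=101))
        assert len(calls) == 1
        c = calls[0]
        assert (c.kind, c.pos, c.length) == ("del", 110, 2)
        # deleted reference bases are 111-112 (1-based)
        assert (c.footprint.start, c.footprint.end) == (110, 112)

    def test_insertion_position_and_sequence(self):
        calls = parse_cigar_indels(read("5M3I20M", pos=51, seq="A" * 5 + "GGG" + "C" * 20))
        assert len(calls) == 1
        c = calls[0]
        assert (c.kind, c.pos, c.length, c.inserted_seq) == ("ins", 55, 3, "GGG")

    def test_match_only_read_has_no_indels(self):
        assert parse_cigar_indels(read("25M")) == []

    @pytest.mark.parametrize("bad", ["", "*", "10M5", "M10", "10M3Q2M"])
    def test_malformed_cigar_raises(self, bad):
        with pytest.raises(CigarError):
            parse_cigar(bad)

    def test_sequence_length_mismatch_raises(self):
        with pytest.raises(CigarError, match="length"):
            parse_cigar_indels(read("10M", seq="ACGT"))

    def test_matches_brute_force_oracle_on_200_random_reads(self):
        rng = random.Random(20240917)
        for i in range(200):
            r = random_read(rng, i)
            got = [(c.kind, c.pos, c.length) for c in parse_cigar_indels(r)]
            assert got == oracle_indels(r), r.cigar

    def test_reference_consumption_matches_span(self):
        rng = random.Random(11)
        for i in range(50):
            r = random_read(rng, i)
            span = reference_span(r)
            consumed = sum(
                n for n, op in parse_cigar(r.cigar) if op in "MDN=X"
            )
            assert len(span) == consumed


class TestLeftNormalize:
    def test_deletion_shifts_through_homopolymer(self):
        #            0123456789  (0-based)
        reference = "GCAAAATTTG"
        # delete one A at 1-based anchor 5 (deleted base index 5, an A)
        call = IndelCall("chr1", 5, "del", 1)
        norm = left_normalize(call, reference)
        assert norm.pos == 2  # leftmost placement: anchor C, delete first A

    def test_insertion_rotates_sequence(self):
        reference = "GCAAAATTTG"
        call = IndelCall("chr1", 6, "ins", 1, inserted_seq="A")
        norm = left_normalize(call, reference)
        assert norm.pos == 2
        assert norm.inserted_seq == "A"

    def test_non_repetitive_context_is_fixed_point(self):
        reference = "ACGTACGTAC"
        call = IndelCall("chr1", 4, "del", 2)
        assert left_normalize(call, reference).pos == 4


class TestCallAtSite:
    site = TargetSite("T1", GenomicInterval("chr1", 100, 120))

    def test_deletion_inside_window_is_called(self):
        r = read("60M2D60M", pos=51)  # deletion at 0-based [110, 112)
        calls = call_indels_at_site([r], self.site)
        assert len(calls) == 1
        assert calls[0].site_id == "T1"

    def test_distant_deletion_not_called(self):
        # spans the window, but the deletion sits ~500 bp downstream of it
        r = read("600M2D60M", pos=51)
        assert call_indels_at_site([r], self.site) == []

    def test_read_not_spanning_window_is_not_genotypable(self):
        # alignment ends at 0-based 110, inside the window
        r = read("60M50S", pos=51)
        assert genotypable_reads([r], self.site) == []
        assert call_indels_at_site([r], self.site) == []

    def test_secondary_alignments_ignored(self):
        r = read("200M", pos=51, flag=0x100)
        assert genotypable_reads([r], self.site) == []

    def test_min_flank_enforced(self):
        # spans exactly [95, 125): ok for min_flank 5, not for 6
        r = read("30M", pos=96)
        assert genotypable_reads([r], self.site, min_flank=5) == [r]
        assert genotypable_reads([r], self.site, min_flank=6) == []

    def test_empty_read_set_gives_empty_result(self):
        assert call_indels_at_site([], self.site) == []


class TestTallyAlleles:
    site = TargetSite("T2", GenomicInterval("chr1", 100, 120))

    def _reads(self, n):
        return [read("200M", pos=1, read_id=f"c{i}") for i in range(n)]

    def test_mosaic_fraction(self):
        reads = self._reads(8)
        calls = [
            IndelCall("chr1", 110, "del", 2, read_id=f"c{i}") for i in range(5)
        ]
        tally = tally_alleles(calls, reads, "fish1", self.site)
        assert tally.n_reads_total == 8
        assert tally.n_reads_wt == 3
        assert tally.mutant_fraction == pytest.approx(0.625)
        assert tally.allele_table == {"WT": 3, "del2@110": 5}

    def test_all_wild_type(self):
        tally = tally_alleles([], self._reads(8), "fish1", self.site)
        assert tally.mutant_fraction == 0.0

    def test_two_mutant_alleles(self):
        reads = self._reads(8)
        calls = [IndelCall("chr1", 110, "del", 2, read_id=f"c{i}") for i in range(4)]
        calls += [
            IndelCall("chr1", 110, "ins", 1, inserted_seq="T", read_id=f"c{i}")
            for i in range(4, 8)
        ]
        tally = tally_alleles(calls, reads, "fish1", self.site)
        assert tally.mutant_fraction == 1.0
        assert len(tally.allele_table) == 2
        assert sum(tally.allele_table.values()) == 8

    def test_composite_allele_is_one_key(self):
        reads = self._reads(1)
        calls = [
            IndelCall("chr1", 105, "del", 2, read_id="c0"),
            IndelCall("chr1", 115, "ins", 1, inserted_seq="A", read_id="c0"),
        ]
        tally = tally_alleles(calls, reads, "fish1", self.site)
        assert tally.allele_table == {"del2@105+ins1@115:A": 1}

    def test_zero_reads_flagged_undefined(self):
        tally = tally_alleles([], [], "fish1", self.site)
        assert tally.n_reads_total == 0
        assert tally.mutant_fraction is None

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_read_permutation(self, rnd):
        reads = self._reads(10)
        calls = [IndelCall("chr1", 110, "del", 3, read_id=f"c{i}") for i in range(4)]
        shuffled = list(reads)
        rnd.shuffle(shuffled)
        a = tally_alleles(calls, reads, "f", self.site)
        b = tally_alleles(calls, shuffled, "f", self.site)
        assert a.allele_table == b.allele_table
        assert a.mutant_fraction == b.mutant_fraction
        assert sum(a.allele_table.values()) == a.n_reads_total
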