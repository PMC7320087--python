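"""Alphabet handling, exact-match search, window excision, ORF screening."""

import pytest
from hypothesis import given, strategies as st

from sardmir.errors import AlphabetError, CoordinateError, DomainError
from sardmir.homology import (
    GenomeHit,
    ReferenceMature,
    dedupe_hits,
    exclude_protein_coding,
    extract_precursor_window,
    find_exact_matches,
    find_orfs,
    read_fasta,
)
from sardmir.sequence import normalize_to_rna, reverse_complement

RNA = st.text(alphabet="ACGU", min_size=18, max_size=26)


def _ref(seq, rid="dre-miR-x"):
    return ReferenceMature(rid, rid.split("-")[0], seq)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [("acgt", "ACGU"), ("ACGU", "ACGU"), ("AcGtN", "ACGUN")],
    )
    def test_normalizes(self, raw, expected):
        assert normalize_to_rna(raw) == expected

    def test_rejects_other_symbols(self):
        with pytest.raises(AlphabetError):
            normalize_to_rna("ACGX")


def brute_force_hits(ref, contig_id, contig):
    """Independent oracle: scan every substring on both strands."""
    out = []
    L = len(ref.seq)
    rc = reverse_complement(ref.seq)
    for i in range(len(contig) - L + 1):
        sub = contig[i : i + L]
        if sub == ref.seq:
            out.append((contig_id, i + 1, i + L, "+"))
        if sub == rc:
            out.append((contig_id, i + 1, i + L, "-"))
    return sorted(out)


class TestExactMatch:
    def test_direct_substring(self):
        ref = _ref("ACGUACGUACGUACGUAC")
        genome = {"c": "UU" + ref.seq + "UU"}
        hits = find_exact_matches([ref], genome)
        assert [(h.start, h.end, h.strand) for h in hits] == [(3, 20, "+")]
        assert hits[0].matched_seq == ref.seq

    def test_minus_strand_reported_on_forward_coords(self):
        ref = _ref("ACGGAUUUCCGGAAAUGG")
        genome = {"c": "AA" + reverse_complement(ref.seq) + "CC"}
        hits = find_exact_matches([ref], genome)
        assert [(h.start, h.end, h.strand) for h in hits] == [(3, 20, "-")]

    def test_n_never_matches(self):
        ref = _ref("ACGUACGUACGUACGUAC")
        genome = {"c": "UU" + ref.seq.replace("G", "N", 1) + "UU"}
        assert find_exact_matches([ref], genome) == []

    def test_empty_reference_set_rejected(self):
        with pytest.raises(DomainError):
            find_exact_matches([], {"c": "ACGU" * 10})

    @given(
        ref_seq=RNA,
        background=st.text(alphabet="ACGU", min_size=0, max_size=1000),
        implant_at=st.integers(min_value=0, max_value=1000),
    )
    def test_matches_equal_brute_force_scan(self, ref_seq, background,
                                            implant_at):
        pos = min(implant_at, len(background))
        contig = background[:pos] + ref_seq + background[pos:]
        ref = _ref(ref_seq)
        got = [
            (h.contig, h.start, h.end, h.strand)
            for h in find_exact_matches([ref], {"c": contig})
        ]
        assert sorted(got) == brute_force_hits(ref, "c", contig)

    @given(seq=RNA, background=st.text(alphabet="ACGU", min_size=50,
                                       max_size=300))
    def test_strand_roundtrip(self, seq, background):
        """Reverse-complementing the genome swaps strands, nothing else."""
        contig = background[:25] + seq + background[25:]
        ref = _ref(seq)
        fwd = find_exact_matches([ref], {"c": contig})
        rev = find_exact_matches([ref], {"c": reverse_complement(contig)})
        n = len(contig)
        flipped = sorted(
            (n - h.end + 1, n - h.start + 1, "-" if h.strand == "+" else "+")
            for h in rev
        )
        assert sorted((h.start, h.end, h.strand) for h in fwd) == flipped


class TestWindows:
    def test_boundary_truncation(self):
        ref = _ref("ACGUACGUACGUACGUAC")
        genome = {"c": "GG" + ref.seq + "AAAA"}
        hit = find_exact_matches([ref], genome)[0]
        w = extract_precursor_window(genome, hit, flank=200)
        assert (w.flank_up, w.flank_down) == (2, 4)
        assert w.mature_offset == 2
        assert w.window_seq == genome["c"]

    def test_zero_flank_is_identity(self):
        ref = _ref("ACGUACGUACGUACGUAC")
        genome = {"c": "GG" + ref.seq + "AAAA"}
        hit = find_exact_matches([ref], genome)[0]
        w = extract_precursor_window(genome, hit, flank=0)
        assert w.window_seq == ref.seq
        assert w.mature_offset == 0

    def test_minus_strand_window_is_reverse_complement(self):
        ref = _ref("ACGGAUUUCCGGAAAUGG")
        contig = "AAAGG" + reverse_complement(ref.seq) + "CCUUUAA"
        genome = {"c": contig}
        hit = find_exact_matches([ref], genome)[0]
        w = extract_precursor_window(genome, hit, flank=4)
        # window reads 5'->3' on the hit (minus) strand
        fwd_slice = contig[hit.start - 1 - 4 : hit.end + 4]
        assert w.window_seq == reverse_complement(fwd_slice)
        start = w.mature_offset
        assert w.window_seq[start : start + 18] == ref.seq

    def test_hit_outside_contig_is_coordinate_error(self):
        hit = GenomeHit("c", 90, 110, "+", "r", "A" * 21)
        with pytest.raises(CoordinateError):
            extract_precursor_window({"c": "A" * 100}, hit)


def _window(seq, ref_seq=None):
    ref_seq = ref_seq or seq[: min(20, len(seq))]
    genome = {"c": seq}
    hit = GenomeHit("c", seq.index(ref_seq) + 1,
                    seq.index(ref_seq) + len(ref_seq), "+", "r", ref_seq)
    return extract_precursor_window(genome, hit, flank=400)


class TestOrfExclusion:
    def test_short_window_retained(self):
        w = _window("ACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGU")
        kept, log = exclude_protein_coding([w], min_orf=300)
        assert kept == [w] and log == []

    def test_implanted_303nt_orf_removed(self):
        orf = "AUG" + "GCU" * 99 + "UAA"  # 303 nt, no internal stops
        assert len(orf) == 303
        w = _window("ACGUACGUACGUACGUACGU" + orf + "CCCC")
        kept, log = exclude_protein_coding([w], min_orf=300)
        assert kept == []
        assert log[0]["orf_length"] >= 303

    def test_reverse_strand_orf_detected(self):
        orf = "AUG" + "GCU" * 99 + "UAA"
        w = _window(
            "ACGUACGUACGUACGUACGU" + reverse_complement(orf) + "CCCC"
        )
        kept, _ = exclude_protein_coding([w], min_orf=300)
        assert kept == []

    def test_degenerate_threshold_zero(self):
        w = _window("ACGUACGUACGUACGUACGUAUGUAAGGGG")
        kept, _ = exclude_protein_coding([w], min_orf=0)
        assert kept == []  # contains AUG directly followed by UAA

    def test_mature_overlap_mode_keeps_flank_orfs(self):
        orf = "AUG" + "GCU" * 99 + "UAA"
        seq = "ACGUACGUACGUACGUACGU" + "U" * 40 + orf
        w = _window(seq)  # mature = first 20 nt, ORF far downstream
        kept, _ = exclude_protein_coding([w], min_orf=300,
                                         require_mature_overlap=True)
        assert kept == [w]
        kept, _ = exclude_protein_coding([w], min_orf=300)
        assert kept == []

    def test_find_orfs_reports_frames(self):
        orf = "AUG" + "GGG" * 3 + "UGA"
        hits = find_orfs("AA" + orf)
        assert (2, 2, 15) in hits


class TestDedupe:
    def test_identical_locus_collapsed_smallest_ref_kept(self):
        h1 = GenomeHit("c", 5, 24, "+", "dre-miR-9", "A" * 20)
        h2 = GenomeHit("c", 5, 24, "+", "dre-miR-1", "A" * 20)
        out, n = dedupe_hits([h1, h2])
        assert n == 1 and out[0].ref_id == "dre-miR-1"

    def test_distinct_loci_kept(self):
        h1 = GenomeHit("c", 5, 24, "+", "r", "A" * 20)
        h2 = GenomeHit("c", 50, 69, "+", "r", "A" * 20)
        out, n = dedupe_hits([h1, h2])
        assert len(out) == 2 and n == 0

    def test_empty_input(self):
        assert dedupe_hits([]) == ([], 0)


class TestFastaIO:
    def test_reads_and_normalizes(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1 description\nacgtACGT\nTTTT\n>c2\nGGGG\n")
        got = read_fasta(p)
        assert got == {"c1": "ACGUACGUUUUU", "c2": "GGGG"}
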