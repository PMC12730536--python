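import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xkmir.io_formats import MatureMiRNA, TranscriptRecord
from xkmir.sites import extended_seed, find_sites, reverse_complement, seed

rna = st.text(alphabet="ACGU", min_size=0, max_size=80)


def mirna(seq, mid="m1"):
    return MatureMiRNA(mirna_id=mid, species="zma", sequence=seq)


def transcript(seq, tid="t1", biotype="noncoding"):
    return TranscriptRecord(
        transcript_id=tid, gene_symbol="G", biotype=biotype, sequence=seq
    )


class TestSeedExtraction:
    @pytest.mark.parametrize(
        "sequence, expected",
        [
            ("AGAAGAGAGAGAGUACAGCCU", "GAAGAG"),  # zma-miR529-5p
            ("GCUCACUUCUCUCUCUGUCAGU", "CUCACU"),  # zma-miR156a-3p
        ],
    )
    def test_seed_is_nt2_to_7(self, sequence, expected):
        assert seed(mirna(sequence)) == expected

    @pytest.mark.parametrize(
        "sequence, expected",
        [
            ("GCUCACUUCUCUCUCUGUCAGU", "CUCACUUCUCUC"),
            ("UGGAAGGGGCAUGCAGAGGAG", "GGAAGGGGCAUG"),  # zma-miR528a-5p
        ],
    )
    def test_extended_seed_is_nt2_to_13(self, sequence, expected):
        assert extended_seed(mirna(sequence)) == expected

    def test_too_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            seed("ACGUAC")  # 6 nt
        with pytest.raises(ValueError):
            extended_seed("ACGUACGUACGU")  # 12 nt


class TestReverseComplement:
    def test_hand_computed_example(self):
        assert reverse_complement("CUCACUUCUCUC") == "GAGAGAAGUGAG"

    def test_empty(self):
        assert reverse_complement("") == ""

    @given(rna)
    @settings(max_examples=60)
    def test_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s


def naive_scan(mirnas, transcripts):
    """Independent oracle: O(n*m) sliding-window comparison."""
    out = []
    for t in transcripts:
        for m in mirnas:
            probe = reverse_complement(m.sequence[1:13])
            for i in range(len(t.sequence) - 11):
                if t.sequence[i : i + 12] == probe:
                    out.append((m.mirna_id, t.transcript_id, i))
    return sorted(out)


class TestFindSites:
    def test_planted_probe_found_at_offset(self):
        m = mirna("GCUCACUUCUCUCUCUGUCAGU")  # probe GAGAGAAGUGAG
        t = transcript("C" * 30 + "GAGAGAAGUGAG" + "C" * 20)
        (hit,) = find_sites([m], [t])
        assert (hit.site_start, hit.site_end) == (30, 42)
        assert hit.site_sequence == "GAGAGAAGUGAG"

    def test_sense_sequence_is_not_a_site(self):
        m = mirna("GCUCACUUCUCUCUCUGUCAGU")
        t = transcript(m.sequence)
        assert find_sites([m], [t]) == []

    def test_overlapping_occurrences_all_reported(self):
        m = mirna("GCUCACUUCUCUCUCUGUCAGU")
        # probe = GAGAGAAGUGAG; it overlaps itself with period 9
        t = transcript("GAGAGAAGUGAGAGAAGUGAG")
        hits = find_sites([m], [t])
        assert [h.site_start for h in hits] == [0, 9]
        t2 = transcript("GAGAGAAGUGAG" + "GAGAGAAGUGAG")
        assert [h.site_start for h in find_sites([m], [t2])] == [0, 12]

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_equivalence_with_naive_scan(self, data):
        """Property: the production scan equals a brute-force substring scan,
        on sequences enriched for repeats so spontaneous matches occur."""
        mirnas = [
            mirna(data.draw(st.text(alphabet="ACG", min_size=13, max_size=22)), f"m{i}")
            for i in range(data.draw(st.integers(1, 3)))
        ]
        transcripts = [
            transcript(data.draw(st.text(alphabet="CGU", min_size=12, max_size=120)), f"t{i}")
            for i in range(data.draw(st.integers(1, 3)))
        ]
        # guarantee at least one hit sometimes: splice a probe into the middle
        spliced = transcripts[0].sequence[:5] + reverse_complement(
            extended_seed(mirnas[0])
        ) + transcripts[0].sequence[5:]
        transcripts[0] = transcript(spliced, "t0")
        got = sorted(
            (h.mirna_id, h.transcript_id, h.site_start)
            for h in find_sites(mirnas, transcripts)
        )
        assert got == naive_scan(mirnas, transcripts)

    def test_output_is_deterministically_ordered(self):
        m1 = mirna("GCUCACUUCUCUCUCUGUCAGU", "b")
        m2 = mirna("GCUCACUUCUCUCUCUGUCAGU"[:13] + "AAAA", "a")
        t = transcript("GAGAGAAGUGAG" * 2, "t1")
        hits = find_sites([m1, m2], [t])
        keys = [(h.transcript_id, h.site_start, h.mirna_id) for h in hits]
        assert keys == sorted(keys)
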