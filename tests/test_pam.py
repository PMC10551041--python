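import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_hamming_hits
from ibcrispr.genome_io import GenomeRecord, revcomp
from ibcrispr.pam import (
    PFM,
    MatchHit,
    PamModel,
    build_pfm,
    enumerate_pam_variants,
    hamming_window_scan,
    match_spacer,
    parse_crispr_array,
    protospacer_seq,
    scan_pams,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


def naive_overlapping_count(hay: str, needle: str) -> int:
    return sum(1 for i in range(len(hay) - len(needle) + 1) if hay[i : i + len(needle)] == needle)


class TestPamModel:
    def test_defaults(self):
        m = PamModel()
        assert m.core == "TTA"
        assert set(m.permissive_set) == {"TTA", "CTA", "TCA", "TTG", "TTT"}
        assert m.upstream_free == 2

    def test_core_must_be_permissive(self):
        with pytest.raises(ValueError):
            PamModel(core="GGG", permissive_set=("TTA",))

    def test_classify(self):
        m = PamModel()
        assert m.classify("TTA") == "core"
        assert m.classify("CTA") == "permissive"
        assert m.classify("GGA") == "none"


class TestScanPams:
    def test_plus_strand_trivial(self):
        g = GenomeRecord("c", "TTAGGGGGG")
        sites = scan_pams(g, strands="+")
        assert len(sites) == 1
        assert sites[0].pam_start == 0
        assert sites[0].protospacer_start == 3
        assert protospacer_seq(g, sites[0], 6) == "GGGGGG"

    def test_minus_strand_remapped(self):
        # oracle: scan revcomp(genome) on + and remap coordinates
        g = GenomeRecord("c", "CCTAACC")
        sites = scan_pams(g, strands="-")
        assert len(sites) == 1
        s = sites[0]
        assert s.strand == "-"
        rc = GenomeRecord("c", revcomp(g.sequence))
        rc_sites = scan_pams(rc, strands="+")
        assert len(rc_sites) == 1
        assert s.pam_start == len(g) - 1 - rc_sites[0].pam_start

    def test_count_matches_naive_substring_oracle(self, random_1kb):
        sites = scan_pams(random_1kb)
        fwd = naive_overlapping_count(random_1kb.sequence, "TTA")
        rev = naive_overlapping_count(random_1kb.sequence, "TAA")
        assert len(sites) == fwd + rev

    def test_region_too_small_for_core(self, random_1kb):
        assert scan_pams(random_1kb, region=(0, 2)) == []

    def test_deterministic_order(self, random_1kb):
        sites = scan_pams(random_1kb)
        keys = [(s.strand, s.pam_start) for s in sites]
        assert keys == sorted(keys)

    def test_protospacer_reads_tta_upstream(self, random_1kb):
        # for every site the 3 nt 5' of the protospacer on its strand == core
        g = random_1kb
        for s in scan_pams(g):
            if s.strand == "+":
                assert g.sequence[s.pam_start : s.pam_start + 3] == "TTA"
            else:
                assert revcomp(g.sequence[s.pam_start - 2 : s.pam_start + 1]) == "TTA"

    @given(dna)
    @settings(max_examples=50, deadline=None)
    def test_strand_mirror_property(self, seq):
        g = GenomeRecord("c", seq)
        grc = GenomeRecord("c", revcomp(seq))
        plus = {s.pam_start for s in scan_pams(g, strands="+")}
        minus_of_rc = {len(seq) - 1 - s.pam_start for s in scan_pams(grc, strands="-")}
        assert plus == minus_of_rc

    def test_circular_origin_spanning_core(self):
        g = GenomeRecord("c", "TAGGGGGT", topology="circular")
        sites = scan_pams(g, strands="+")
        assert [s.pam_start for s in sites] == [7]
        assert protospacer_seq(g, sites[0], 4) == "GGGG"


class TestEnumerate:
    def test_nnn_64(self):
        motifs = enumerate_pam_variants("NNN")
        assert len(motifs) == 64
        assert len(set(motifs)) == 64
        assert motifs == sorted(motifs)

    def test_nntta_16(self):
        motifs = enumerate_pam_variants("NNTTA")
        assert len(motifs) == 16
        assert all(m.endswith("TTA") for m in motifs)

    def test_fixed_identity(self):
        assert enumerate_pam_variants("TTA") == ["TTA"]

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=6))
    def test_size_is_power_of_four(self, template):
        motifs = enumerate_pam_variants(template)
        assert len(motifs) == 4 ** template.count("N")
        assert len(set(motifs)) == len(motifs)


class TestPFM:
    def test_five_copies(self):
        p = build_pfm(["TTA"] * 5)
        assert p.counts.sum(axis=0).tolist() == [5, 5, 5]
        assert p.consensus() == "TTA"

    def test_two_sequences(self):
        p = build_pfm(["TTA", "CTA"])
        # column 0: T:1, C:1
        assert p.counts[3, 0] == 1 and p.counts[1, 0] == 1

    def test_random_matches_independent_counter(self):
        rng = np.random.default_rng(9)
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 5)) for _ in range(100)]
        p = build_pfm(seqs)
        # oracle: per-position Counter tally
        from collections import Counter

        for j in range(5):
            tally = Counter(s[j] for s in seqs)
            for bi, b in enumerate("ACGT"):
                assert p.counts[bi, j] == tally[b]

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_pfm(["TTA", "TT"])

    @given(st.lists(st.text(alphabet="ACGT", min_size=4, max_size=4), min_size=1, max_size=30))
    def test_column_sums_conserved(self, seqs):
        p = build_pfm(seqs)
        assert (p.counts.sum(axis=0) == len(seqs)).all()
        p2 = build_pfm(seqs + ["ACGT"])
        assert (p2.counts.sum(axis=0) == p.counts.sum(axis=0) + 1).all()


class TestMatchSpacer:
    def test_verbatim_hit(self):
        t = GenomeRecord("t", "AAAAATTACCGGTTAACCGGAAAAA")
        spacer = "CCGGTTAA"
        hits = match_spacer(spacer, [t], 0)
        exact = [h for h in hits if h.strand == "+"]
        assert exact and exact[0].mismatches == 0
        assert t.sequence[exact[0].offset : exact[0].offset + 8] == spacer

    def test_one_substitution(self):
        t = GenomeRecord("t", "GGGGACGTACGTACGTGGGG")
        spacer = "ACGTACGAACGT"  # one mismatch vs ACGTACGTACGT
        assert not [h for h in match_spacer(spacer, [t], 0) if h.mismatches == 0]
        hits = match_spacer(spacer, [t], 1)
        assert any(h.mismatches == 1 for h in hits)

    def test_flank5_is_upstream_5nt(self):
        t = GenomeRecord("t", "TTTTAACGTACGTACGT")
        hits = [h for h in match_spacer("ACGTACGT", [t], 0) if h.strand == "+" and h.offset == 5]
        assert hits[0].flank5 == "TTTTA"
        assert hits[0].pam_core == "TTA"

    def test_brute_force_equivalence_10kb(self):
        rng = np.random.default_rng(77)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
        t = GenomeRecord("t", seq)
        spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, 12))
        hits = match_spacer(spacer, [t], 3)
        fwd = {(h.offset, h.mismatches) for h in hits if h.strand == "+"}
        assert fwd == set(brute_hamming_hits(seq, spacer, 3))
        rc = revcomp(seq)
        rev = {(len(seq) - i - 12, mm) for i, mm in brute_hamming_hits(rc, spacer, 3)}
        assert {(h.offset, h.mismatches) for h in hits if h.strand == "-"} == rev

    def test_spacer_longer_than_target(self):
        t = GenomeRecord("t", "ACGTACGT")
        assert match_spacer("A" * 20, [t], 2) == []

    def test_short_spacer_rejected(self):
        with pytest.raises(ValueError):
            match_spacer("ACGT", [GenomeRecord("t", "ACGTACGT")], 0)

    def test_sorted_by_mismatch_then_coord(self, random_1kb):
        hits = match_spacer(random_1kb.sequence[100:112], [random_1kb], 3)
        keys = [(h.mismatches, h.target_id, h.offset, h.strand) for h in hits]
        assert keys == sorted(keys)


class TestParseArray:
    REPEAT = "GTTGCAAACCTATGAGGAATTGAAAC"

    def test_two_spacers(self):
        r = self.REPEAT
        seq = r + "AAAAACCCCCGGGGGTTTTTAAAAA" + r + "CACACACACATGTGTGTGTGCACAC" + r
        assert parse_crispr_array(seq, r) == [
            "AAAAACCCCCGGGGGTTTTTAAAAA",
            "CACACACACATGTGTGTGTGCACAC",
        ]

    def test_single_repeat_not_an_array(self):
        with pytest.raises(ValueError, match="not an array"):
            parse_crispr_array(self.REPEAT + "ACGTACGT", self.REPEAT)

    def test_mutated_repeat_tolerated(self):
        r = self.REPEAT
        mut = "A" + r[1:]  # one substitution
        seq = r + "ACGTACGTACGTACGTACGTACGTA" + mut + "TGCATGCATGCATGCATGCATGCAT" + r
        spacers = parse_crispr_array(seq, r, max_repeat_mm=1)
        assert spacers == ["ACGTACGTACGTACGTACGTACGTA", "TGCATGCATGCATGCATGCATGCAT"]

    @given(
        st.lists(
            st.text(alphabet="ACG", min_size=20, max_size=28), min_size=1, max_size=6
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_with_build_array(self, spacers):
        # T-free spacers cannot collide with the T-rich repeat
        import warnings

        from ibcrispr.assembly import build_array

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate spacers are fine here
            arr = build_array(spacers, self.REPEAT, mode_boundary=28)
        assert parse_crispr_array(arr.assembled, self.REPEAT) == list(spacers)


class TestHammingScan:
    @given(dna, st.text(alphabet="ACGT", min_size=1, max_size=10))
    @settings(max_examples=60, deadline=None)
    def test_matches_pure_python(self, target, query):
        got = hamming_window_scan(target, query)
        want = [
            sum(a != b for a, b in zip(target[i : i + len(query)], query))
            for i in range(len(target) - len(query) + 1)
        ]
        assert got.tolist() == want
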