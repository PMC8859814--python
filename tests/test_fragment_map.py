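"""In-silico digestion, rmap/baitmap I/O and bait-probe eligibility."""

import numpy as np
import pytest

from chicbench import (
    HINDIII,
    MBOI,
    BaitDesignRules,
    Enzyme,
    Fragment,
    FragmentMap,
    bait_eligible,
    digest_genome,
    digest_sequence,
    read_baitmap,
    read_rmap,
    write_baitmap,
    write_rmap,
)
from chicbench.fragment_map import find_cut_sites, write_fasta


def brute_force_cuts(seq: str, enzyme: Enzyme) -> list[int]:
    """Position-by-position scan, independent of the implementation's find loop."""
    rec, cuts = enzyme.recognition, []
    for i in range(len(seq) - len(rec) + 1):
        if all(seq[i + k] == rec[k] for k in range(len(rec))):
            cut = i + enzyme.cut_offset + 1
            if 1 < cut <= len(seq):
                cuts.append(cut)
    return cuts


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


class TestDigestSequence:
    @pytest.mark.parametrize(
        "enzyme,expected",
        [
            (HINDIII, [(1, 4), (5, 19)]),
            (MBOI, [(1, 12), (13, 19)]),
        ],
    )
    def test_worked_examples(self, enzyme, expected):
        frags = digest_sequence("GGGAAGCTTCCCGATCAAA", "chr1", enzyme)
        assert [(f.start, f.end) for f in frags] == expected
        assert [f.frag_id for f in frags] == [1, 2]

    def test_no_site_single_fragment(self):
        frags = digest_sequence("ACGT" * 10, "chr1", HINDIII)
        assert [(f.start, f.end) for f in frags] == [(1, 40)]

    def test_overlapping_recognition_matches_all_found(self):
        # GAGA matches at offsets 0 and 2 of GAGAGA: the scan must restart
        # inside the previous match
        enz = Enzyme("toy", "GAGA", 2)
        cuts = find_cut_sites("TTGAGAGATT", HINDIII.__class__("toy", "GAGA", 2))
        assert cuts == brute_force_cuts("TTGAGAGATT", enz) == [5, 7]

    def test_n_never_matches(self):
        assert find_cut_sites("GGGANGCTTCCC", HINDIII) == []

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError, match="empty"):
            digest_sequence("", "chr1", HINDIII)

    def test_invalid_characters_error(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            digest_sequence("ACGTX", "chr1", HINDIII)

    def test_cut_at_position_one_skipped(self):
        # MboI site at the very start: the cut would create an empty fragment
        frags = digest_sequence("GATCAAAA", "chr1", MBOI)
        assert [(f.start, f.end) for f in frags] == [(1, 8)]

    @pytest.mark.parametrize("enzyme", [HINDIII, MBOI], ids=lambda e: e.name)
    def test_agrees_with_brute_force_scanner(self, enzyme, rng):
        for _ in range(60):
            seq = random_seq(rng, 3000)
            got = find_cut_sites(seq, enzyme)
            assert got == brute_force_cuts(seq, enzyme)


class TestEnzyme:
    def test_invalid_recognition_rejected(self):
        with pytest.raises(ValueError):
            Enzyme("bad", "AXGT", 0)
        with pytest.raises(ValueError):
            Enzyme("short", "ACG", 0)
        with pytest.raises(ValueError):
            Enzyme("off", "ACGT", 7)


class TestDigestGenome:
    def test_two_chromosomes_sequential_ids(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nACGTACGT\n>chr2\nGGG\nAAGCTTCC\n")
        fmap = digest_genome(fa, HINDIII)
        assert len(fmap) == 3
        assert list(fmap.frag_ids) == [1, 2, 3]
        assert fmap.chrom_lengths == {"chr1": 8, "chr2": 11}

    def test_partition_identity(self, rng):
        genome = {f"c{k}": random_seq(rng, 5000) for k in range(3)}
        fmap = digest_genome(genome, MBOI)
        for chrom, g in fmap.df.groupby("chrom"):
            assert (g["end"] - g["start"] + 1).sum() == len(genome[chrom])
            assert g["start"].iloc[0] == 1
            assert g["end"].iloc[-1] == len(genome[chrom])

    def test_duplicate_chromosome_rejected(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nACGT\n>chr1\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            digest_genome(fa, HINDIII)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            digest_genome(tmp_path / "nope.fa", HINDIII)

    def test_enzyme_duality_four_cutter_finer(self, rng):
        # every HindIII site co-occurs with a GATC: MboI must cut at least as often
        parts = []
        for _ in range(20):
            parts.append(random_seq(rng, 200).replace("AAGCTT", "AAGATT"))
            parts.append("AAGCTTGATC")
        seq = "".join(parts)
        n_hind = len(digest_sequence(seq, "c", HINDIII))
        n_mbo = len(digest_sequence(seq, "c", MBOI))
        assert n_mbo >= n_hind


class TestRmapIO:
    def test_round_trip_identity(self, six_fragment_map, tmp_path):
        p = tmp_path / "m.rmap"
        write_rmap(p, six_fragment_map)
        assert read_rmap(p) == six_fragment_map
        first = p.read_text()
        write_rmap(p, read_rmap(p))
        assert p.read_text() == first

    def test_gap_rejected_naming_position(self, tmp_path):
        p = tmp_path / "bad.rmap"
        p.write_text("chr1\t1\t100\t1\nchr1\t102\t200\t2\n")
        with pytest.raises(ValueError, match="gap.*100.*102"):
            read_rmap(p)

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "bad.rmap"
        p.write_text("chr1\t1\t100\t1\nchr1\t90\t200\t2\n")
        with pytest.raises(ValueError, match="overlap"):
            read_rmap(p)

    def test_non_integer_coordinates_rejected(self, tmp_path):
        p = tmp_path / "bad.rmap"
        p.write_text("chr1\t1\t100.5\t1\n")
        with pytest.raises(ValueError, match="non-integer"):
            read_rmap(p)

    def test_zero_based_import_matches_shifted(self, six_fragment_map, tmp_path):
        p1 = tmp_path / "one.rmap"
        write_rmap(p1, six_fragment_map)
        p0 = tmp_path / "zero.rmap"
        rows = []
        for line in p1.read_text().splitlines():
            c, s, e, i = line.split("\t")
            rows.append(f"{c}\t{int(s) - 1}\t{e}\t{i}")
        p0.write_text("\n".join(rows) + "\n")
        assert read_rmap(p0, zero_based=True) == six_fragment_map


class TestBaitmapIO:
    def test_round_trip(self, six_fragment_map, bait_map, tmp_path):
        p = tmp_path / "b.baitmap"
        write_baitmap(p, bait_map, six_fragment_map)
        back = read_baitmap(p, six_fragment_map)
        assert back.annotations == bait_map.annotations

    def test_unknown_frag_id_rejected(self, six_fragment_map, tmp_path):
        p = tmp_path / "b.baitmap"
        p.write_text("chr1\t1\t999\t99\tgeneX\n")
        with pytest.raises(ValueError, match="99"):
            read_baitmap(p, six_fragment_map)

    def test_coordinate_mismatch_rejected(self, six_fragment_map, tmp_path):
        p = tmp_path / "b.baitmap"
        p.write_text("chr1\t1\t998\t1\tgeneX\n")
        with pytest.raises(ValueError, match="do not match"):
            read_baitmap(p, six_fragment_map)


class TestBaitEligible:
    def test_uniform_gc_eligible_both_ends(self):
        seq = "ACGT" * 125  # 500 bp, 50% GC
        frag = Fragment("chr1", 1, 500, 1)
        ok, probes = bait_eligible(frag, seq)
        assert ok
        assert {p.terminus for p in probes} == {"left", "right"}
        assert probes[0].start == 1 and probes[0].end == 120
        assert probes[1].start == 381 and probes[1].end == 500

    def test_low_gc_ineligible(self):
        seq = ("AAAAG" * 100)  # GC 20% in every window
        frag = Fragment("chr1", 1, 500, 1)
        ok, probes = bait_eligible(frag, seq)
        assert not ok and probes == []

    def test_short_fragment_ineligible_not_error(self):
        frag = Fragment("chr1", 1, 100, 1)
        ok, probes = bait_eligible(frag, "ACGT" * 25)
        assert not ok and probes == []

    def test_n_blocks_all_but_one_window(self):
        # with no Ns allowed, the N at index 2 taints windows at offsets 0-2;
        # offset 3 is the first clean window
        rules = BaitDesignRules(probe_length=10, max_terminus_distance=3,
                                max_consecutive_n=0, gc_min=0.25, gc_max=0.65)
        seq = "ACN" + "ACGTACGTAC" + "TTTTTTT"
        frag = Fragment("chr1", 1, len(seq), 1)
        ok, probes = bait_eligible(frag, seq, rules)
        # independent exhaustive scan over candidate windows
        expected = None
        for off in range(0, min(rules.max_terminus_distance, len(seq) - 10) + 1):
            w = seq[off : off + 10]
            gc = (w.count("G") + w.count("C")) / 10
            if rules.gc_min <= gc <= rules.gc_max and "N" not in w:
                expected = off + 1
                break
        assert ok
        left = [p for p in probes if p.terminus == "left"]
        assert left and left[0].start == expected == 4

    def test_sequence_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            bait_eligible(Fragment("chr1", 1, 10, 1), "ACGT")

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            BaitDesignRules(gc_min=0.7, gc_max=0.6)


class TestFragmentMapInvariants:
    def test_tiling_on_random_chromosomes(self, rng):
        for _ in range(40):
            seq = random_seq(rng, int(rng.integers(500, 3000)))
            frags = digest_sequence(seq, "c", MBOI)
            assert frags[0].start == 1
            assert frags[-1].end == len(seq)
            for a, b in zip(frags, frags[1:]):
                assert b.start == a.end + 1

    def test_locate_and_resolve(self, six_fragment_map):
        assert six_fragment_map.locate("chr1", 1500).frag_id == 2
        assert six_fragment_map.resolve_exact("chr1", 1000, 2000) == 2
        with pytest.raises(KeyError):
            six_fragment_map.resolve_exact("chr1", 1000, 1999)

    def test_fasta_round_trip(self, rng, tmp_path):
        from chicbench.fragment_map import read_fasta

        genome = {"chr1": random_seq(rng, 301), "chr2": random_seq(rng, 80)}
        p = tmp_path / "g.fa"
        write_fasta(p, genome, width=60)
        assert read_fasta(p) == genome
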