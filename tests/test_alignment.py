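"""SAM streaming, NH grouping, CIGAR decomposition and mate pairing."""

import pytest

from mmcount.alignment import (
    FragmentHit,
    HitGroup,
    HitGroupStream,
    LibraryConfig,
    ReadHit,
    _cigar_intervals,
    pair_fragments,
    stream_hit_groups,
)
from mmcount.fixtures import make_random_scenario
from conftest import shuffle_sam, write_scenario


def make_hit(blocks, skips=(), mate=1, strand="+", chrom="c1",
             name="r", nh=1):
    size = sum(e - s for s, e in blocks)
    return ReadHit(name, chrom, strand, tuple(blocks), tuple(skips),
                   size, mate, nh)


class TestCigarIntervals:
    @pytest.mark.parametrize("pos,cigar,blocks,skips,size", [
        (100, [(0, 50)], [(100, 150)], [], 50),
        (100, [(0, 50), (3, 10), (0, 50)],
         [(100, 150), (160, 210)], [(150, 160)], 100),       # 50M10N50M
        (100, [(0, 20), (2, 5), (0, 30)],
         [(100, 120), (125, 155)], [], 50),                  # 20M5D30M
        (100, [(4, 5), (0, 20), (1, 3), (0, 10), (5, 2)],
         [(100, 130)], [], 30),                              # 5S20M3I10M2H
    ])
    def test_blocks_skips_size(self, pos, cigar, blocks, skips, size):
        b, s, n = _cigar_intervals(pos, cigar)
        assert list(b) == blocks
        assert list(s) == skips
        assert n == size


class TestStreaming:
    def test_worked_example_groups(self, worked_scenario, worked_files):
        _, sam = worked_files
        groups = list(stream_hit_groups(sam))
        assert len(groups) == 6
        two_hit = sorted(g.read_name for g in groups if len(g.hits1) == 2)
        assert two_hit == ["read2", "read4", "read6"]
        assert all(g.complete for g in groups)

    def test_shuffled_records_give_same_groups(self, tmp_path):
        scenario = make_random_scenario(3, n_genes=8, n_reads=40)
        _, sam = write_scenario(scenario, tmp_path)
        shuffled = tmp_path / "shuffled.sam"
        shuffle_sam(sam, shuffled)

        def snapshot(path):
            return sorted(
                (g.read_name, sorted(h.blocks for h in g.hits1),
                 sorted(h.blocks for h in g.hits2))
                for g in stream_hit_groups(path)
            )

        assert snapshot(sam) == snapshot(shuffled)

    def test_one_group_per_mapped_read_name(self, tmp_path):
        scenario = make_random_scenario(5, n_genes=10, n_reads=50)
        _, sam = write_scenario(scenario, tmp_path)
        names = [g.read_name for g in stream_hit_groups(sam)]
        assert sorted(names) == sorted(r.name for r in scenario.reads)
        assert len(set(names)) == len(names)

    def test_missing_nh_falls_back_to_name_buffering(self, tmp_path,
                                                     worked_files, caplog):
        _, sam = worked_files
        stripped = tmp_path / "no_nh.sam"
        stripped.write_text(
            "\n".join(
                line.replace("\tNH:i:1", "").replace("\tNH:i:2", "")
                for line in sam.read_text().splitlines()
            ) + "\n"
        )
        with caplog.at_level("WARNING"):
            groups = {g.read_name: g for g in stream_hit_groups(stripped)}
        assert len(groups) == 6
        assert len(groups["read2"].hits1) == 2
        assert sum("NH" in r.message for r in caplog.records) == 1

    def test_sorted_input_streams_with_small_buffer(self, tmp_path):
        """Position-sorted input with honest NH tags keeps the pending
        buffer bounded by the reads whose hit sets span the window."""
        scenario = make_random_scenario(7, n_genes=10, n_reads=80,
                                        duplication_rate=0.5)
        gtf, sam = write_scenario(scenario, tmp_path, sort=True)
        stream = HitGroupStream(sam)
        n_multi = sum(
            1 for g in stream if any((h.nh or 1) > 1 for h in g.hits1)
        )
        assert 0 < n_multi
        assert stream.max_pending <= n_multi + 1

    def test_unmapped_and_secondary_handling(self, tmp_path):
        sam = tmp_path / "u.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:c1\tLN:10000\n"
            "r1\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*\n"              # unmapped
            "r2\t0\tc1\t101\t60\t4M\t*\t0\t0\tAAAA\t*\tNH:i:2\n"
            "r2\t256\tc1\t201\t60\t4M\t*\t0\t0\tAAAA\t*\tNH:i:2\n"
            "r3\t2048\tc1\t301\t60\t4M\t*\t0\t0\tAAAA\t*\tNH:i:1\n"  # suppl
        )
        groups = {g.read_name: g for g in stream_hit_groups(sam)}
        assert set(groups) == {"r2"}
        assert len(groups["r2"].hits1) == 2  # secondary records are hits


class TestPairing:
    def test_proper_fr_pair_gives_one_fragment(self):
        h1 = make_hit([(100, 150)], mate=1, strand="+", name="p")
        h2 = make_hit([(300, 350)], mate=2, strand="-", name="p")
        group = HitGroup("p", [h1], [h2], complete=True)
        lib = LibraryConfig(paired=True)
        (frag,) = pair_fragments(group, lib)
        assert frag.blocks == ((100, 150), (300, 350))
        assert frag.size == 100
        assert frag.strand1 == "+"

    def test_chimeric_mates_are_discarded(self):
        h1 = make_hit([(100, 150)], mate=1, chrom="c1", name="p")
        h2 = make_hit([(300, 350)], mate=2, strand="-", chrom="c2", name="p")
        group = HitGroup("p", [h1], [h2], complete=True)
        lib = LibraryConfig(paired=True, require_both_mates=False,
                            discard_chimeric=True)
        assert pair_fragments(group, lib) == []

    def test_multihit_mates_pair_by_smallest_hull(self):
        # two loci 10 kb apart; each mate has a hit at both
        h1a = make_hit([(1_000, 1_100)], mate=1, strand="+", nh=2)
        h1b = make_hit([(11_000, 11_100)], mate=1, strand="+", nh=2)
        h2a = make_hit([(1_200, 1_300)], mate=2, strand="-", nh=2)
        h2b = make_hit([(11_200, 11_300)], mate=2, strand="-", nh=2)
        group = HitGroup("p", [h1a, h1b], [h2b, h2a], complete=True)
        lib = LibraryConfig(paired=True)
        frags = pair_fragments(group, lib)
        assert len(frags) == 2
        spans = sorted((f.start, f.end) for f in frags)
        assert spans == [(1_000, 1_300), (11_000, 11_300)]

    def test_orientation_filter(self):
        h1 = make_hit([(100, 150)], mate=1, strand="+")
        h2 = make_hit([(300, 350)], mate=2, strand="+")
        group = HitGroup("p", [h1], [h2], complete=True)
        assert pair_fragments(
            group, LibraryConfig(paired=True, orientation="fr")
        ) == []
        assert len(pair_fragments(
            group, LibraryConfig(paired=True, orientation="ff")
        )) == 1

    def test_single_end_hits_are_their_own_fragments(self):
        hits = [make_hit([(100, 150)]), make_hit([(900, 950)])]
        group = HitGroup("s", hits, [], complete=True)
        frags = pair_fragments(group, LibraryConfig(paired=False))
        assert [f.blocks for f in frags] == [((100, 150),), ((900, 950),)]

    def test_spliced_fragment_properties(self):
        h = make_hit([(100, 150), (250, 300)], skips=[(150, 250)])
        frag = FragmentHit("c1", (h,))
        assert frag.spliced
        assert frag.size == 100
        assert (frag.start, frag.end) == (100, 300)
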