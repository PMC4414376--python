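import pytest

from conftest import make_pair
from microsynt.genome_io import Assembly, ChromosomeMap
from microsynt.synteny_map import (
    SyntenyParams,
    build_blocks,
    build_tracks,
    classify_rearrangements,
    link_scaffolds,
    place_unplaced,
    summarize_synteny,
)


def _track(pairs, chrom_ref=None, chrom_partner=None):
    return build_tracks(pairs, chrom_ref, chrom_partner)


class TestBuildTracks:
    def test_sorting_and_grouping(self):
        pairs = [
            make_pair("r1", 3000, "p1", 3000),
            make_pair("r1", 1000, "p1", 1000),
            make_pair("r2", 500, "p2", 500),
        ]
        tracks = _track(pairs)
        assert [t.ref_scaffold for t in tracks] == ["r1", "r2"]
        assert [m.ref_start for m in tracks[0].markers] == [1000, 3000]

    def test_empty(self):
        assert _track([]) == []


class TestBuildBlocks:
    def test_fully_concordant_single_block(self):
        pairs = [make_pair("r1", i * 1000, "p1", i * 1000) for i in range(10)]
        blocks = build_blocks(_track(pairs))
        assert len(blocks) == 1
        assert blocks[0].n_markers == 10
        assert blocks[0].orientation == "+"

    def test_single_discordant_locus_ignored(self):
        """An isolated marker pointing elsewhere does not break the chain."""
        pairs = [make_pair("r1", i * 1000, "p1", i * 1000) for i in range(10)]
        pairs[4] = make_pair("r1", 4000, "pX", 4000)
        blocks = build_blocks(_track(pairs))
        assert len(blocks) == 1
        assert blocks[0].n_markers == 9

    def test_inversion_splits_into_three_blocks(self):
        """Markers 4..7 reversed on the partner -> blocks (+, -, +)."""
        ppos = [0, 1000, 2000, 3000, 7000, 6000, 5000, 4000, 8000, 9000]
        orient = ["+"] * 4 + ["-"] * 4 + ["+"] * 2
        pairs = [
            make_pair("r1", i * 1000, "p1", ppos[i], orient[i]) for i in range(10)
        ]
        blocks = build_blocks(_track(pairs))
        assert [(b.orientation, b.n_markers) for b in blocks] == [
            ("+", 4), ("-", 4), ("+", 2)
        ]
        assert blocks[0].ref_range.end <= blocks[1].ref_range.start
        assert blocks[1].ref_range.end <= blocks[2].ref_range.start

    def test_blocks_never_overlap_and_are_monotone(self):
        ppos = [0, 1000, 9000, 8000, 2000, 3000, 7000, 6000, 5000, 4000]
        orient = ["+", "+", "-", "-", "+", "+", "-", "-", "-", "-"]
        pairs = [
            make_pair("r1", i * 1000, "p1", ppos[i], orient[i]) for i in range(10)
        ]
        blocks = build_blocks(_track(pairs))
        for b1, b2 in zip(blocks, blocks[1:]):
            assert b1.ref_range.end <= b2.ref_range.start
        for b in blocks:
            pp = [m.partner_start for m in b.markers]
            assert pp == sorted(pp) or pp == sorted(pp, reverse=True)

    def test_short_blocks_discarded(self):
        pairs = [make_pair("r1", 0, "p1", 0)]
        assert build_blocks(_track(pairs)) == []

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SyntenyParams(max_singleton_ignore=2, min_break_support=2)


class TestLinkScaffolds:
    def test_partner_bridges_two_reference_scaffolds(self):
        pairs = [make_pair("rA", i * 1000, "p1", i * 1000) for i in range(5)]
        pairs += [
            make_pair("rB", i * 1000, "p1", 5000 + i * 1000) for i in range(5)
        ]
        blocks = build_blocks(_track(pairs))
        links, conflicts = link_scaffolds(blocks)
        assert conflicts == []
        assert len(links) == 1
        link = links[0]
        assert {link.ref_scaffold_1, link.ref_scaffold_2} == {"rA", "rB"}
        assert link.end_1 == "end" and link.end_2 == "start"

    def test_no_bridging_partner_no_links(self):
        pairs = [make_pair("rA", i * 1000, "p1", i * 1000) for i in range(5)]
        pairs += [make_pair("rB", i * 1000, "p2", i * 1000) for i in range(5)]
        links, _ = link_scaffolds(build_blocks(_track(pairs)))
        assert links == []

    def test_chained_links_use_each_end_once(self):
        # p1 bridges rA-end to rB-start; p2 bridges rB-end to rC-start
        pairs = [make_pair("rA", i * 1000, "p1", i * 1000) for i in range(5)]
        pairs += [make_pair("rB", i * 1000, "p1", 5000 + i * 1000) for i in range(5)]
        pairs += [make_pair("rB", 5000 + i * 1000, "p2", i * 1000) for i in range(3)]
        pairs += [make_pair("rC", i * 1000, "p2", 3000 + i * 1000) for i in range(3)]
        blocks = build_blocks(_track(pairs))
        links, conflicts = link_scaffolds(blocks)
        assert conflicts == []
        kept = {
            frozenset([l.ref_scaffold_1, l.ref_scaffold_2]) for l in links
        }
        assert kept == {frozenset(["rA", "rB"]), frozenset(["rB", "rC"])}
        ends = [
            (l.ref_scaffold_1, l.end_1) for l in links
        ] + [(l.ref_scaffold_2, l.end_2) for l in links]
        assert len(ends) == len(set(ends))  # each scaffold end linked once


class TestPlaceUnplaced:
    def _setup(self, n_support):
        cm_ref = ChromosomeMap({"rA": "LG01"})  # rU absent = unplaced
        pairs = [make_pair("rA", i * 1000, "p1", i * 1000) for i in range(5)]
        pairs += [
            make_pair("rU", i * 1000, "p1", 10000 + i * 1000)
            for i in range(n_support)
        ]
        blocks = build_blocks(_track(pairs, cm_ref))
        return blocks, cm_ref

    def test_placed_with_three_consecutive_markers(self):
        blocks, cm = self._setup(3)
        _, placements = place_unplaced(blocks, cm)
        assert [(p.ref_scaffold, p.chromosome) for p in placements] == [("rU", "LG01")]

    def test_not_placed_below_support_threshold(self):
        blocks, cm = self._setup(2)
        _, placements = place_unplaced(blocks, cm)
        assert placements == []

    def test_ambiguous_context_not_placed(self):
        cm_ref = ChromosomeMap({"rA": "LG01", "rB": "LG02"})
        pairs = [make_pair("rA", i * 1000, "p1", i * 1000) for i in range(3)]
        pairs += [make_pair("rB", i * 1000, "p1", 20000 + i * 1000) for i in range(3)]
        pairs += [make_pair("rU", i * 1000, "p1", 10000 + i * 1000) for i in range(3)]
        blocks = build_blocks(_track(pairs, cm_ref))
        _, placements = place_unplaced(blocks, cm_ref)
        assert placements == []

    def test_input_map_never_modified(self):
        blocks, cm = self._setup(3)
        before = dict(cm.entries)
        place_unplaced(blocks, cm)
        assert cm.entries == before


class TestClassifyRearrangements:
    def test_collinear_genomes_no_events(self):
        cm_r = ChromosomeMap({"r1": "c1"})
        cm_p = ChromosomeMap({"p1": "c1"})
        pairs = [make_pair("r1", i * 1000, "p1", i * 1000) for i in range(10)]
        blocks = build_blocks(_track(pairs, cm_r, cm_p))
        assert classify_rearrangements(blocks, cm_r, cm_p) == []

    def test_inversion_counted_once(self):
        """+,-,+ block run is one intra event despite two flip boundaries."""
        cm_r = ChromosomeMap({"r1": "c1"})
        cm_p = ChromosomeMap({"p1": "c1"})
        ppos = [0, 1000, 2000, 3000, 7000, 6000, 5000, 4000, 8000, 9000]
        orient = ["+"] * 4 + ["-"] * 4 + ["+"] * 2
        pairs = [
            make_pair("r1", i * 1000, "p1", ppos[i], orient[i]) for i in range(10)
        ]
        blocks = build_blocks(_track(pairs, cm_r, cm_p))
        events = classify_rearrangements(blocks, cm_r, cm_p)
        assert [e.type for e in events] == ["intra"]
        # the breakpoints bracket the inverted segment
        (bp1, bp2) = events[0].breakpoints
        assert bp1[0] <= 4000 <= bp1[1] + 12
        assert bp2[0] <= 8000 <= bp2[1] + 12

    def test_translocated_segment_counted_once(self):
        """chr1-chr2-chr1 partner context is one inter event."""
        cm_r = ChromosomeMap({"r1": "c1"})
        cm_p = ChromosomeMap({"p1": "c1", "p2": "c2"})
        pairs = [make_pair("r1", i * 1000, "p1", i * 1000) for i in range(4)]
        pairs += [make_pair("r1", (4 + i) * 1000, "p2", i * 1000) for i in range(3)]
        pairs += [make_pair("r1", (7 + i) * 1000, "p1", (4 + i) * 1000) for i in range(4)]
        blocks = build_blocks(_track(pairs, cm_r, cm_p))
        events = classify_rearrangements(blocks, cm_r, cm_p)
        assert [e.type for e in events] == ["inter"]
        assert events[0].partner_context == "c2"


class TestSummarize:
    def test_arithmetic(self):
        asm_r = Assembly(name="r", scaffolds={"r1": "A" * 24_000})
        asm_p = Assembly(name="p", scaffolds={"p1": "A" * 24_000})
        # three blocks of ref spans 2k, 4k, 6k
        pairs = []
        pos = 0
        for span, pscaf in ((2000, "p1"), (4000, "p2"), (6000, "p3")):
            pairs.append(make_pair("r1", pos, pscaf, 0))
            pairs.append(make_pair("r1", pos + span - 12, pscaf, span - 12))
            pos += span + 3000
        blocks = build_blocks(_track(pairs))
        s = summarize_synteny(blocks, [], asm_r, asm_p)
        assert s.n_blocks == 3
        assert s.ref_len_mean == 4000
        assert s.ref_len_median == 4000
        assert s.ref_len_total == 12000
        assert s.coverage_ref == pytest.approx(0.5)

    def test_empty_blocks(self):
        asm = Assembly(name="r", scaffolds={"r1": "ACGT"})
        s = summarize_synteny([], [], asm, asm)
        assert s.n_blocks == 0 and s.coverage_ref == 0.0
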