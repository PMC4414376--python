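"""Synteny-block construction, scaffold linking/placement, rearrangement calls.

One assembly is the *reference* (its scaffolds define marker order), the
other the *partner*.  Homologous markers on each reference scaffold, sorted
by reference coordinate, are chained greedily into blocks: a block extends
while the next marker keeps the same partner scaffold, the same relative
orientation, and a monotone partner coordinate.  Isolated discordant markers
(run length <= ``max_singleton_ignore``) are ignored and the chain continues;
longer discordant runs terminate the block.  Blocks need at least two
supporting markers.

Rearrangements are read off the block sequence along each reference
scaffold: a maximal run of blocks whose partner chromosome differs from the
scaffold's modal partner chromosome is one inter-chromosomal event; within
the modal chromosome, a maximal run of blocks in the minority orientation
(or a same-scaffold order discontinuity) is one intra-chromosomal event.
Boundaries that coincide with scaffold ends are never events: a draft
assembly break is not biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean, median

from microsynt.genome_io import Assembly, ChromosomeMap, Interval
from microsynt.marker_match import MarkerPair

__all__ = [
    "OrderedMarkerTrack",
    "Placement",
    "RearrangementEvent",
    "ScaffoldLink",
    "SyntenyBlock",
    "SyntenyParams",
    "SyntenySummary",
    "TrackMarker",
    "build_blocks",
    "build_tracks",
    "classify_rearrangements",
    "link_scaffolds",
    "place_unplaced",
    "summarize_synteny",
]

UNPLACED = "unplaced"


@dataclass(frozen=True)
class SyntenyParams:
    max_singleton_ignore: int = 1   # discordant run length that is ignored
    min_break_support: int = 2      # discordant run length that breaks a block
    min_placement_support: int = 3  # consecutive markers to place an unplaced scaffold

    def __post_init__(self) -> None:
        if self.min_break_support <= self.max_singleton_ignore:
            raise ValueError("min_break_support must exceed max_singleton_ignore")


@dataclass(frozen=True)
class TrackMarker:
    """One homologous marker as seen from the reference side."""

    pair: MarkerPair

    @property
    def ref_scaffold(self) -> str:
        return self.pair.locus_a.scaffold

    @property
    def ref_start(self) -> int:
        return self.pair.locus_a.start

    @property
    def ref_end(self) -> int:
        return self.pair.locus_a.end

    @property
    def partner_scaffold(self) -> str:
        return self.pair.locus_b.scaffold

    @property
    def partner_start(self) -> int:
        return self.pair.locus_b.start

    @property
    def partner_end(self) -> int:
        return self.pair.locus_b.end

    @property
    def orientation(self) -> str:
        return self.pair.orientation


@dataclass
class OrderedMarkerTrack:
    ref_scaffold: str
    markers: list[TrackMarker]
    ref_chromosome: str = UNPLACED


@dataclass
class SyntenyBlock:
    ref_range: Interval
    partner_scaffold: str
    partner_range: Interval
    orientation: str
    n_markers: int
    ref_chromosome: str = UNPLACED
    partner_chromosome: str = UNPLACED
    markers: list[TrackMarker] = field(default_factory=list, repr=False)
    placed_chromosome: str | None = None  # filled by place_unplaced

    @property
    def ref_scaffold(self) -> str:
        return self.ref_range.scaffold

    @property
    def ref_span(self) -> int:
        return len(self.ref_range)

    @property
    def partner_span(self) -> int:
        return len(self.partner_range)


@dataclass(frozen=True)
class ScaffoldLink:
    ref_scaffold_1: str
    end_1: str  # "start" | "end"
    ref_scaffold_2: str
    end_2: str
    partner_scaffold: str
    support: int


@dataclass(frozen=True)
class Placement:
    ref_scaffold: str
    chromosome: str
    via_partner_scaffold: str
    n_support: int


@dataclass(frozen=True)
class RearrangementEvent:
    type: str  # "intra" | "inter"
    ref_scaffold: str
    ref_chromosome: str
    partner_context: str
    # inter-marker intervals (ref coordinates) bracketing the event's edges
    breakpoints: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class SyntenySummary:
    n_blocks: int
    ref_len_mean: float
    ref_len_median: float
    ref_len_min: int
    ref_len_max: int
    ref_len_total: int
    partner_len_total: int
    n_ref_scaffolds_covered: int
    coverage_ref: float
    coverage_partner: float
    n_large_blocks: int
    n_intra: int
    n_inter: int


def build_tracks(
    pairs: list[MarkerPair],
    chrom_map_ref: ChromosomeMap | None = None,
    chrom_map_partner: ChromosomeMap | None = None,
) -> list[OrderedMarkerTrack]:
    """One track per reference scaffold, markers sorted by reference coordinate."""
    by_scaffold: dict[str, list[TrackMarker]] = {}
    for p in pairs:
        m = TrackMarker(pair=p)
        by_scaffold.setdefault(m.ref_scaffold, []).append(m)
    tracks = []
    for sid in sorted(by_scaffold):
        markers = sorted(by_scaffold[sid], key=lambda m: m.ref_start)
        chrom = UNPLACED
        if chrom_map_ref is not None:
            chrom = chrom_map_ref.chromosome(sid) or UNPLACED
        tracks.append(
            OrderedMarkerTrack(ref_scaffold=sid, markers=markers, ref_chromosome=chrom)
        )
    # partner chromosome annotation is resolved lazily in build_blocks
    if chrom_map_partner is not None:
        for t in tracks:
            t._chrom_map_partner = chrom_map_partner  # type: ignore[attr-defined]
    return tracks


def _concordant(m: TrackMarker, scaffold: str, orientation: str, last_ppos: int) -> bool:
    if m.partner_scaffold != scaffold or m.orientation != orientation:
        return False
    if orientation == "+":
        return m.partner_start >= last_ppos
    return m.partner_start <= last_ppos


def build_blocks(
    tracks: list[OrderedMarkerTrack],
    params: SyntenyParams | None = None,
    chrom_map_partner: ChromosomeMap | None = None,
) -> list[SyntenyBlock]:
    """Greedy left-to-right chaining of each track into synteny blocks."""
    params = params or SyntenyParams()
    blocks: list[SyntenyBlock] = []
    for track in tracks:
        ms = track.markers
        cmp_map = chrom_map_partner or getattr(track, "_chrom_map_partner", None)
        i = 0
        n = len(ms)
        while i < n:
            seed = ms[i]
            members = [seed]
            scaffold = seed.partner_scaffold
            orientation = seed.orientation
            last_ppos = seed.partner_start
            j = i + 1
            while j < n:
                if _concordant(ms[j], scaffold, orientation, last_ppos):
                    members.append(ms[j])
                    last_ppos = ms[j].partner_start
                    j += 1
                    continue
                # measure the discordant run
                r = j
                while r < n and not _concordant(ms[r], scaffold, orientation, last_ppos):
                    r += 1
                run = r - j
                if run <= params.max_singleton_ignore and r < n:
                    j = r  # skip (ignore) the run, resume the chain
                    continue
                break  # run breaks the block (or track ends inside the run)
            if len(members) >= 2:
                blocks.append(_make_block(track, members, orientation, cmp_map))
            i = j
    return blocks


def _make_block(
    track: OrderedMarkerTrack,
    members: list[TrackMarker],
    orientation: str,
    chrom_map_partner: ChromosomeMap | None,
) -> SyntenyBlock:
    ref_range = Interval(track.ref_scaffold, members[0].ref_start, members[-1].ref_end)
    pstarts = [m.partner_start for m in members]
    pends = [m.partner_end for m in members]
    partner_scaffold = members[0].partner_scaffold
    partner_range = Interval(partner_scaffold, min(pstarts), max(pends))
    pchrom = UNPLACED
    if chrom_map_partner is not None:
        pchrom = chrom_map_partner.chromosome(partner_scaffold) or UNPLACED
    return SyntenyBlock(
        ref_range=ref_range,
        partner_scaffold=partner_scaffold,
        partner_range=partner_range,
        orientation=orientation,
        n_markers=len(members),
        ref_chromosome=track.ref_chromosome,
        partner_chromosome=pchrom,
        markers=members,
    )


def _blocks_by_ref(blocks: list[SyntenyBlock]) -> dict[str, list[SyntenyBlock]]:
    by_ref: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_ref.setdefault(b.ref_scaffold, []).append(b)
    for bs in by_ref.values():
        bs.sort(key=lambda b: b.ref_range.start)
    return by_ref


def link_scaffolds(
    blocks: list[SyntenyBlock],
    tracks: list[OrderedMarkerTrack] | None = None,
    params: SyntenyParams | None = None,
) -> tuple[list[ScaffoldLink], list[str]]:
    """Partner scaffolds bridging the ends of two reference scaffolds.

    Two reference scaffolds are linked when one partner scaffold carries
    consecutive blocks that sit at a terminal end of each.  Each reference
    scaffold end joins at most one link; conflicts keep the better-supported
    link and are reported as messages.
    """
    params = params or SyntenyParams()
    by_ref = _blocks_by_ref(blocks)
    by_partner: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_partner.setdefault(b.partner_scaffold, []).append(b)
    candidates: list[ScaffoldLink] = []
    for pid, bs in by_partner.items():
        bs = sorted(bs, key=lambda b: b.partner_range.start)
        for b1, b2 in zip(bs, bs[1:]):
            if b1.ref_scaffold == b2.ref_scaffold:
                continue
            end1 = "end" if b1.orientation == "+" else "start"
            end2 = "start" if b2.orientation == "+" else "end"
            if not _is_terminal(by_ref, b1, end1) or not _is_terminal(by_ref, b2, end2):
                continue
            candidates.append(
                ScaffoldLink(
                    ref_scaffold_1=b1.ref_scaffold,
                    end_1=end1,
                    ref_scaffold_2=b2.ref_scaffold,
                    end_2=end2,
                    partner_scaffold=pid,
                    support=min(b1.n_markers, b2.n_markers),
                )
            )
    # resolve: each (scaffold, end) in at most one link, best support wins
    candidates.sort(key=lambda l: -l.support)
    taken: set[tuple[str, str]] = set()
    links: list[ScaffoldLink] = []
    conflicts: list[str] = []
    for link in candidates:
        k1 = (link.ref_scaffold_1, link.end_1)
        k2 = (link.ref_scaffold_2, link.end_2)
        if k1 in taken or k2 in taken:
            conflicts.append(
                f"link {link.ref_scaffold_1}:{link.end_1} - "
                f"{link.ref_scaffold_2}:{link.end_2} via {link.partner_scaffold} "
                f"(support {link.support}) dropped: end already linked"
            )
            continue
        taken.update((k1, k2))
        links.append(link)
    return links, conflicts


def _is_terminal(
    by_ref: dict[str, list[SyntenyBlock]], block: SyntenyBlock, end: str
) -> bool:
    bs = by_ref[block.ref_scaffold]
    return block is (bs[0] if end == "start" else bs[-1])


def place_unplaced(
    blocks: list[SyntenyBlock],
    chrom_map_ref: ChromosomeMap,
    chrom_map_partner: ChromosomeMap | None = None,
    params: SyntenyParams | None = None,
) -> tuple[list[SyntenyBlock], list[Placement]]:
    """Putatively place unplaced reference scaffolds from their partner context.

    An unplaced reference scaffold is assigned a chromosome when a block of at
    least ``min_placement_support`` consecutive markers ties it to a partner
    scaffold whose chromosome is known — either directly from the partner
    chromosome map, or inferred from placed reference scaffolds syntenic to
    the same partner scaffold.  The input chromosome map is never modified;
    placements are annotations on the returned blocks.
    """
    params = params or SyntenyParams()
    # partner scaffold -> set of ref chromosomes of placed ref scaffolds
    inferred: dict[str, set[str]] = {}
    for b in blocks:
        chrom = chrom_map_ref.chromosome(b.ref_scaffold)
        if chrom is not None:
            inferred.setdefault(b.partner_scaffold, set()).add(chrom)
    placements: list[Placement] = []
    placed: dict[str, Placement] = {}
    for b in blocks:
        if chrom_map_ref.is_placed(b.ref_scaffold):
            continue
        if b.n_markers < params.min_placement_support:
            continue
        chroms: set[str] = set()
        if chrom_map_partner is not None:
            pc = chrom_map_partner.chromosome(b.partner_scaffold)
            if pc is not None:
                chroms.add(pc)
        chroms |= inferred.get(b.partner_scaffold, set())
        if len(chroms) != 1:
            continue  # no or ambiguous chromosome context
        chrom = chroms.pop()
        prev = placed.get(b.ref_scaffold)
        if prev is None or b.n_markers > prev.n_support:
            placed[b.ref_scaffold] = Placement(
                ref_scaffold=b.ref_scaffold,
                chromosome=chrom,
                via_partner_scaffold=b.partner_scaffold,
                n_support=b.n_markers,
            )
    placements = sorted(placed.values(), key=lambda p: p.ref_scaffold)
    for b in blocks:
        p = placed.get(b.ref_scaffold)
        if p is not None:
            b.placed_chromosome = p.chromosome
    return blocks, placements


def _runs(labels: list, context) -> list[tuple[int, int]]:
    """Maximal runs (half-open index ranges) of labels differing from context."""
    runs = []
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] == context:
            i += 1
            continue
        j = i
        while j < n and labels[j] != context:
            j += 1
        runs.append((i, j))
        i = j
    return runs


def classify_rearrangements(
    blocks: list[SyntenyBlock],
    chrom_map_ref: ChromosomeMap | None = None,
    chrom_map_partner: ChromosomeMap | None = None,
) -> list[RearrangementEvent]:
    """Event calls from block adjacencies along each reference scaffold.

    An inversion is one intra event even though it creates two orientation
    flips; a translocated insertion is one inter event even though it creates
    two chromosome switches: maximal discordant runs are counted, not
    boundaries.
    """
    events: list[RearrangementEvent] = []
    for ref_scaffold, bs in sorted(_blocks_by_ref(blocks).items()):
        if len(bs) < 2:
            continue
        # --- inter: runs of blocks on a non-modal partner chromosome ---
        pchroms = [b.partner_chromosome for b in bs]
        known = [c for c in pchroms if c != UNPLACED]
        if not known:
            continue
        context_chrom = _modal([b for b in bs if b.partner_chromosome != UNPLACED])
        for i, j in _runs(pchroms, context_chrom):
            run_chroms = {c for c in pchroms[i:j] if c != UNPLACED}
            if not run_chroms:
                continue  # unplaced-partner run: cannot classify
            events.append(
                RearrangementEvent(
                    type="inter",
                    ref_scaffold=ref_scaffold,
                    ref_chromosome=bs[i].ref_chromosome,
                    partner_context=",".join(sorted(run_chroms)),
                    breakpoints=_run_breakpoints(bs, i, j),
                )
            )
        # --- intra: within the context chromosome, minority-orientation runs
        #     and same-scaffold order discontinuities ---
        ctx_blocks = [b for b in bs if b.partner_chromosome == context_chrom]
        if len(ctx_blocks) < 2:
            continue
        orients = [b.orientation for b in ctx_blocks]
        modal_orient = max(set(orients), key=lambda o: (orients.count(o), o == "+"))
        idx = {id(b): k for k, b in enumerate(bs)}
        for i, j in _runs(orients, modal_orient):
            lo, hi = idx[id(ctx_blocks[i])], idx[id(ctx_blocks[j - 1])] + 1
            events.append(
                RearrangementEvent(
                    type="intra",
                    ref_scaffold=ref_scaffold,
                    ref_chromosome=bs[lo].ref_chromosome,
                    partner_context=context_chrom,
                    breakpoints=_run_breakpoints(bs, lo, hi),
                )
            )
        # order discontinuity: same partner scaffold, same orientation, but
        # the ref-order block sequence maps to non-monotone partner positions
        for b1, b2 in zip(ctx_blocks, ctx_blocks[1:]):
            if b1.partner_scaffold != b2.partner_scaffold:
                continue
            if b1.orientation != b2.orientation or b1.orientation != modal_orient:
                continue
            forward = b2.partner_range.start >= b1.partner_range.start
            if forward != (modal_orient == "+"):
                lo = idx[id(b2)]
                events.append(
                    RearrangementEvent(
                        type="intra",
                        ref_scaffold=ref_scaffold,
                        ref_chromosome=b2.ref_chromosome,
                        partner_context=context_chrom,
                        breakpoints=_run_breakpoints(bs, lo, lo + 1),
                    )
                )
    return events


def _modal(blocks: list[SyntenyBlock]) -> str:
    """Partner chromosome with the most marker support."""
    weight: dict[str, int] = {}
    for b in blocks:
        weight[b.partner_chromosome] = weight.get(b.partner_chromosome, 0) + b.n_markers
    return max(sorted(weight), key=lambda c: weight[c])


def _run_breakpoints(
    bs: list[SyntenyBlock], i: int, j: int
) -> tuple[tuple[int, int], ...]:
    bps = []
    if i > 0:
        bps.append((bs[i - 1].ref_range.end, bs[i].ref_range.start))
    if j < len(bs):
        bps.append((bs[j - 1].ref_range.end, bs[j].ref_range.start))
    return tuple(bps)


def summarize_synteny(
    blocks: list[SyntenyBlock],
    events: list[RearrangementEvent],
    assembly_ref: Assembly,
    assembly_partner: Assembly,
    large_block_threshold: int = 5_000_000,
) -> SyntenySummary:
    n_intra = sum(1 for e in events if e.type == "intra")
    n_inter = sum(1 for e in events if e.type == "inter")
    if not blocks:
        return SyntenySummary(
            n_blocks=0, ref_len_mean=0.0, ref_len_median=0.0, ref_len_min=0,
            ref_len_max=0, ref_len_total=0, partner_len_total=0,
            n_ref_scaffolds_covered=0, coverage_ref=0.0, coverage_partner=0.0,
            n_large_blocks=0, n_intra=n_intra, n_inter=n_inter,
        )
    ref_lens = [b.ref_span for b in blocks]
    partner_total = sum(b.partner_span for b in blocks)
    return SyntenySummary(
        n_blocks=len(blocks),
        ref_len_mean=mean(ref_lens),
        ref_len_median=median(ref_lens),
        ref_len_min=min(ref_lens),
        ref_len_max=max(ref_lens),
        ref_len_total=sum(ref_lens),
        partner_len_total=partner_total,
        n_ref_scaffolds_covered=len({b.ref_scaffold for b in blocks}),
        coverage_ref=sum(ref_lens) / assembly_ref.total_span(),
        coverage_partner=partner_total / assembly_partner.total_span(),
        n_large_blocks=sum(1 for L in ref_lens if L > large_block_threshold),
        n_intra=n_intra,
        n_inter=n_inter,
    )
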