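"""End-to-end orchestration: SSR scan -> marker match -> synteny -> summary."""

from __future__ import annotations

from dataclasses import dataclass, field

from microsynt.genome_io import Assembly, ChromosomeMap
from microsynt.marker_match import MarkerPair, MatchParams, match_markers
from microsynt.ssr_detect import SSRLocus, SSRParams, find_ssrs_assembly
from microsynt.synteny_map import (
    OrderedMarkerTrack,
    RearrangementEvent,
    ScaffoldLink,
    SyntenyBlock,
    SyntenyParams,
    SyntenySummary,
    build_blocks,
    build_tracks,
    classify_rearrangements,
    link_scaffolds,
    place_unplaced,
    summarize_synteny,
)

__all__ = ["SyntenyRun", "run_synteny_pipeline"]


@dataclass
class SyntenyRun:
    loci_ref: list[SSRLocus]
    loci_partner: list[SSRLocus]
    pairs: list[MarkerPair]
    tracks: list[OrderedMarkerTrack]
    blocks: list[SyntenyBlock]
    links: list[ScaffoldLink]
    link_conflicts: list[str]
    events: list[RearrangementEvent]
    summary: SyntenySummary
    placements: list = field(default_factory=list)


def run_synteny_pipeline(
    assembly_ref: Assembly,
    assembly_partner: Assembly,
    chrom_map_ref: ChromosomeMap | None = None,
    chrom_map_partner: ChromosomeMap | None = None,
    ssr_params: SSRParams | None = None,
    match_params: MatchParams | None = None,
    synteny_params: SyntenyParams | None = None,
) -> SyntenyRun:
    """Run the full marker-based synteny comparison of two assemblies."""
    ssr_params = ssr_params or SSRParams()
    chrom_map_ref = chrom_map_ref or ChromosomeMap()
    chrom_map_partner = chrom_map_partner or ChromosomeMap()
    loci_ref = find_ssrs_assembly(assembly_ref, ssr_params)
    loci_partner = find_ssrs_assembly(assembly_partner, ssr_params)
    pairs = match_markers(loci_ref, loci_partner, match_params)
    tracks = build_tracks(pairs, chrom_map_ref, chrom_map_partner)
    blocks = build_blocks(tracks, synteny_params, chrom_map_partner)
    links, conflicts = link_scaffolds(blocks, tracks, synteny_params)
    blocks, placements = place_unplaced(
        blocks, chrom_map_ref, chrom_map_partner, synteny_params
    )
    events = classify_rearrangements(blocks, chrom_map_ref, chrom_map_partner)
    summary = summarize_synteny(blocks, events, assembly_ref, assembly_partner)
    return SyntenyRun(
        loci_ref=loci_ref,
        loci_partner=loci_partner,
        pairs=pairs,
        tracks=tracks,
        blocks=blocks,
        links=links,
        link_conflicts=conflicts,
        events=events,
        summary=summary,
        placements=placements,
    )
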