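"""One-to-one homologous SSR pairing across two assemblies by flank similarity.

The repeat tract itself carries no positional information, so homology is
decided on the flanking sequence: the left/right flank pairs are aligned
semi-globally (free end gaps, affine gap costs) in both the given and the
reverse-complement orientation, and a pair is accepted only as a reciprocal
best hit with a clear identity margin over the runner-up.  Left and right
flanks are aligned separately so the aligner can never bridge across the
repeat.

A fast bounded edit-distance screen (edlib) prunes the per-motif candidate
space before the affine-scored alignment is computed; accepted identities
always come from the affine aligner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
from Bio import Align

from microsynt.ssr_detect import SSRLocus, revcomp

__all__ = ["MatchParams", "MarkerPair", "flank_identity", "match_markers"]


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class MatchParams:
    min_identity: float = 0.90
    min_aligned_fraction: float = 0.80
    require_same_motif: bool = True
    tie_margin: float = 0.02
    scoring: Scoring = field(default_factory=Scoring)

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class MarkerPair:
    locus_a: SSRLocus
    locus_b: SSRLocus
    identity: float
    orientation: str  # "+" or "-"
    aligned_fraction: float


def _make_aligner(s: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = s.match
    aligner.mismatch_score = s.mismatch
    aligner.open_gap_score = s.gap_open
    aligner.extend_gap_score = s.gap_extend
    # free end gaps = semi-global
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _aligned_counts(aligner: Align.PairwiseAligner, a: str, b: str) -> tuple[int, int]:
    """(identities, aligned columns with a base on both sides)."""
    if not a or not b:
        return 0, 0
    aln = aligner.align(a, b)[0]
    c = aln.counts()
    return c.identities, c.identities + c.mismatches


def flank_identity(
    flanks_a: tuple[str, str],
    flanks_b: tuple[str, str],
    scoring: Scoring | None = None,
) -> tuple[float, str, float]:
    """(identity, orientation, aligned_fraction) of two loci's flank pairs.

    "+" aligns left-with-left and right-with-right; "-" aligns A's left flank
    with the reverse complement of B's right flank (and vice versa), the
    geometry of a marker on the opposite strand.  Identity is pooled matches
    over pooled aligned columns; aligned_fraction is pooled aligned columns
    over the shorter combined flank length.  The better orientation wins.
    """
    la, ra = flanks_a
    lb, rb = flanks_b
    if not (la or ra) or not (lb or rb):
        raise ValueError("flank_identity on empty flanks")
    aligner = _make_aligner(scoring or Scoring())
    total_a = len(la) + len(ra)
    total_b = len(lb) + len(rb)
    shorter = min(total_a, total_b)
    results = []
    for orient, pairs in (
        ("+", ((la, lb), (ra, rb))),
        ("-", ((la, revcomp(rb)), (ra, revcomp(lb)))),
    ):
        ident = cols = 0
        for x, y in pairs:
            i, c = _aligned_counts(aligner, x, y)
            ident += i
            cols += c
        identity = ident / cols if cols else 0.0
        fraction = cols / shorter if shorter else 0.0
        results.append((identity, orient, fraction))
    # prefer the orientation with more matching columns; break ties toward "+"
    results.sort(key=lambda t: (t[0] * t[2],), reverse=True)
    return results[0]


def _edlib_screen(
    fa: tuple[str, str], fb: tuple[str, str], max_dist: int
) -> bool:
    """Cheap lower-bound screen: can these flanks possibly reach min_identity?"""
    ca = fa[0] + "#" + fa[1]
    for cb in (fb[0] + "#" + fb[1], revcomp(fb[1]) + "#" + revcomp(fb[0])):
        r = edlib.align(ca, cb, mode="NW", task="distance", k=max_dist)
        if r["editDistance"] != -1:
            return True
    return False


def match_markers(
    loci_a: list[SSRLocus],
    loci_b: list[SSRLocus],
    params: MatchParams | None = None,
) -> list[MarkerPair]:
    """Partial one-to-one matching of usable loci across the two assemblies.

    Candidates are restricted to the same canonical motif (configurable),
    must reach ``min_identity`` and ``min_aligned_fraction``, and a pair is
    kept only if it is the reciprocal best hit on both sides with the
    second-best identity at least ``tie_margin`` lower; loci with tied top
    candidates are dropped entirely.
    """
    params = params or MatchParams()
    usable_a = [l for l in loci_a if l.usable]
    usable_b = [l for l in loci_b if l.usable]

    def bins(loci: list[SSRLocus]) -> dict[str, list[SSRLocus]]:
        out: dict[str, list[SSRLocus]] = {}
        for l in loci:
            out.setdefault(l.motif if params.require_same_motif else "*", []).append(l)
        return out

    bins_a, bins_b = bins(usable_a), bins(usable_b)
    # candidate identities: {a_index: [(identity, orientation, fraction, b)]}
    cand: dict[int, list[tuple[float, str, float, SSRLocus]]] = {}
    cand_rev: dict[int, list[tuple[float, SSRLocus]]] = {}
    for motif, group_a in bins_a.items():
        group_b = bins_b.get(motif, [])
        if not group_b:
            continue
        for a in group_a:
            fa = (a.left_flank, a.right_flank)
            shorter_cap = len(fa[0]) + len(fa[1]) + 1
            max_dist = int((1 - params.min_identity + 0.10) * shorter_cap) + 2
            for b in group_b:
                fb = (b.left_flank, b.right_flank)
                if not _edlib_screen(fa, fb, max_dist):
                    continue
                identity, orient, fraction = flank_identity(fa, fb)
                if identity < params.min_identity:
                    continue
                if fraction < params.min_aligned_fraction:
                    continue
                cand.setdefault(id(a), []).append((identity, orient, fraction, b))
                cand_rev.setdefault(id(b), []).append((identity, a))

    pairs: list[MarkerPair] = []
    obj_a = {id(a): a for a in usable_a}
    for aid, ranked in cand.items():
        ranked_sorted = sorted(ranked, key=lambda t: t[0], reverse=True)
        if (
            len(ranked_sorted) > 1
            and ranked_sorted[0][0] - ranked_sorted[1][0] < params.tie_margin
        ):
            continue  # ambiguous on A's side
        identity, orient, fraction, b = ranked_sorted[0]
        rev = sorted(cand_rev.get(id(b), []), key=lambda t: t[0], reverse=True)
        if not rev or rev[0][1] is not obj_a[aid]:
            continue  # not reciprocal
        if len(rev) > 1 and rev[0][0] - rev[1][0] < params.tie_margin:
            continue  # ambiguous on B's side
        pairs.append(
            MarkerPair(
                locus_a=obj_a[aid],
                locus_b=b,
                identity=identity,
                orientation=orient,
                aligned_fraction=fraction,
            )
        )
    pairs.sort(key=lambda p: (p.locus_a.scaffold, p.locus_a.start))
    return pairs
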