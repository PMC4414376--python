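"""Synthetic inputs with ground truth for every pipeline stage.

The genome simulator emulates the situation the synteny pipeline assumes:
two assemblies descended from one ancestor that share SSR loci, where one
lineage (role B) has experienced a known history of inversions and
inter-chromosomal translocations, both lineages accumulate point mutations
and small indels in the marker flanks (never inside the repeats themselves,
so detection thresholds rather than repeat decay are what is tested), and
both can be fragmented into N-gapped scaffolds.  Every implanted and chance
SSR locus, every homologous pair and every rearrangement breakpoint is
recorded in truth tables in the coordinates of the derived assemblies.

Companion generators produce two-species protein-domain annotation tables
with implanted expansions/contractions and repeat-number shifts, and gene
sequence sets drawn from two CpG[O/E] classes.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from microsynt.genome_io import Assembly, ChromosomeMap
from microsynt.marker_match import MarkerPair
from microsynt.ssr_detect import SSRParams, canonical_motif, find_ssrs, is_reducible
from microsynt.synteny_map import RearrangementEvent

__all__ = [
    "DerivedGenome",
    "DomainSim",
    "DomainSimParams",
    "MethylomeSim",
    "MethylomeSimParams",
    "RearrangementSpec",
    "SimParams",
    "TrueEvent",
    "derive_assembly",
    "random_rearrangements",
    "score_events",
    "score_pairs",
    "simulate_ancestor",
    "simulate_domain_tables",
    "simulate_genome_pair",
    "simulate_methylome",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_LUT = np.zeros(256, dtype=np.uint8)
for x, y in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[x] = y


# --------------------------------------------------------------------------
# parameters and result containers


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the genome-pair simulation."""

    genome_size: int = 10_000_000
    n_chromosomes: int = 5
    gc_content: float = 0.38          # bumblebee-like AT-rich background
    ssr_density_per_mb: float = 40.0  # implanted marker density
    motif_length_mix: tuple[tuple[int, float], ...] = ((2, 0.5), (3, 0.3), (4, 0.2))
    units_range: tuple[tuple[int, tuple[int, int]], ...] = (
        (1, (12, 20)), (2, (8, 16)), (3, (6, 12)), (4, (6, 10)),
        (5, (5, 9)), (6, (5, 8)),
    )
    min_spacing: int = 500            # between implanted loci
    edge_margin: int = 400            # keep loci away from chromosome ends
    mutation_rate: float = 0.005      # per-base substitutions, per lineage
    indel_rate: float = 0.0002        # small indels, per lineage
    indel_max_len: int = 3
    n_inversions: int = 6
    n_translocations: int = 4
    min_markers_per_event: int = 5
    max_markers_per_event: int = 8
    # fragmentation (None = one scaffold per chromosome)
    mean_scaffold_len: int | None = None
    gaps_per_mb: float = 10.0
    gap_len: int = 100
    unplaced_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.mutation_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class Ancestor:
    chromosomes: dict[str, np.ndarray]         # uint8 ASCII arrays
    loci: dict[str, tuple[str, int, int, str]]  # id -> (chrom, start, end, motif)
    order: dict[str, list[str]]                 # chrom -> locus ids in coordinate order


@dataclass(frozen=True)
class RearrangementSpec:
    kind: str                       # "inversion" | "translocation"
    chrom: str
    marker_run: tuple[str, ...]     # consecutive ancestral marker ids
    dest_chrom: str | None = None
    dest_after_marker: str | None = None


@dataclass(frozen=True)
class TrueEvent:
    kind: str                       # "intra" | "inter"
    chrom: str                      # ancestral source chromosome
    marker_run: tuple[str, ...]
    left_neighbor: str | None       # ancestral neighbours bracketing the run
    right_neighbor: str | None
    dest_chrom: str | None = None
    dest_left: str | None = None
    dest_right: str | None = None


@dataclass
class DerivedGenome:
    assembly: Assembly
    chrom_map: ChromosomeMap
    # locus id -> (scaffold, start, end, orientation "+"/"-")
    loci: dict[str, tuple[str, int, int, str]]
    events: list[TrueEvent] = field(default_factory=list)


# --------------------------------------------------------------------------
# ancestor


def _random_motif(k: int, rng: np.random.Generator) -> str:
    while True:
        motif = "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))
        if not is_reducible(motif):
            return motif


def simulate_ancestor(params: SimParams, rng: np.random.Generator) -> Ancestor:
    """Background sequence at the stated GC with implanted perfect SSRs.

    Loci are placed uniformly at random with a minimum spacing and an edge
    margin.  Chance tandem repeats arising in the background that meet the
    default detection minimums are added to the truth table too, so that the
    table is the complete set of detectable homologous loci.
    """
    g = params.gc_content
    probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    n_loci_total = int(round(params.ssr_density_per_mb * params.genome_size / 1e6))
    chrom_len = params.genome_size // params.n_chromosomes
    mix_k = [k for k, _ in params.motif_length_mix]
    mix_w = np.array([w for _, w in params.motif_length_mix], dtype=float)
    mix_w /= mix_w.sum()
    units = dict(params.units_range)

    chromosomes: dict[str, np.ndarray] = {}
    loci: dict[str, tuple[str, int, int, str]] = {}
    order: dict[str, list[str]] = {}
    counter = 0
    for c in range(params.n_chromosomes):
        name = f"chr{c + 1}"
        arr = _BASES[rng.choice(4, size=chrom_len, p=probs)]
        n_loci = n_loci_total // params.n_chromosomes
        lo = params.edge_margin
        hi = chrom_len - params.edge_margin - 200
        for attempt in range(200):
            starts = np.sort(rng.integers(lo, hi, size=n_loci))
            if n_loci < 2 or np.min(np.diff(starts)) >= params.min_spacing + 200:
                break
        else:
            raise ValueError("SSR density too high to satisfy the minimum spacing")
        placed: list[str] = []
        for s in starts.tolist():
            k = int(rng.choice(mix_k, p=mix_w))
            u = int(rng.integers(units[k][0], units[k][1] + 1))
            motif = _random_motif(k, rng)
            tract = np.frombuffer((motif * u).encode(), dtype=np.uint8)
            arr[s : s + len(tract)] = tract
            lid = f"m{counter:05d}"
            counter += 1
            loci[lid] = (name, s, s + len(tract), canonical_motif(motif))
            placed.append(lid)
        chromosomes[name] = arr
        order[name] = placed
    _add_chance_loci(chromosomes, loci, order, counter)
    return Ancestor(chromosomes=chromosomes, loci=loci, order=order)


def _add_chance_loci(chromosomes, loci, order, counter) -> None:
    """Record background tandem repeats that meet the default thresholds."""
    scan_params = SSRParams()
    for name, arr in chromosomes.items():
        implanted = [(loci[i][1], loci[i][2]) for i in order[name]]
        starts = [s for s, _ in implanted]
        found = find_ssrs(arr.tobytes().decode(), scan_params, scaffold=name)
        new: list[str] = []
        for l in found:
            i = bisect.bisect_left(starts, l.start)
            hit = None
            for j in range(max(0, i - 1), min(len(implanted), i + 1)):
                s, e = implanted[j]
                if l.start < e and l.end > s:
                    hit = j
                    break
            if hit is not None:
                # an implanted locus, possibly extended by background bases
                # that happen to continue the repeat: record the maximal
                # interval the truth table should expect
                lid = order[name][hit]
                if loci[lid][3] == l.motif:
                    loci[lid] = (name, l.start, l.end, l.motif)
                continue
            lid = f"m{counter:05d}"
            counter += 1
            loci[lid] = (name, l.start, l.end, l.motif)
            new.append(lid)
        merged = order[name] + new
        merged.sort(key=lambda lid: loci[lid][1])
        order[name] = merged


# --------------------------------------------------------------------------
# rearrangement planning


def random_rearrangements(
    ancestor: Ancestor, params: SimParams, rng: np.random.Generator
) -> list[RearrangementSpec]:
    """Disjoint inversion/translocation plans over consecutive marker runs."""
    used: dict[str, set[int]] = {c: set() for c in ancestor.order}
    chroms = sorted(ancestor.order)
    specs: list[RearrangementSpec] = []

    def pick_run(chrom: str, n: int) -> tuple[str, ...] | None:
        ids = ancestor.order[chrom]
        if len(ids) < n + 4:
            return None
        for _ in range(100):
            i = int(rng.integers(2, len(ids) - n - 2))
            span = set(range(i - 1, i + n + 1))
            if span & used[chrom]:
                continue
            used[chrom] |= span
            return tuple(ids[i : i + n])
        return None

    kinds = ["inversion"] * params.n_inversions + [
        "translocation"
    ] * params.n_translocations
    for kind in kinds:
        n = int(
            rng.integers(params.min_markers_per_event, params.max_markers_per_event + 1)
        )
        run = None
        chrom = ""
        for _ in range(100):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            run = pick_run(chrom, n)
            if run is not None:
                break
        if run is None:
            raise ValueError("could not place disjoint rearrangement spans")
        if kind == "inversion":
            specs.append(RearrangementSpec("inversion", chrom, run))
            continue
        dest = None
        for _ in range(200):
            dc = chroms[int(rng.integers(0, len(chroms)))]
            if dc == chrom:
                continue
            ids = ancestor.order[dc]
            j = int(rng.integers(2, len(ids) - 2))
            if {j - 1, j, j + 1, j + 2} & used[dc]:
                continue
            used[dc] |= {j, j + 1}
            dest = (dc, ids[j])
            break
        if dest is None:
            raise ValueError("could not place translocation destination")
        specs.append(
            RearrangementSpec(
                "translocation", chrom, run, dest_chrom=dest[0], dest_after_marker=dest[1]
            )
        )
    return specs


# --------------------------------------------------------------------------
# deriving an assembly


class _ChromState:
    __slots__ = ("arr", "loci")

    def __init__(self, arr: np.ndarray, loci: dict[str, list[int]]):
        self.arr = arr
        self.loci = loci  # id -> [start, end, orient(+1/-1)]


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP_LUT[arr][::-1]


def _current_order(state: _ChromState) -> list[str]:
    return sorted(state.loci, key=lambda i: state.loci[i][0])


def _boundaries(state: _ChromState, run: tuple[str, ...]) -> tuple[int, int]:
    order = _current_order(state)
    first, last = run[0], run[-1]
    i0, i1 = order.index(first), order.index(last)
    if tuple(order[i0 : i1 + 1]) != run:
        raise ValueError(f"marker run {run} is not contiguous at application time")
    left = state.loci[order[i0 - 1]][1] if i0 > 0 else 0
    s = (left + state.loci[first][0]) // 2
    right = (
        state.loci[order[i1 + 1]][0] if i1 + 1 < len(order) else len(state.arr)
    )
    e = (state.loci[last][1] + right) // 2
    return s, e


def _apply_inversion(state: _ChromState, run: tuple[str, ...]) -> None:
    s, e = _boundaries(state, run)
    state.arr[s:e] = _revcomp_arr(state.arr[s:e])
    for lid, (ls, le, orient) in list(state.loci.items()):
        if ls >= s and le <= e:
            state.loci[lid] = [s + (e - le), s + (e - ls), -orient]
        elif ls < e and le > s and not (ls >= s and le <= e):
            if ls < s < le or ls < e < le:
                raise ValueError("inversion boundary cuts a marker")


def _apply_translocation(
    src: _ChromState, dst: _ChromState, run: tuple[str, ...], after: str
) -> None:
    s, e = _boundaries(src, run)
    seg = src.arr[s:e].copy()
    moved = {
        lid: v for lid, v in src.loci.items() if v[0] >= s and v[1] <= e
    }
    src.arr = np.concatenate([src.arr[:s], src.arr[e:]])
    for lid in moved:
        del src.loci[lid]
    for lid, v in src.loci.items():
        if v[0] >= e:
            src.loci[lid] = [v[0] - (e - s), v[1] - (e - s), v[2]]
    order = _current_order(dst)
    j = order.index(after)
    right = dst.loci[order[j + 1]][0] if j + 1 < len(order) else len(dst.arr)
    p = (dst.loci[after][1] + right) // 2
    dst.arr = np.concatenate([dst.arr[:p], seg, dst.arr[p:]])
    for lid, v in dst.loci.items():
        if v[0] >= p:
            dst.loci[lid] = [v[0] + len(seg), v[1] + len(seg), v[2]]
    for lid, v in moved.items():
        dst.loci[lid] = [p + (v[0] - s), p + (v[1] - s), v[2]]


def _apply_substitutions(
    state: _ChromState, rate: float, rng: np.random.Generator
) -> None:
    if rate <= 0:
        return
    L = len(state.arr)
    n = rng.binomial(L, rate)
    if n == 0:
        return
    pos = rng.choice(L, size=n, replace=False)
    mask = np.zeros(L, dtype=bool)
    for ls, le, _ in state.loci.values():
        mask[ls:le] = True
    pos = pos[~mask[pos]]
    base_index = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        base_index[b] = i
    cur = base_index[state.arr[pos]]
    shift = rng.integers(1, 4, size=len(pos))
    state.arr[pos] = _BASES[(cur + shift) % 4]


def _apply_indels(
    state: _ChromState, params: SimParams, rng: np.random.Generator
) -> None:
    if params.indel_rate <= 0:
        return
    L = len(state.arr)
    n = rng.binomial(L, params.indel_rate)
    if n == 0:
        return
    mask = np.zeros(L, dtype=bool)
    for ls, le, _ in state.loci.values():
        mask[max(0, ls - 1) : le + 1] = True
    pos = np.sort(rng.choice(L, size=n, replace=False))
    lens = rng.integers(1, params.indel_max_len + 1, size=n)
    is_ins = rng.random(n) < 0.5
    pieces: list[np.ndarray] = []
    edits: list[tuple[int, int]] = []  # (position, shift)
    prev = 0
    g = params.gc_content
    probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    for p, ln, ins in zip(pos.tolist(), lens.tolist(), is_ins.tolist()):
        if p < prev:
            continue
        if ins:
            if mask[p]:
                continue
            pieces.append(state.arr[prev:p])
            pieces.append(_BASES[rng.choice(4, size=ln, p=probs)])
            edits.append((p, ln))
            prev = p
        else:
            if p + ln > L or mask[p : p + ln].any():
                continue
            pieces.append(state.arr[prev:p])
            edits.append((p, -ln))
            prev = p + ln
    pieces.append(state.arr[prev:])
    state.arr = np.concatenate(pieces)
    if edits:
        epos = np.array([p for p, _ in edits])
        eshift = np.cumsum([d for _, d in edits])
        for lid, (ls, le, orient) in state.loci.items():
            i = np.searchsorted(epos, ls, side="right") - 1
            shift = int(eshift[i]) if i >= 0 else 0
            state.loci[lid] = [ls + shift, le + shift, orient]


def _fragment(
    name_prefix: str,
    chrom: str,
    state: _ChromState,
    params: SimParams,
    rng: np.random.Generator,
    scaffold_counter: list[int],
) -> tuple[dict[str, str], dict[str, str], dict[str, tuple[str, int, int, str]]]:
    """Split one chromosome into N-gapped scaffolds; lift locus coordinates."""
    L = len(state.arr)
    locus_spans = sorted((v[0], v[1]) for v in state.loci.values())
    starts = [s for s, _ in locus_spans]

    def in_locus(p: int) -> bool:
        i = bisect.bisect_right(starts, p) - 1
        return i >= 0 and locus_spans[i][0] <= p < locus_spans[i][1]

    cuts: list[int] = []
    if params.mean_scaffold_len:
        n_cuts = max(0, int(round(L / params.mean_scaffold_len)) - 1)
        for p in np.sort(rng.integers(1, L, size=n_cuts)).tolist():
            if not in_locus(p) and (not cuts or p - cuts[-1] > 1000):
                cuts.append(p)
    bounds = [0] + cuts + [L]
    scaffolds: dict[str, str] = {}
    chrom_of: dict[str, str] = {}
    lifted: dict[str, tuple[str, int, int, str]] = {}
    for lo, hi in zip(bounds, bounds[1:]):
        sid = f"{name_prefix}s{scaffold_counter[0]:04d}"
        scaffold_counter[0] += 1
        seg = state.arr[lo:hi]
        seg_loci = {
            lid: (v[0] - lo, v[1] - lo, v[2])
            for lid, v in state.loci.items()
            if v[0] >= lo and v[1] <= hi
        }
        # internal N gaps (insertions)
        n_gaps = rng.poisson(params.gaps_per_mb * len(seg) / 1e6) if params.mean_scaffold_len else 0
        gap_pos: list[int] = []
        span_list = sorted((s, e) for (s, e, _) in seg_loci.values())
        sstarts = [s for s, _ in span_list]

        def in_seg_locus(p: int) -> bool:
            i = bisect.bisect_right(sstarts, p) - 1
            return i >= 0 and span_list[i][0] <= p < span_list[i][1]

        for p in np.sort(rng.integers(1, max(2, len(seg)), size=n_gaps)).tolist():
            if not in_seg_locus(p):
                gap_pos.append(p)
        if gap_pos:
            pieces = []
            prev = 0
            for p in gap_pos:
                pieces.append(seg[prev:p])
                pieces.append(np.full(params.gap_len, ord("N"), dtype=np.uint8))
                prev = p
            pieces.append(seg[prev:])
            seg = np.concatenate(pieces)
            gp = np.array(gap_pos)
            for lid, (s, e, orient) in seg_loci.items():
                shift = int(np.searchsorted(gp, s, side="right")) * params.gap_len
                seg_loci[lid] = (s + shift, e + shift, orient)
        scaffolds[sid] = seg.tobytes().decode()
        chrom_of[sid] = chrom
        for lid, (s, e, orient) in seg_loci.items():
            lifted[lid] = (sid, s, e, "+" if orient > 0 else "-")
    return scaffolds, chrom_of, lifted


def derive_assembly(
    ancestor: Ancestor,
    params: SimParams,
    role: str,
    rng: np.random.Generator,
    rearrangements: list[RearrangementSpec] | None = None,
) -> DerivedGenome:
    """Descend one assembly from the ancestor.

    Role B receives the rearrangement history; both roles then accumulate
    independent substitutions and small indels outside the marker loci, and
    are optionally fragmented into N-gapped scaffolds.
    """
    states = {
        c: _ChromState(
            arr.copy(),
            {
                lid: [ancestor.loci[lid][1], ancestor.loci[lid][2], +1]
                for lid in ancestor.order[c]
            },
        )
        for c, arr in ancestor.chromosomes.items()
    }
    events: list[TrueEvent] = []
    if rearrangements:
        for spec in rearrangements:
            anc_ids = ancestor.order[spec.chrom]
            i0 = anc_ids.index(spec.marker_run[0])
            i1 = anc_ids.index(spec.marker_run[-1])
            left = anc_ids[i0 - 1] if i0 > 0 else None
            right = anc_ids[i1 + 1] if i1 + 1 < len(anc_ids) else None
            if spec.kind == "inversion":
                _apply_inversion(states[spec.chrom], spec.marker_run)
                events.append(
                    TrueEvent("intra", spec.chrom, spec.marker_run, left, right)
                )
            else:
                dst_ids = ancestor.order[spec.dest_chrom]
                j = dst_ids.index(spec.dest_after_marker)
                dest_right = dst_ids[j + 1] if j + 1 < len(dst_ids) else None
                _apply_translocation(
                    states[spec.chrom],
                    states[spec.dest_chrom],
                    spec.marker_run,
                    spec.dest_after_marker,
                )
                events.append(
                    TrueEvent(
                        "inter", spec.chrom, spec.marker_run, left, right,
                        dest_chrom=spec.dest_chrom,
                        dest_left=spec.dest_after_marker,
                        dest_right=dest_right,
                    )
                )
    for state in states.values():
        _apply_substitutions(state, params.mutation_rate, rng)
        _apply_indels(state, params, rng)
    scaffolds: dict[str, str] = {}
    chrom_of: dict[str, str] = {}
    loci: dict[str, tuple[str, int, int, str]] = {}
    counter = [0]
    for c in sorted(states):
        sc, co, lf = _fragment(role, c, states[c], params, rng, counter)
        scaffolds.update(sc)
        chrom_of.update(co)
        loci.update(lf)
    if params.unplaced_fraction > 0:
        sids = sorted(chrom_of)
        n_unplaced = int(round(params.unplaced_fraction * len(sids)))
        drop = set(
            rng.choice(len(sids), size=n_unplaced, replace=False).tolist()
        )
        chrom_of = {s: c for i, (s, c) in enumerate(sorted(chrom_of.items())) if i not in drop}
    return DerivedGenome(
        assembly=Assembly(name=role, scaffolds=scaffolds),
        chrom_map=ChromosomeMap(entries=chrom_of),
        loci=loci,
        events=events,
    )


def simulate_genome_pair(
    params: SimParams, seed: int
) -> tuple[DerivedGenome, DerivedGenome, Ancestor, list[RearrangementSpec]]:
    """Ancestor -> (A, B) with B carrying the rearrangement history."""
    rng = np.random.default_rng(seed)
    ancestor = simulate_ancestor(params, rng)
    specs = (
        random_rearrangements(ancestor, params, rng)
        if params.n_inversions + params.n_translocations > 0
        else []
    )
    genome_a = derive_assembly(ancestor, params, "A", rng, rearrangements=None)
    genome_b = derive_assembly(ancestor, params, "B", rng, rearrangements=specs)
    return genome_a, genome_b, ancestor, specs


# --------------------------------------------------------------------------
# scoring detected pairs / events against the truth tables


def _overlap_lookup(loci: dict[str, tuple[str, int, int, str]]):
    by_scaffold: dict[str, list[tuple[int, int, str]]] = {}
    for lid, (sid, s, e, _) in loci.items():
        by_scaffold.setdefault(sid, []).append((s, e, lid))
    for v in by_scaffold.values():
        v.sort()

    def find(sid: str, s: int, e: int) -> str | None:
        lst = by_scaffold.get(sid, [])
        i = bisect.bisect_right(lst, (s, e, "\xff")) if lst else 0
        for j in range(max(0, i - 2), min(len(lst), i + 2)):
            ts, te, lid = lst[j]
            if s < te and e > ts:
                return lid
        return None

    return find


def score_pairs(
    pairs: list[MarkerPair],
    truth_a: dict[str, tuple[str, int, int, str]],
    truth_b: dict[str, tuple[str, int, int, str]],
) -> dict[str, float]:
    """Recall and precision of detected marker pairs against the truth.

    A detected pair is correct when its two loci overlap the two recorded
    intervals of one and the same ancestral locus.
    """
    find_a = _overlap_lookup(truth_a)
    find_b = _overlap_lookup(truth_b)
    n_true_pairs = len(set(truth_a) & set(truth_b))
    tp = fp = 0
    for p in pairs:
        ida = find_a(p.locus_a.scaffold, p.locus_a.start, p.locus_a.end)
        idb = find_b(p.locus_b.scaffold, p.locus_b.start, p.locus_b.end)
        if ida is not None and ida == idb:
            tp += 1
        else:
            fp += 1
    return {
        "n_pairs": len(pairs),
        "n_true_pairs": n_true_pairs,
        "recall": tp / n_true_pairs if n_true_pairs else 0.0,
        "precision": tp / (tp + fp) if (tp + fp) else 0.0,
    }


def score_events(
    detected: list[RearrangementEvent],
    truth_events: list[TrueEvent],
    truth_a: dict[str, tuple[str, int, int, str]],
    ancestor: Ancestor,
) -> dict[str, object]:
    """Compare detected rearrangements to the implanted history.

    Each true event must be matched by one detected event of the same type
    whose breakpoint intervals fall within one inter-marker interval of the
    true breakpoints (marker coordinates taken on the reference assembly A).
    """
    n_intra = sum(1 for e in detected if e.type == "intra")
    n_inter = sum(1 for e in detected if e.type == "inter")
    unmatched_truth = []
    used: set[int] = set()
    for t in truth_events:
        tol = _truth_breakpoint_window(t, truth_a, ancestor)
        hit = None
        for k, d in enumerate(detected):
            if k in used or d.type != t.kind or tol is None:
                continue
            sid, lo, hi = tol
            if d.ref_scaffold != sid:
                continue
            if all(x1 <= hi and x2 >= lo for x1, x2 in d.breakpoints):
                hit = k
                break
        if hit is None:
            unmatched_truth.append(t)
        else:
            used.add(hit)
    return {
        "n_intra_detected": n_intra,
        "n_inter_detected": n_inter,
        "n_intra_true": sum(1 for t in truth_events if t.kind == "intra"),
        "n_inter_true": sum(1 for t in truth_events if t.kind == "inter"),
        "n_truth_matched": len(truth_events) - len(unmatched_truth),
        "unmatched_truth": unmatched_truth,
    }


def _truth_breakpoint_window(
    t: TrueEvent,
    truth_a: dict[str, tuple[str, int, int, str]],
    ancestor: Ancestor,
) -> tuple[str, int, int] | None:
    """A-coordinate window [lo, hi] that must contain detected breakpoints:
    the rearranged run expanded by one inter-marker interval on each side."""
    anc_ids = ancestor.order[t.chrom]
    i0 = anc_ids.index(t.marker_run[0])
    i1 = anc_ids.index(t.marker_run[-1])
    lo_id = anc_ids[max(0, i0 - 2)]
    hi_id = anc_ids[min(len(anc_ids) - 1, i1 + 2)]
    if lo_id not in truth_a or hi_id not in truth_a:
        return None
    sid, lo_s, _, _ = truth_a[lo_id]
    sid2, _, hi_e, _ = truth_a[hi_id]
    if sid != sid2:
        return None  # run split across scaffolds; no well-defined window
    return sid, lo_s, hi_e


# --------------------------------------------------------------------------
# protein-domain table simulation


@dataclass(frozen=True)
class DomainSimParams:
    n_domains: int = 500
    abundance_range: tuple[float, float] = (5.0, 100.0)  # log-uniform mean counts
    implanted_effects: tuple[tuple[int, float], ...] = ()  # (domain index, fold in sp2)
    n_shared_arrangements: int = 30
    arrangement_occurrences: tuple[int, int] = (2, 6)
    repeat_range: tuple[int, int] = (1, 4)
    # (arrangement index, (min1, max1), (min2, max2)) repeat-count shifts
    implanted_repeat_shifts: tuple[tuple[int, tuple[int, int], tuple[int, int]], ...] = ()


@dataclass
class DomainSim:
    counts_1: dict[str, int]
    counts_2: dict[str, int]
    annotations_1: pd.DataFrame
    annotations_2: pd.DataFrame
    implanted_domains: list[str]
    implanted_arrangements: list[str]


def simulate_domain_tables(params: DomainSimParams, seed: int) -> DomainSim:
    """Two-species domain tables with implanted expansions and repeat shifts.

    Background per-domain gene counts are Poisson draws around a shared
    log-uniform abundance; implanted effects multiply the species-2 mean.
    Annotation tables (for the repeat-number statistics) place each protein's
    domain copies as separate full-model hits, far enough apart on the
    protein that they are genuine repeats, not split hits.
    """
    rng = np.random.default_rng(seed)
    lo, hi = params.abundance_range
    lam = np.exp(rng.uniform(np.log(lo), np.log(hi), size=params.n_domains))
    domains = [f"PF{i:05d}" for i in range(params.n_domains)]
    fold = np.ones(params.n_domains)
    for idx, f in params.implanted_effects:
        fold[idx] = f
    c1 = rng.poisson(lam)
    c2 = rng.poisson(lam * fold)
    counts_1 = {d: int(c) for d, c in zip(domains, c1) if c > 0}
    counts_2 = {d: int(c) for d, c in zip(domains, c2) if c > 0}

    shift_by_arr = {i: (r1, r2) for i, r1, r2 in params.implanted_repeat_shifts}
    rows1: list[dict] = []
    rows2: list[dict] = []
    implanted_arrs: list[str] = []
    for a in range(params.n_shared_arrangements):
        size = int(rng.integers(1, 3))
        members = [f"AR{a:03d}D{k}" for k in range(size)]
        arr_name = ";".join(sorted(members))
        if a in shift_by_arr:
            implanted_arrs.append(arr_name)
        base_repeats = {
            (a, d): int(rng.integers(params.repeat_range[0], params.repeat_range[1] + 1))
            for d in members
        }
        for sp, rows in ((1, rows1), (2, rows2)):
            n_prot = int(
                rng.integers(
                    params.arrangement_occurrences[0],
                    params.arrangement_occurrences[1] + 1,
                )
            )
            for pidx in range(n_prot):
                gene = f"sp{sp}_arr{a:03d}_{pidx}"
                pos = 1
                for d in members:
                    if a in shift_by_arr:
                        r_lo, r_hi = shift_by_arr[a][sp - 1]
                        reps = int(rng.integers(r_lo, r_hi + 1))
                    else:
                        # null: the repeat count is a conserved property of
                        # the domain family, identical in both species
                        reps = base_repeats[(a, d)]
                    for _ in range(reps):
                        rows.append(
                            {
                                "gene": gene,
                                "domain": d,
                                "protein_start": pos,
                                "protein_end": pos + 80,
                                "model_start": 1,
                                "model_end": 80,
                            }
                        )
                        pos += 140  # > protein_gap: never merged
    cols = ["gene", "domain", "protein_start", "protein_end", "model_start", "model_end"]
    return DomainSim(
        counts_1=counts_1,
        counts_2=counts_2,
        annotations_1=pd.DataFrame(rows1, columns=cols),
        annotations_2=pd.DataFrame(rows2, columns=cols),
        implanted_domains=[domains[i] for i, _ in params.implanted_effects],
        implanted_arrangements=implanted_arrs,
    )


# --------------------------------------------------------------------------
# methylome simulation


@dataclass(frozen=True)
class MethylomeSimParams:
    n_genes: int = 2000
    gene_len: int = 2000
    class_targets: tuple[float, ...] = (0.65, 1.05)
    class_proportions: tuple[float, ...] = (0.5, 0.5)
    class_sd: float = 0.02  # per-gene dispersion of the O/E target
    gc_content: float = 0.42


@dataclass
class MethylomeSim:
    sequences: dict[str, str]
    labels: dict[str, int]  # index into class_targets
    params: MethylomeSimParams


def _gene_with_cpg_ratio(
    length: int, target: float, probs: np.ndarray, rng: np.random.Generator
) -> str:
    """A sequence of the given base composition whose CpG count is pinned.

    The base composition is drawn multinomially, the CpG count is set to
    m = round(target * nC * nG / L), and the sequence is assembled from m
    "CG" blocks plus single-base tokens, with single G tokens inserted only
    in positions not preceded by a single C so that no accidental CpG is
    created.  Realized O/E therefore equals the target up to rounding.
    """
    counts = rng.multinomial(length, probs)  # A, C, G, T
    n_c, n_g = int(counts[1]), int(counts[2])
    if n_c == 0 or n_g == 0:
        return "".join("ACGT"[i] for i in np.repeat(np.arange(4), counts))
    m = int(round(target * n_c * n_g / length))
    bound = length * min(n_c, n_g) / (n_c * n_g)
    if m > min(n_c, n_g):
        raise ValueError(
            f"CpG O/E target {target} unattainable (bound {bound:.2f} at this "
            f"composition)"
        )
    # token codes: 0=A, 1=C(single), 2=T, 3=CG block; single Gs inserted after
    tokens = np.repeat(
        np.array([0, 1, 2, 3]),
        [int(counts[0]), n_c - m, int(counts[3]), m],
    )
    tokens = rng.permutation(tokens)
    # gap g = before token g; forbidden if the preceding token is a single C
    allowed = np.flatnonzero(np.concatenate([[True], tokens != 1]))
    gaps = rng.choice(allowed, size=n_g - m, replace=True)
    expanded = np.insert(tokens, np.sort(gaps), 4)  # 4 = single G
    lut = ["A", "C", "T", "CG", "G"]
    return "".join(lut[t] for t in expanded.tolist())


def simulate_methylome(params: MethylomeSimParams, seed: int) -> MethylomeSim:
    """Gene sequences drawn from CpG-depleted vs non-depleted classes.

    Per-gene CpG[O/E] targets are drawn around the class centre with a small
    dispersion and realized exactly (up to integer rounding) by a
    composition-constrained dinucleotide construction, producing the sharply
    bimodal O/E distribution the threshold classifier assumes.
    """
    if len(params.class_targets) != len(params.class_proportions):
        raise ValueError("class_targets and class_proportions lengths differ")
    g = params.gc_content
    probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    rng = np.random.default_rng(seed)
    labels_arr = rng.choice(
        len(params.class_targets), size=params.n_genes, p=params.class_proportions
    )
    sequences: dict[str, str] = {}
    labels: dict[str, int] = {}
    for i, cls in enumerate(labels_arr.tolist()):
        t = float(
            np.clip(
                rng.normal(params.class_targets[cls], params.class_sd), 0.02, None
            )
        )
        gid = f"g{i:05d}"
        sequences[gid] = _gene_with_cpg_ratio(params.gene_len, t, probs, rng)
        labels[gid] = int(cls)
    return MethylomeSim(sequences=sequences, labels=labels, params=params)
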