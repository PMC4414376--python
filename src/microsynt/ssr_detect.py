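"""Perfect microsatellite (SSR) detection and flank extraction.

SSR loci are the orthologous markers of the synteny pipeline: the repeat
itself is uninformative, but its unique flanking sequence can be matched
across assemblies.  Only perfect tandem repeats are reported; motif-length
minimum unit counts default to community-standard values (mononucleotide 12,
di 6, tri/tetra/penta/hexa 5).

Detection is a period-``k`` self-comparison: a maximal run of positions with
``seq[i] == seq[i+k]`` (no N involved) of length ``r`` is a perfect tandem
array of total length ``r + k``; the locus keeps only whole repeat units,
anchored at the run start.  Runs whose leading motif is itself a repetition
of a shorter motif (e.g. "ACAC" at k=4) are reported at the shorter period
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from microsynt.genome_io import Assembly, Interval

__all__ = [
    "SSRLocus",
    "SSRParams",
    "canonical_motif",
    "extract_flanks",
    "find_ssrs",
    "find_ssrs_assembly",
    "is_reducible",
    "revcomp",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MIN_UNITS: dict[int, int] = {1: 12, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SSRParams:
    """Detection thresholds; minimum units per motif length, flank lengths."""

    min_units: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_UNITS))
    flank_len: int = 200
    min_flank_total: int = 60

    def __post_init__(self) -> None:
        for k, m in self.min_units.items():
            if not 1 <= k <= 6:
                raise ValueError(f"motif length {k} outside 1..6")
            if k >= 2 and m < 2:
                raise ValueError(f"minimum units for motif length {k} must be >= 2")


@dataclass(frozen=True)
class SSRLocus:
    """A perfect tandem repeat with (optionally) extracted flanks."""

    interval: Interval
    motif: str  # canonical form
    motif_len: int
    n_units: int
    left_flank: str = ""
    right_flank: str = ""
    usable: bool = False

    @property
    def scaffold(self) -> str:
        return self.interval.scaffold

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def is_reducible(motif: str) -> bool:
    """True if the motif is a whole-number repetition of a shorter motif."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return True
    return False


def canonical_motif(motif: str) -> str:
    """Lexicographic minimum over rotations of the motif and of its
    reverse complement, so that the same repeat found on either strand or in
    any phase maps to one name (e.g. "TG" -> "AC")."""
    if not motif or len(motif) > 6:
        raise ValueError(f"motif length must be 1..6, got {motif!r}")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT symbols")
    if is_reducible(motif):
        raise ValueError(f"motif {motif!r} is a repetition of a shorter motif")
    rc = revcomp(motif)
    n = len(motif)
    candidates = [motif[i:] + motif[:i] for i in range(n)]
    candidates += [rc[i:] + rc[:i] for i in range(n)]
    return min(candidates)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    if mask.size == 0:
        return []
    padded = np.empty(mask.size + 2, dtype=np.int8)
    padded[0] = padded[-1] = 0
    padded[1:-1] = mask
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def find_ssrs(
    seq: str, params: SSRParams | None = None, scaffold: str = "seq"
) -> list[SSRLocus]:
    """All maximal perfect tandem runs meeting the per-motif-length minimum.

    Runs never cross an N; loci are sorted by start.  A run reportable under
    a reducible motif (e.g. an A-homopolymer seen at period 2) is reported
    only at its minimal period.
    """
    params = params or SSRParams()
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = a != ord("N")
    loci: list[SSRLocus] = []
    for k, min_units in sorted(params.min_units.items()):
        if len(seq) < k * min_units:
            continue
        eq = (a[:-k] == a[k:]) & valid[:-k] & valid[k:]
        for run_start, run_end in _bool_runs(eq):
            total = (run_end - run_start) + k
            units = total // k
            if units < min_units:
                continue
            motif = seq[run_start : run_start + k]
            if is_reducible(motif):
                continue
            interval = Interval(scaffold, run_start, run_start + k * units)
            loci.append(
                SSRLocus(
                    interval=interval,
                    motif=canonical_motif(motif),
                    motif_len=k,
                    n_units=units,
                )
            )
    loci.sort(key=lambda l: (l.start, l.end, l.motif))
    return loci


def extract_flanks(
    locus: SSRLocus, assembly: Assembly, params: SSRParams | None = None
) -> SSRLocus:
    """Fill in up to ``flank_len`` bases each side of the repeat.

    Flanks are truncated at the scaffold edge or at the nearest N; a locus
    whose combined flanks fall below ``min_flank_total`` is marked unusable.
    """
    params = params or SSRParams()
    seq = assembly[locus.scaffold]
    if locus.end > len(seq):
        raise ValueError(f"locus {locus.interval} outside scaffold bounds")
    left_lo = max(0, locus.start - params.flank_len)
    left = seq[left_lo : locus.start]
    ncut = left.rfind("N")
    if ncut != -1:
        left = left[ncut + 1 :]
    right_hi = min(len(seq), locus.end + params.flank_len)
    right = seq[locus.end : right_hi]
    ncut = right.find("N")
    if ncut != -1:
        right = right[:ncut]
    usable = len(left) + len(right) >= params.min_flank_total
    return replace(locus, left_flank=left, right_flank=right, usable=usable)


def find_ssrs_assembly(
    assembly: Assembly, params: SSRParams | None = None, with_flanks: bool = True
) -> list[SSRLocus]:
    """Scan every scaffold of an assembly; optionally extract flanks."""
    params = params or SSRParams()
    loci: list[SSRLocus] = []
    for sid, seq in assembly.items():
        found = find_ssrs(seq, params, scaffold=sid)
        if with_flanks:
            found = [extract_flanks(l, assembly, params) for l in found]
        loci.extend(found)
    return loci
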