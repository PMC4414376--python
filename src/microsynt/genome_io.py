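"""Assembly containers, FASTA / chromosome-map I/O and gap conventions.

All coordinates in this package are 0-based, half-open.  Sequences are stored
uppercase over the alphabet {A, C, G, T, N}; IUPAC ambiguity codes other than
N are normalized to N on input, since an ambiguous base can anchor neither an
SSR call nor a flank match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_IUPAC = set("ACGTNRYSWKMBDHV")
_AMBIG_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHV"})

__all__ = [
    "Assembly",
    "ChromosomeMap",
    "Interval",
    "normalize_sequence",
    "read_chromosome_map",
    "read_fasta",
    "split_contigs",
    "write_fasta",
]


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open interval on a named scaffold."""

    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Assembly:
    """A named, ordered collection of scaffold sequences."""

    name: str
    scaffolds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, seq in self.scaffolds.items():
            if not seq:
                raise ValueError(f"scaffold {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self.scaffolds

    def __getitem__(self, scaffold_id: str) -> str:
        return self.scaffolds[scaffold_id]

    def items(self):
        return self.scaffolds.items()

    def total_span(self) -> int:
        """Total length including N gaps."""
        return sum(len(s) for s in self.scaffolds.values())

    def total_sequence(self) -> int:
        """Total length excluding N."""
        return sum(len(s) - s.count("N") for s in self.scaffolds.values())


@dataclass
class ChromosomeMap:
    """scaffold id -> chromosome label; absent scaffolds are unplaced."""

    entries: dict[str, str] = field(default_factory=dict)

    def chromosome(self, scaffold_id: str) -> str | None:
        return self.entries.get(scaffold_id)

    def is_placed(self, scaffold_id: str) -> bool:
        return scaffold_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and map IUPAC ambiguity codes (other than N) to N.

    Raises ValueError on symbols outside the IUPAC nucleotide alphabet.
    """
    up = seq.upper()
    bad = set(up) - _IUPAC
    if bad:
        raise ValueError(f"{context}: non-nucleotide symbols {sorted(bad)}")
    return up.translate(_AMBIG_TO_N)


def read_fasta(path: str | Path, name: str | None = None) -> Assembly:
    """Read a (multi-)FASTA file into an Assembly, normalizing sequences.

    Record order is preserved.  Duplicate ids, empty records and
    non-nucleotide symbols are errors.
    """
    path = Path(path)
    scaffolds: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in scaffolds:
            raise ValueError(f"{path}: duplicate scaffold id {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: empty record {rec.id!r}")
        scaffolds[rec.id] = normalize_sequence(seq, context=f"{path}:{rec.id}")
    if not scaffolds:
        raise ValueError(f"{path}: no FASTA records found")
    return Assembly(name=name or path.stem, scaffolds=scaffolds)


def write_fasta(assembly: Assembly, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in assembly.scaffolds.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def split_contigs(assembly: Assembly, min_gap: int = 10) -> list[Interval]:
    """Cut every scaffold at each run of >= min_gap consecutive N.

    Runs shorter than min_gap stay inside a contig; all-N scaffolds yield no
    contig.  Returned intervals never overlap and tile each scaffold minus
    the cut gap runs.
    """
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    contigs: list[Interval] = []
    for sid, seq in assembly.scaffolds.items():
        pos = 0
        n = len(seq)
        cut_points: list[tuple[int, int]] = []
        i = 0
        while True:
            j = seq.find("N", i)
            if j == -1:
                break
            k = j
            while k < n and seq[k] == "N":
                k += 1
            if k - j >= min_gap:
                cut_points.append((j, k))
            i = k
        for gap_start, gap_end in cut_points:
            if gap_start > pos:
                contigs.append(Interval(sid, pos, gap_start))
            pos = gap_end
        if pos < n:
            seg = seq[pos:]
            if set(seg) != {"N"}:
                contigs.append(Interval(sid, pos, n))
            # a trailing sub-threshold all-N segment still counts as contig
            # only if it contains non-N; pure-N remainder (whole scaffold N
            # with short runs) is dropped
    return contigs


def read_chromosome_map(path: str | Path) -> ChromosomeMap:
    """Read a two-column TSV (scaffold, chromosome).

    A scaffold listed twice with conflicting chromosomes is an error;
    an empty file yields an empty map (every scaffold unplaced).
    """
    entries: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sid, chrom = parts
            if sid in entries and entries[sid] != chrom:
                raise ValueError(
                    f"{path}:{lineno}: scaffold {sid!r} mapped to both "
                    f"{entries[sid]!r} and {chrom!r}"
                )
            entries[sid] = chrom
    return ChromosomeMap(entries=entries)
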