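"""Whole-assembly summary statistics: lengths, scaffold/contig counts, N50.

Conventions: scaffold statistics are computed on gapped spans (N included);
contig statistics on the N-light segments produced by
:func:`microsynt.genome_io.split_contigs` (a contig can retain N runs shorter
than ``min_gap``).  The scaffold length filter is strict (> ``min_scaffold_len``).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from microsynt.genome_io import Assembly, split_contigs

__all__ = ["AssemblyStats", "nstat", "summarize_assembly", "round_half_up"]


@dataclass(frozen=True)
class AssemblyStats:
    name: str
    total_sequence_length: int  # bases excluding N
    total_assembly_length: int  # span including N gaps
    n_scaffolds: int
    scaffold_n50: int
    n_contigs: int
    contig_n50: int

    def as_dict(self) -> dict[str, int | str]:
        return {
            "assembly": self.name,
            "total_sequence_length": self.total_sequence_length,
            "total_assembly_length": self.total_assembly_length,
            "n_scaffolds": self.n_scaffolds,
            "scaffold_n50": self.scaffold_n50,
            "n_contigs": self.n_contigs,
            "contig_n50": self.contig_n50,
        }


def nstat(lengths: list[int], fraction: float = 0.5) -> int:
    """N-statistic: smallest L with sum(lengths >= L) >= fraction * total.

    nstat(lengths, 0.5) is the standard N50.  Invariant to input order and to
    duplicating the whole list; non-increasing in ``fraction``.
    """
    if not lengths:
        raise ValueError("nstat of an empty length list")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    target = fraction * sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= target:
            return length
    raise AssertionError("unreachable: cumulative sum must reach total")


def summarize_assembly(
    assembly: Assembly, min_scaffold_len: int = 0, min_gap: int = 10
) -> AssemblyStats:
    """Compute the six summary statistics after a strict scaffold-length filter.

    Scaffolds of length <= ``min_scaffold_len`` are excluded before anything
    else is computed (the filtered assembly is what contigs are derived from).
    """
    kept = {
        sid: seq
        for sid, seq in assembly.scaffolds.items()
        if len(seq) > min_scaffold_len
    }
    if not kept:
        raise ValueError(
            f"length filter > {min_scaffold_len} removed all scaffolds of "
            f"{assembly.name}"
        )
    filtered = Assembly(name=assembly.name, scaffolds=kept)
    contigs = split_contigs(filtered, min_gap=min_gap)
    scaffold_spans = [len(s) for s in kept.values()]
    contig_lengths = [
        len(filtered[c.scaffold][c.start : c.end])
        - filtered[c.scaffold][c.start : c.end].count("N")
        for c in contigs
    ]
    return AssemblyStats(
        name=assembly.name,
        total_sequence_length=filtered.total_sequence(),
        total_assembly_length=filtered.total_span(),
        n_scaffolds=len(kept),
        scaffold_n50=nstat(scaffold_spans, 0.5),
        n_contigs=len(contigs),
        contig_n50=nstat(contig_lengths, 0.5) if contig_lengths else 0,
    )


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for Mb/Kb reporting)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
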