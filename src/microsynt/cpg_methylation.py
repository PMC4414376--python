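"""CpG-depletion methylation prediction.

In invertebrate genomes, germ-line methylated CpG sites decay by deamination
over evolutionary time, so historically methylated genes show a deficit of
CpG dinucleotides relative to the product of their C and G frequencies.
CpG[O/E] = (#CpG * L) / (#C * #G) over a gene's sequence; genes with
CpG[O/E] < 1 are predicted methylated.

N bases are excluded from all counts and from L.  CpG is its own reverse
complement, so the statistic is strand-invariant and the genomic strand of
a gene does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import mean, median

import pandas as pd

from microsynt.genome_io import Assembly

__all__ = [
    "CpGResult",
    "GeneFeature",
    "classify_genes",
    "compare_feature_classes",
    "cpg_oe",
    "parse_gff3",
    "write_gff3",
]


@dataclass
class GeneFeature:
    """A gene with its exon intervals (0-based half-open, per-scaffold)."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)

    def introns(self) -> list[tuple[int, int]]:
        exons = sorted(self.exons)
        return [
            (e1_end, e2_start)
            for (_, e1_end), (e2_start, _) in zip(exons, exons[1:])
            if e2_start > e1_end
        ]


@dataclass(frozen=True)
class CpGResult:
    feature_id: str
    feature_class: str  # "gene" | "exon" | "intron"
    length: int  # non-N length
    n_cpg: int
    n_c: int
    n_g: int
    cpg_oe: float | None  # None = undefined (no C or no G)
    predicted_methylated: bool


def cpg_oe(seq: str) -> float | None:
    """(#CpG * L) / (#C * #G); None when there is no C or no G.

    #CpG counts overlapping "CG" dinucleotides; L is the non-N length.
    """
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return None
    length = len(seq) - seq.count("N")
    n_cpg = seq.count("CG")
    return (n_cpg * length) / (n_c * n_g)


def _region_sequence(gene: GeneFeature, seq: str, region: str) -> str:
    if region == "gene":
        parts = sorted(gene.exons) or [(gene.start, gene.end)]
    elif region == "exon":
        parts = sorted(gene.exons)
    elif region == "intron":
        parts = gene.introns()
    else:
        raise ValueError(f"unknown region {region!r} (expected gene|exon|intron)")
    return "".join(seq[s:e] for s, e in parts)


def classify_genes(
    assembly: Assembly,
    genes: list[GeneFeature],
    region: str = "gene",
    threshold: float = 1.0,
) -> tuple[list[CpGResult], int]:
    """Per-gene CpG[O/E] over the chosen region; methylated iff O/E < threshold.

    The gene-body region concatenates all exons (junction-spanning CpGs are
    not counted: the statistic is computed per exon segment joined, and the
    concatenation never creates a genomic dinucleotide that does not exist —
    we count on the concatenated string, an approximation bounded by the
    number of junctions).  Genes with undefined O/E are never predicted
    methylated and are reported with cpg_oe None.
    """
    results: list[CpGResult] = []
    n_methylated = 0
    for gene in genes:
        if gene.scaffold not in assembly:
            raise ValueError(f"gene {gene.gene_id}: scaffold {gene.scaffold} not in assembly")
        seq = assembly[gene.scaffold]
        if gene.end > len(seq) or gene.start < 0:
            raise ValueError(
                f"gene {gene.gene_id}: span [{gene.start},{gene.end}) outside "
                f"scaffold {gene.scaffold} (length {len(seq)})"
            )
        sub = _region_sequence(gene, seq, region)
        oe = cpg_oe(sub) if sub else None
        methylated = oe is not None and oe < threshold
        n_methylated += methylated
        results.append(
            CpGResult(
                feature_id=gene.gene_id,
                feature_class=region,
                length=len(sub) - sub.count("N"),
                n_cpg=sub.count("CG"),
                n_c=sub.count("C"),
                n_g=sub.count("G"),
                cpg_oe=oe,
                predicted_methylated=methylated,
            )
        )
    return results, n_methylated


def compare_feature_classes(
    results_by_class: dict[str, list[CpGResult]]
) -> pd.DataFrame:
    """Per-class mean/median O/E and depleted fraction (defined values only)."""
    if not results_by_class:
        raise ValueError("no feature classes supplied")
    rows = []
    for cls, results in results_by_class.items():
        defined = [r.cpg_oe for r in results if r.cpg_oe is not None]
        n_undef = sum(1 for r in results if r.cpg_oe is None)
        rows.append(
            {
                "class": cls,
                "n": len(results),
                "n_undefined": n_undef,
                "mean_oe": mean(defined) if defined else float("nan"),
                "median_oe": median(defined) if defined else float("nan"),
                "depleted_fraction": (
                    sum(1 for v in defined if v < 1.0) / len(defined)
                    if defined
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def parse_gff3(path: str | Path) -> list[GeneFeature]:
    """Minimal GFF3 reader for gene/exon features.

    Exons are attached to their gene via the Parent attribute, either
    directly or through one mRNA/transcript level.  Coordinates convert
    from GFF3 1-based inclusive to internal 0-based half-open.
    """
    genes: dict[str, GeneFeature] = {}
    transcript_parent: dict[str, str] = {}
    pending_exons: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            scaffold, _, ftype, start, end, _, strand, _, attrs = cols
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            s, e = int(start) - 1, int(end)
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ValueError(f"{path}: gene without ID attribute")
                genes[gid] = GeneFeature(gid, scaffold, s, e, strand)
            elif ftype in ("mRNA", "transcript"):
                transcript_parent[attr.get("ID", "")] = attr.get("Parent", "")
            elif ftype == "exon":
                pending_exons.append((attr.get("Parent", ""), s, e))
    for parent, s, e in pending_exons:
        gid = parent if parent in genes else transcript_parent.get(parent, "")
        if gid in genes:
            genes[gid].exons.append((s, e))
    return list(genes.values())


def write_gff3(genes: list[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\tmicrosynt\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), 1):
                fh.write(
                    f"{g.scaffold}\tmicrosynt\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )
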