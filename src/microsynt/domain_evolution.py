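"""Comparative protein-domain statistics between two species' annotations.

Inputs are per-species tables of ordered Pfam-model hits on proteins (one
record per gene; longest transcript only is an upstream responsibility).
Provided statistics: domains unique to the focal species, expansion or
contraction of per-domain occurrence counts (two-sided Fisher's exact test
on once-per-gene counts, raw P values), and within-protein repeat-number
comparison across domain arrangements.

Two hits of the same domain that cover one Pfam model consecutively (the
second resumes on the model where the first stopped, and lies nearby on the
protein) are a split hit and merged into one domain; two full-model copies
are a genuine tandem repeat and stay separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "DOMAIN_TABLE_COLUMNS",
    "collapse_consecutive",
    "compare_repeat_numbers",
    "count_domains",
    "fisher_expansion_test",
    "read_domain_table",
    "scan_expansions",
    "unique_domains",
    "write_domain_table",
]

DOMAIN_TABLE_COLUMNS = [
    "gene",
    "domain",
    "protein_start",
    "protein_end",
    "model_start",
    "model_end",
]


def read_domain_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DOMAIN_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[DOMAIN_TABLE_COLUMNS].sort_values(
        ["gene", "protein_start"], kind="stable", ignore_index=True
    )


def write_domain_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def collapse_consecutive(
    hits: pd.DataFrame, model_tolerance: int = 10, protein_gap: int = 30
) -> pd.DataFrame:
    """Merge split coverage of one model into a single domain hit.

    Adjacent same-domain hits merge when the second hit's model start
    resumes within ``model_tolerance`` of the first hit's model end AND the
    protein-coordinate gap between them is at most ``protein_gap`` residues.
    Independent full-model repeats (model start back near the model's
    beginning) are not merged.
    """
    if hits.empty:
        return hits.copy()
    out_rows: list[dict] = []
    for gene, g in hits.sort_values(["gene", "protein_start"], kind="stable").groupby(
        "gene", sort=False
    ):
        current: dict | None = None
        for row in g.to_dict("records"):
            if (
                current is not None
                and row["domain"] == current["domain"]
                and abs(row["model_start"] - current["model_end"]) <= model_tolerance
                and row["model_start"] > current["model_start"]
                and 0 <= row["protein_start"] - current["protein_end"] <= protein_gap
            ):
                current["protein_end"] = row["protein_end"]
                current["model_end"] = row["model_end"]
                continue
            if current is not None:
                out_rows.append(current)
            current = dict(row)
        if current is not None:
            out_rows.append(current)
    return pd.DataFrame(out_rows, columns=hits.columns).reset_index(drop=True)


def count_domains(annotations: pd.DataFrame) -> dict[str, int]:
    """Per-domain count of genes containing it at least once."""
    if annotations.empty:
        return {}
    return (
        annotations.drop_duplicates(["gene", "domain"])
        .groupby("domain")["gene"]
        .count()
        .to_dict()
    )


def unique_domains(
    focal: dict[str, int], references: list[dict[str, int]]
) -> set[str]:
    """Domains present in the focal species and absent in every reference."""
    if not references:
        raise ValueError("unique_domains requires at least one reference species")
    present_elsewhere: set[str] = set()
    for ref in references:
        present_elsewhere |= {d for d, c in ref.items() if c > 0}
    return {d for d, c in focal.items() if c > 0} - present_elsewhere


def fisher_expansion_test(
    count_focal: int, total_focal: int, count_ref: int, total_ref: int
) -> float:
    """Two-sided Fisher's exact P for a domain's occurrence proportions.

    Table: [[count_focal, total_focal - count_focal],
            [count_ref,   total_ref   - count_ref]].
    """
    if total_focal <= 0 or total_ref <= 0:
        raise ValueError("totals must be positive")
    if count_focal > total_focal or count_ref > total_ref:
        raise ValueError("counts exceed totals")
    table = [
        [count_focal, total_focal - count_focal],
        [count_ref, total_ref - count_ref],
    ]
    return float(fisher_exact(table, alternative="two-sided").pvalue)


@dataclass(frozen=True)
class ExpansionResult:
    domain: str
    count_focal: int
    count_ref: int
    total_focal: int
    total_ref: int
    p_value: float
    direction: str  # "expanded" | "contracted" (in the focal species)


def scan_expansions(
    table_focal: dict[str, int],
    table_ref: dict[str, int],
    alpha: float = 0.05,
) -> list[ExpansionResult]:
    """Test every domain present in either species; report raw P < alpha.

    Margins are the total once-per-gene domain instances in each species.
    No multiple-testing correction is applied by default.
    """
    if not table_focal or not table_ref:
        raise ValueError("both domain count tables must be non-empty")
    total_focal = sum(table_focal.values())
    total_ref = sum(table_ref.values())
    results: list[ExpansionResult] = []
    for domain in sorted(set(table_focal) | set(table_ref)):
        cf = table_focal.get(domain, 0)
        cr = table_ref.get(domain, 0)
        p = fisher_expansion_test(cf, total_focal, cr, total_ref)
        if p < alpha:
            direction = (
                "expanded" if cf / total_focal > cr / total_ref else "contracted"
            )
            results.append(
                ExpansionResult(domain, cf, cr, total_focal, total_ref, p, direction)
            )
    return results


def _arrangements(annotations: pd.DataFrame) -> dict[tuple[str, ...], list[dict[str, int]]]:
    """Cluster genes by their domain arrangement (set of domains, ignoring
    copy number and order); each member gene contributes its per-domain
    repeat counts."""
    out: dict[tuple[str, ...], list[dict[str, int]]] = {}
    for gene, g in annotations.groupby("gene", sort=False):
        arrangement = tuple(sorted(g["domain"].unique()))
        counts = g.groupby("domain")["gene"].count().to_dict()
        out.setdefault(arrangement, []).append(counts)
    return out


def compare_repeat_numbers(
    annotations_1: pd.DataFrame, annotations_2: pd.DataFrame
) -> pd.DataFrame:
    """Min/max within-protein repeat counts per (arrangement, domain).

    Only arrangements present in both species and occurring at least twice
    in at least one species are kept.  A domain whose repeat-count ranges do
    not overlap between the species is flagged disjoint.
    """
    arr1 = _arrangements(annotations_1)
    arr2 = _arrangements(annotations_2)
    rows = []
    for arrangement in sorted(set(arr1) & set(arr2)):
        members1, members2 = arr1[arrangement], arr2[arrangement]
        if max(len(members1), len(members2)) < 2:
            continue
        for domain in arrangement:
            c1 = [m.get(domain, 0) for m in members1]
            c2 = [m.get(domain, 0) for m in members2]
            lo1, hi1, lo2, hi2 = min(c1), max(c1), min(c2), max(c2)
            rows.append(
                {
                    "arrangement": ";".join(arrangement),
                    "domain": domain,
                    "min_1": lo1,
                    "max_1": hi1,
                    "min_2": lo2,
                    "max_2": hi2,
                    "n_proteins_1": len(members1),
                    "n_proteins_2": len(members2),
                    "disjoint": hi1 < lo2 or hi2 < lo1,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "arrangement", "domain", "min_1", "max_1", "min_2", "max_2",
            "n_proteins_1", "n_proteins_2", "disjoint",
        ],
    )
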