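"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised/library code paths:
the SSR oracle is a character-by-character scan, and the Fisher oracle is
a full hypergeometric enumeration with exact integer binomials.
"""

from __future__ import annotations

from math import comb


def _reducible(motif: str) -> bool:
    n = len(motif)
    return any(
        n % p == 0 and motif == motif[:p] * (n // p) for p in range(1, n)
    )


def _canonical(motif: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(motif))
    n = len(motif)
    return min(
        [motif[i:] + motif[:i] for i in range(n)]
        + [rc[i:] + rc[:i] for i in range(n)]
    )


def ssr_scan_oracle(
    seq: str, min_units: dict[int, int]
) -> set[tuple[int, int, str, int]]:
    """All maximal perfect tandem runs as (start, end, canonical motif, units).

    For each period k, a maximal run of positions j with seq[j] == seq[j+k]
    (neither being N) of length r spans a tandem array of total length r+k;
    only whole units anchored at the run start are kept, and runs whose
    leading motif is a repetition of a shorter motif are left to that
    shorter period.
    """
    n = len(seq)
    out: set[tuple[int, int, str, int]] = set()

    def eq(j: int, k: int) -> bool:
        return (
            0 <= j and j + k < n
            and seq[j] != "N" and seq[j + k] != "N"
            and seq[j] == seq[j + k]
        )

    for k, mu in min_units.items():
        i = 0
        while i + k < n:
            if not eq(i, k) or eq(i - 1, k):
                i += 1
                continue
            j = i
            while eq(j, k):
                j += 1
            total = (j - i) + k
            units = total // k
            motif = seq[i : i + k]
            if units >= mu and "N" not in motif and not _reducible(motif):
                out.add((i, i + k * units, _canonical(motif), units))
            i = j
    return out


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact P by summing all tables with probability not
    exceeding the observed one (standard 1e-7 relative tie tolerance)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    def pmf(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom
    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return min(
        1.0,
        sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-7)),
    )
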