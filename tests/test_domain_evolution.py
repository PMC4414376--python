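import numpy as np
import pandas as pd
import pytest

from microsynt.domain_evolution import (
    collapse_consecutive,
    compare_repeat_numbers,
    count_domains,
    fisher_expansion_test,
    scan_expansions,
    unique_domains,
)
from oracles import fisher_two_sided_oracle


def _hits(rows):
    return pd.DataFrame(
        rows,
        columns=["gene", "domain", "protein_start", "protein_end",
                 "model_start", "model_end"],
    )


class TestCollapseConsecutive:
    def test_split_model_coverage_merged(self):
        df = _hits([
            ("g1", "A", 10, 50, 1, 40),
            ("g1", "A", 55, 95, 41, 80),
        ])
        out = collapse_consecutive(df)
        assert len(out) == 1
        assert out.iloc[0]["model_start"] == 1 and out.iloc[0]["model_end"] == 80

    def test_two_full_copies_not_merged(self):
        df = _hits([
            ("g1", "A", 10, 90, 1, 80),
            ("g1", "A", 100, 180, 1, 80),
        ])
        assert len(collapse_consecutive(df)) == 2

    def test_interleaved_domains_unchanged(self):
        df = _hits([
            ("g1", "A", 10, 50, 1, 40),
            ("g1", "B", 60, 100, 1, 40),
            ("g1", "A", 110, 150, 41, 80),
        ])
        assert len(collapse_consecutive(df)) == 3

    def test_distant_on_protein_not_merged(self):
        df = _hits([
            ("g1", "A", 10, 50, 1, 40),
            ("g1", "A", 500, 540, 41, 80),  # 450-residue gap
        ])
        assert len(collapse_consecutive(df)) == 2


class TestCountDomains:
    def test_once_per_gene(self):
        df = _hits([
            ("g1", "A", 1, 10, 1, 10),
            ("g1", "A", 200, 210, 1, 10),
            ("g1", "B", 400, 410, 1, 10),
            ("g2", "A", 1, 10, 1, 10),
        ])
        assert count_domains(df) == {"A": 2, "B": 1}

    def test_empty(self):
        assert count_domains(_hits([])) == {}

    def test_invariant_to_hit_order(self, rng):
        rows = [
            (f"g{i}", d, int(p), int(p) + 10, 1, 10)
            for i in range(20)
            for d, p in zip(rng.choice(list("ABCD"), 5), rng.integers(0, 5000, 5))
        ]
        df = _hits(rows)
        shuffled = df.sample(frac=1, random_state=3)
        assert count_domains(df) == count_domains(shuffled)


class TestUniqueDomains:
    def test_set_difference(self):
        assert unique_domains({"A": 3, "B": 1}, [{"A": 5}, {"A": 2}]) == {"B"}
        assert unique_domains({"A": 1}, [{"A": 2, "B": 1}]) == set()

    def test_requires_references(self):
        with pytest.raises(ValueError):
            unique_domains({"A": 1}, [])


class TestFisher:
    @pytest.mark.parametrize(
        "cf, tf, cr, tr, expected",
        [
            (5, 100, 5, 100, 1.0),
            (3, 4, 1, 4, 0.4857142857142857),  # [[3,1],[1,3]]
            (0, 10, 10, 10, 1.0825088224469029e-05),  # [[0,10],[10,0]]
        ],
    )
    def test_enumerated_values(self, cf, tf, cr, tr, expected):
        assert fisher_expansion_test(cf, tf, cr, tr) == pytest.approx(
            expected, abs=1e-12
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fisher_expansion_test(1, 0, 1, 5)
        with pytest.raises(ValueError):
            fisher_expansion_test(6, 5, 1, 5)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            tf, tr = (int(x) for x in rng.integers(1, 201, size=2))
            cf = int(rng.integers(0, tf + 1))
            cr = int(rng.integers(0, tr + 1))
            p = fisher_expansion_test(cf, tf, cr, tr)
            q = fisher_two_sided_oracle(cf, tf - cf, cr, tr - cr)
            assert p == pytest.approx(q, abs=1e-9)


class TestScanExpansions:
    def test_identical_tables_empty(self):
        t = {"A": 50, "B": 60, "C": 10}
        assert scan_expansions(t, t) == []

    def test_implanted_contrast_flagged_with_direction(self):
        focal = {"A": 100, "B": 100, "RJ": 6}
        ref = {"A": 100, "B": 100, "RJ": 22}
        hits = scan_expansions(focal, ref)
        assert [h.domain for h in hits] == ["RJ"]
        assert hits[0].direction == "contracted"
        assert hits[0].p_value < 0.05

    def test_absent_in_focal_flagged_contracted(self):
        focal = {"A": 200}
        ref = {"A": 200, "Z": 30}
        hits = scan_expansions(focal, ref)
        assert any(h.domain == "Z" and h.direction == "contracted" for h in hits)


class TestCompareRepeatNumbers:
    def test_disjoint_ranges_flagged(self):
        sp1 = _hits(
            [("g1", "A", i * 200, i * 200 + 80, 1, 80) for i in range(3)]
            + [("g2", "A", i * 200, i * 200 + 80, 1, 80) for i in range(5)]
        )
        sp2 = _hits(
            [("g3", "A", i * 200, i * 200 + 80, 1, 80) for i in range(2)]
            + [("g4", "A", i * 200, i * 200 + 80, 1, 80) for i in range(2)]
        )
        out = compare_repeat_numbers(sp1, sp2)
        row = out.iloc[0]
        assert (row["min_1"], row["max_1"]) == (3, 5)
        assert (row["min_2"], row["max_2"]) == (2, 2)
        assert bool(row["disjoint"])

    def test_arrangement_must_recur(self):
        sp1 = _hits([("g1", "A", 0, 80, 1, 80)])
        sp2 = _hits([("g2", "A", 0, 80, 1, 80)])
        assert compare_repeat_numbers(sp1, sp2).empty

    def test_arrangement_must_be_shared(self):
        sp1 = _hits([("g1", "A", 0, 80, 1, 80), ("g2", "A", 0, 80, 1, 80)])
        sp2 = _hits([("g3", "B", 0, 80, 1, 80), ("g4", "B", 0, 80, 1, 80)])
        assert compare_repeat_numbers(sp1, sp2).empty
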