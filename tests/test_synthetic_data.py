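import statistics

import numpy as np
import pytest

from microsynt import synthetic_data as sd
from microsynt.cpg_methylation import cpg_oe
from microsynt.ssr_detect import find_ssrs

SMALL = sd.SimParams(
    genome_size=1_000_000, n_chromosomes=2, n_inversions=1, n_translocations=1
)


class TestAncestor:
    def test_deterministic_under_seed(self):
        a1 = sd.simulate_ancestor(SMALL, np.random.default_rng(5))
        a2 = sd.simulate_ancestor(SMALL, np.random.default_rng(5))
        assert all(
            np.array_equal(a1.chromosomes[c], a2.chromosomes[c])
            for c in a1.chromosomes
        )
        assert a1.loci == a2.loci

    def test_implanted_density_by_construction(self):
        params = sd.SimParams(
            genome_size=2_000_000, n_chromosomes=2, ssr_density_per_mb=30,
            n_inversions=0, n_translocations=0,
        )
        anc = sd.simulate_ancestor(params, np.random.default_rng(1))
        # at least the 60 implanted loci; chance background loci may add a few
        assert 60 <= len(anc.loci) <= 60 + 30

    def test_scanner_recovers_every_truth_locus(self):
        anc = sd.simulate_ancestor(SMALL, np.random.default_rng(9))
        for chrom, arr in anc.chromosomes.items():
            found = {
                (l.start, l.end) for l in find_ssrs(arr.tobytes().decode())
            }
            for lid in anc.order[chrom]:
                _, s, e, _ = anc.loci[lid]
                assert (s, e) in found

    def test_impossible_density_rejected(self):
        params = sd.SimParams(
            genome_size=100_000, n_chromosomes=1, ssr_density_per_mb=5000
        )
        with pytest.raises(ValueError, match="spacing"):
            sd.simulate_ancestor(params, np.random.default_rng(0))


class TestDeriveAssembly:
    def test_identity_when_nothing_happens(self):
        params = sd.SimParams(
            genome_size=500_000, n_chromosomes=2, mutation_rate=0.0,
            indel_rate=0.0, n_inversions=0, n_translocations=0,
        )
        ga, gb, _, _ = sd.simulate_genome_pair(params, 3)
        seqs_a = list(ga.assembly.scaffolds.values())
        seqs_b = list(gb.assembly.scaffolds.values())
        assert seqs_a == seqs_b

    def test_event_counts_by_construction(self):
        params = sd.SimParams(
            genome_size=2_000_000, n_chromosomes=4, n_inversions=3,
            n_translocations=2,
        )
        _, gb, _, specs = sd.simulate_genome_pair(params, 8)
        assert sum(1 for e in gb.events if e.kind == "intra") == 3
        assert sum(1 for e in gb.events if e.kind == "inter") == 2
        assert len(specs) == 5

    def test_empirical_mutation_rate(self):
        params = sd.SimParams(
            genome_size=1_000_000, n_chromosomes=1, mutation_rate=0.01,
            indel_rate=0.0, n_inversions=0, n_translocations=0,
        )
        rng = np.random.default_rng(4)
        anc = sd.simulate_ancestor(params, rng)
        derived = sd.derive_assembly(anc, params, "A", rng)
        (sid, seq), = derived.assembly.scaffolds.items()
        orig = anc.chromosomes["chr1"].tobytes().decode()
        mismatches = sum(a != b for a, b in zip(orig, seq))
        assert mismatches / len(orig) == pytest.approx(0.01, abs=0.002)

    def test_truth_coordinates_valid_under_fragmentation(self):
        params = sd.SimParams(
            genome_size=1_000_000, n_chromosomes=2, n_inversions=1,
            n_translocations=1, mean_scaffold_len=100_000,
            unplaced_fraction=0.2,
        )
        ga, gb, _, _ = sd.simulate_genome_pair(params, 6)
        for g in (ga, gb):
            assert len(g.assembly) > 2  # fragmentation happened
            for lid, (sid, s, e, orient) in g.loci.items():
                seq = g.assembly[sid]
                assert 0 <= s < e <= len(seq)
                assert "N" not in seq[s:e]
            assert len(g.chrom_map) < len(g.assembly)  # some unplaced

    def test_pair_generation_deterministic(self):
        g1 = sd.simulate_genome_pair(SMALL, 12)
        g2 = sd.simulate_genome_pair(SMALL, 12)
        assert g1[0].assembly.scaffolds == g2[0].assembly.scaffolds
        assert g1[1].assembly.scaffolds == g2[1].assembly.scaffolds
        assert g1[1].loci == g2[1].loci


class TestDomainSim:
    def test_implanted_contrast_present(self):
        params = sd.DomainSimParams(implanted_effects=((3, 4.0),))
        sim = sd.simulate_domain_tables(params, 5)
        d = sim.implanted_domains[0]
        assert sim.counts_2[d] > sim.counts_1.get(d, 0)

    def test_deterministic(self):
        s1 = sd.simulate_domain_tables(sd.DomainSimParams(), 7)
        s2 = sd.simulate_domain_tables(sd.DomainSimParams(), 7)
        assert s1.counts_1 == s2.counts_1
        assert s1.annotations_1.equals(s2.annotations_1)


class TestMethylomeSim:
    def test_realized_class_means_near_targets(self):
        sim = sd.simulate_methylome(sd.MethylomeSimParams(n_genes=400), 2)
        by = {}
        for gid, seq in sim.sequences.items():
            by.setdefault(sim.labels[gid], []).append(cpg_oe(seq))
        for cls, vals in by.items():
            target = sim.params.class_targets[cls]
            assert statistics.mean(vals) == pytest.approx(target, abs=0.05)

    def test_single_class(self):
        params = sd.MethylomeSimParams(
            n_genes=50, class_targets=(0.7,), class_proportions=(1.0,)
        )
        sim = sd.simulate_methylome(params, 1)
        assert set(sim.labels.values()) == {0}

    def test_deterministic(self):
        p = sd.MethylomeSimParams(n_genes=50)
        assert (
            sd.simulate_methylome(p, 9).sequences
            == sd.simulate_methylome(p, 9).sequences
        )

    def test_unattainable_target_rejected(self):
        params = sd.MethylomeSimParams(
            n_genes=5, gene_len=100, class_targets=(30.0,),
            class_proportions=(1.0,),
        )
        with pytest.raises(ValueError, match="unattainable"):
            sd.simulate_methylome(params, 1)
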