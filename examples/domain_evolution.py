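"""Protein-domain expansion/contraction and repeat-number comparison.

Simulates two species' Pfam-style annotation tables sharing a common
background, implants one 4-fold occurrence change for a single domain and
one repeat-number shift in a shared domain arrangement, then runs the two
statistics and shows that the implanted signals are recovered (the raw-P
scan additionally flags ~alpha of the null domains, by design).
"""

from microsynt import synthetic_data as sd
from microsynt.domain_evolution import compare_repeat_numbers, scan_expansions

params = sd.DomainSimParams(
    implanted_effects=((10, 4.0),),               # domain 10: 4x mean in species 2
    implanted_repeat_shifts=((5, (3, 5), (2, 2)),),  # arrangement 5: 3-5 vs 2 repeats
)
sim = sd.simulate_domain_tables(params, seed=7)

hits = scan_expansions(sim.counts_1, sim.counts_2, alpha=0.05)
implanted = set(sim.implanted_domains)
print(f"domains flagged at P < 0.05: {len(hits)} "
      f"(of {len(set(sim.counts_1) | set(sim.counts_2))} tested)")
for h in hits:
    tag = "implanted" if h.domain in implanted else "false positive (alpha risk)"
    print(f"  {h.domain}: {h.count_focal} vs {h.count_ref}, "
          f"P = {h.p_value:.2e}, {h.direction} in species 1 [{tag}]")

repeats = compare_repeat_numbers(sim.annotations_1, sim.annotations_2)
flagged = repeats[repeats["disjoint"]]
print(f"arrangement/domain pairs with disjoint repeat ranges: {len(flagged)}")
for row in flagged.itertuples():
    print(f"  {row.arrangement} / {row.domain}: "
          f"{row.min_1}-{row.max_1} vs {row.min_2}-{row.max_2}")
# The implanted fold-change is flagged with the smallest P value (plus ~5%
# of null domains, by construction of the raw-P threshold); the only
# disjoint repeat ranges come from the implanted arrangement.
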