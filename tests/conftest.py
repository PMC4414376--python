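from __future__ import annotations

import numpy as np
import pytest

from microsynt.genome_io import Assembly, Interval
from microsynt.marker_match import MarkerPair
from microsynt.ssr_detect import SSRLocus


@pytest.fixture
def tiny_assembly() -> Assembly:
    return Assembly(
        name="tiny",
        scaffolds={
            "s1": "ACGT" + "N" * 12 + "ACGTACGT",
            "s2": "ACACACACACAC" + "GATTACA" * 30,
        },
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250929)


def make_pair(
    ref_scaffold: str,
    ref_pos: int,
    partner_scaffold: str,
    partner_pos: int,
    orientation: str = "+",
    motif: str = "AC",
) -> MarkerPair:
    """A synthetic homologous marker pair with 12-bp loci (for track tests)."""
    a = SSRLocus(
        interval=Interval(ref_scaffold, ref_pos, ref_pos + 12),
        motif=motif, motif_len=2, n_units=6,
        left_flank="A" * 60, right_flank="A" * 60, usable=True,
    )
    b = SSRLocus(
        interval=Interval(partner_scaffold, partner_pos, partner_pos + 12),
        motif=motif, motif_len=2, n_units=6,
        left_flank="A" * 60, right_flank="A" * 60, usable=True,
    )
    return MarkerPair(
        locus_a=a, locus_b=b, identity=1.0, orientation=orientation,
        aligned_fraction=1.0,
    )
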