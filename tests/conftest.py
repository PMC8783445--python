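"""Shared fixtures: one toy locus and pre-mapped alignment sets per genotype.

The 30x alignment sets are expensive enough to share session-wide; tests
must not mutate them.
"""

import pytest

from microloh import align as al
from microloh.locus import Genotype, make_locus_model
from microloh.reference import build_hybrid_reference
from microloh.synth.wgs import simulate_wgs_readpairs

FRAGMENT_MEAN = 350.0
DEPTH30_FRAGMENTS = 4286  # 30x fragment depth on the 50 kb toy contig


@pytest.fixture(scope="session")
def locus():
    return make_locus_model(seed=1)


@pytest.fixture(scope="session")
def hybrid(locus):
    return build_hybrid_reference(locus)


@pytest.fixture(scope="session")
def aligned_30x(locus, hybrid):
    """Filtered 30x alignment sets per genotype: (proper-only, with-split)."""
    ref, _ = hybrid
    out = {}
    for i, gt in enumerate(Genotype):
        pairs = simulate_wgs_readpairs(
            locus, gt, DEPTH30_FRAGMENTS, dup_rate=0.02, seed=40 + i
        )
        aset = al.mark_duplicates(al.map_readpairs(pairs, ref))
        out[gt] = (
            al.filter_alignments(aset),
            al.filter_alignments(aset, require_proper=False),
        )
    return out
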