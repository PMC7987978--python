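import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth():
    """A 6 Mb instance with one window-aligned LOH segment."""
    from hicphaser.synthetic_data import GenomeParams, simulate_genome

    params = GenomeParams(length_bp=6_000_000,
                          loh_intervals=[(2_000_000, 3_000_000)])
    return simulate_genome(params, seed=11)


@pytest.fixture(scope="session")
def small_fragments(small_truth):
    from hicphaser.synthetic_data import simulate_hic

    return simulate_hic(small_truth, 120_000, eps=0.01, seed=11)


def make_block(indices, phase, block_id="b", region_id=0):
    from hicphaser.phasing import HaplotypeBlock

    return HaplotypeBlock(block_id, list(indices), list(phase), region_id)
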