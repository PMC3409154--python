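import numpy as np
import pytest

from crmchip.alignment import AlignmentBlock
from crmchip.simulate import demo_alignment_config, simulate_alignment


def single_row_block(seq: str, species: str = "mouse", chrom: str = "chr1", start: int = 0):
    return AlignmentBlock(ref_species=species, ref_chrom=chrom, ref_start=start,
                          rows=((species, seq),))


@pytest.fixture
def demo_alignment():
    """Seeded demo block: TAATCC planted at 800/2600/4400, conserved in 4/6/7 species."""
    return simulate_alignment(demo_alignment_config(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
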