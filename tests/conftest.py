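import numpy as np
import pytest

from bitrank import RankConfig

# reduced superblock widths so small inputs still cross superblock
# boundaries (both are multiples of 2*block)
SMALL_SB = {64: 256, 512: 1024}
DEFAULT_SB = 65536
BLOCK_WIDTHS = (64, 512)
STRATEGIES = ("mask", "shift")


def iter_configs(block_bits, superblock_bits):
    """All 8 layout/strategy combinations at one block/superblock width."""
    for layers in (1, 2):
        for paired in (False, True):
            for strategy in STRATEGIES:
                yield RankConfig(
                    block_bits=block_bits,
                    superblock_bits=superblock_bits,
                    paired=paired,
                    layers=layers,
                    strategy=strategy,
                )


def two_layer_config(block_bits, paired, superblock_bits=DEFAULT_SB, strategy="mask"):
    return RankConfig(
        block_bits=block_bits,
        superblock_bits=superblock_bits,
        paired=paired,
        layers=2,
        strategy=strategy,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
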