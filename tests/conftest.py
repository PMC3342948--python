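import numpy as np
import pytest

from tfcoreg.motif import PositionWeightMatrix
from tfcoreg.types import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ebox_pwm():
    """One-hot E-box-like consensus matrix (CANNTG family member)."""
    return PositionWeightMatrix.from_consensus("CATGTG", motif_id="ebox")


@pytest.fixture
def random_intervals(rng):
    """100 random valid intervals across two chromosomes, with names,
    scores and strands populated."""
    out = []
    for i in range(100):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(0, 10_000))
        length = int(rng.integers(1, 500))
        out.append(GenomicInterval(
            chrom, start, start + length,
            strand=["+", "-", "."][rng.integers(0, 3)],
            score=float(np.round(rng.uniform(0, 100), 3)),
            name=f"iv{i}",
        ))
    return out
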