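import numpy as np
import pytest

from asbkit.motif import PWMModel
from asbkit.types import AlleleCount, HetSNP


@pytest.fixture
def sharp_pwm() -> PWMModel:
    """A width-10 near-one-hot PWM: strong consensus, finite log-odds."""
    rng = np.random.default_rng(42)
    counts = np.full((4, 10), 1.0)
    counts[rng.integers(0, 4, size=10), np.arange(10)] = 97.0
    return PWMModel.from_counts(counts, name="sharp", pseudocount=1.0)


@pytest.fixture
def random_pwm_factory():
    """Factory for random PWMs of a given width (positive probabilities)."""

    def make(width: int, seed: int = 0) -> PWMModel:
        rng = np.random.default_rng(seed)
        counts = rng.uniform(1.0, 50.0, size=(4, width))
        return PWMModel.from_counts(counts, name=f"rand{width}", pseudocount=0.5)

    return make


def make_count(ref: int, alt: int, *, chrom="chr1", pos=100, rsid="rs1",
               ref_allele="A", alt_allele="G") -> AlleleCount:
    snp = HetSNP(chrom, pos, rsid, ref_allele, alt_allele)
    return AlleleCount(snp, ref, alt)


@pytest.fixture
def count_factory():
    return make_count
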