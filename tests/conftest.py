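import numpy as np
import pytest

from basetf.core import PWM, PromoterRegion


@pytest.fixture
def sharp_pwm():
    """Near-deterministic 4-bp motif on consensus ACGT (0.97 per row)."""
    matrix = np.full((4, 4), 0.01)
    for i, base in enumerate("ACGT"):
        matrix[i, "ACGT".index(base)] = 0.97
    return PWM(motif_id="SHARP", factor_name="SharpFactor", matrix=matrix,
               is_probability=True)


def make_promoter(seq, gene_id="g1", start=0, strand="+"):
    return PromoterRegion(
        gene_id=gene_id, chrom="chr1", start=start, end=start + len(seq),
        strand=strand, sequence=seq,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
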