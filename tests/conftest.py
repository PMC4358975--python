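import numpy as np
import pytest

from clonechron.io_formats import SomaticMutation


def binom_cohort(rng, n, vaf, depth_mean=105, chrom="chr1", start_id=0):
    """n mutations with Poisson depths and binomial alt counts at `vaf`."""
    depths = np.maximum(rng.poisson(depth_mean, n), 1)
    alts = rng.binomial(depths, vaf)
    return [
        SomaticMutation(f"m{start_id + i}", chrom, start_id + i + 1,
                        int(d - a), int(a))
        for i, (d, a) in enumerate(zip(depths, alts))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
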