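import numpy as np
import pytest

from spikepattern import spikegen

# reference operating point used across the suite
REF = dict(N=10_000, f=3.2, L=0.1, T=0.0032, tau=0.018, dt_opt=0.023)


@pytest.fixture(scope="session")
def small_pattern():
    """A small frozen pattern for classifier/selection fixtures."""
    cfg = spikegen.PatternConfig(N=2000, f=3.2, L=0.1, seed=5)
    return spikegen.generate_pattern(cfg)


@pytest.fixture(scope="session")
def ref_pattern():
    """A full-size reference pattern (N=1e4, f=3.2 Hz, L=100 ms)."""
    cfg = spikegen.PatternConfig(N=REF["N"], f=REF["f"], L=REF["L"], seed=11)
    return spikegen.generate_pattern(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
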