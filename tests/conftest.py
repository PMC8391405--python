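import numpy as np
import pytest

from passnet import SyntheticSpec, canonical_fixtures, generate


@pytest.fixture(scope="session")
def fixtures():
    return canonical_fixtures()


@pytest.fixture(scope="session")
def random_graphs():
    """A reusable batch of random match-like networks, n in 3..12."""

    def make(count, seed0=1000, n_lo=3, n_hi=12, total=300):
        rng = np.random.default_rng(seed0)
        graphs = []
        for k in range(count):
            n = int(rng.integers(n_lo, n_hi + 1))
            conc = float(rng.uniform(0.3, 3.0))
            graphs.append(
                generate(SyntheticSpec(n=n, total_passes=total, concentration=conc,
                                       seed=seed0 + k))
            )
        return graphs

    return make
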