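import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_pairs(rng, n, max_total=200, kd_lo=1e-6, kd_hi=1e3):
    """Random valid binding pairs on the testing grid."""
    from stoqssa import BindingPair

    out = []
    for _ in range(n):
        a_t = int(rng.integers(0, max_total + 1))
        b_t = int(rng.integers(0, max_total + 1))
        kd = float(np.exp(rng.uniform(np.log(kd_lo), np.log(kd_hi))))
        out.append(BindingPair(a_t, b_t, kd))
    return out
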