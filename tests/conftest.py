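import random

import pytest

from mqfilter import MQF, FilterConfig


@pytest.fixture
def rng():
    return random.Random(1234)


@pytest.fixture
def small_filter():
    """Exact-contract filter over a 16-bit fingerprint space (q=8, r=8)."""
    return MQF(FilterConfig(q=8, r=8, f_size=2, seed=7))


@pytest.fixture
def labeled_filter():
    return MQF(FilterConfig(q=10, r=10, f_size=2, label_bits=6,
                            block_label_bits=20, seed=7))


def fill_random(filt, rng, n_items, max_count=30, universe_bits=None):
    """Insert n_items distinct random fingerprints; returns the oracle dict."""
    bits = universe_bits or filt.config.p
    oracle = {}
    while len(oracle) < n_items:
        h = rng.randrange(1 << bits)
        c = rng.randrange(1, max_count + 1)
        filt.insert_hash(h, c)
        oracle[h] = oracle.get(h, 0) + c
    return oracle
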