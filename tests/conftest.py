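import numpy as np
import pytest

from etpt.io import TimeSeriesSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def constant_level_set(levels, n_per_level, t_len, noise_sd=0.0, rng=None):
    """Groups of (optionally jittered) constant nonnegative series."""
    rows, labels = [], []
    for g, level in enumerate(levels):
        block = np.full((n_per_level, t_len), float(level))
        if noise_sd and rng is not None:
            block = np.maximum(block + rng.normal(0, noise_sd, block.shape), 0.0)
        rows.append(block)
        labels.extend([g] * n_per_level)
    return TimeSeriesSet(np.vstack(rows)), np.asarray(labels)
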