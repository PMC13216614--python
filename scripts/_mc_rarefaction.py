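"""Brute-force Monte-Carlo rarefaction oracle used by the acceptance script."""

import numpy as np


def mc_rarefaction(abund, n=50, draws=100_000, seed=0):
    """Mean species count in seeded draws of n individuals without
    replacement, plus its standard error."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(abund)), abund)
    N = labels.size
    counts = np.empty(draws)
    block = max(1, int(2e7 // N))
    done = 0
    while done < draws:
        b = min(block, draws - done)
        keys = rng.random((b, N))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        sel = labels[idx]
        sel.sort(axis=1)
        counts[done:done + b] = 1 + (np.diff(sel, axis=1) != 0).sum(axis=1)
        done += b
    return counts.mean(), counts.std(ddof=1) / np.sqrt(draws)
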