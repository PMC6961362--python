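"""Independent brute-force oracles used by unit and acceptance tests."""

import numpy as np


def midranks(values):
    """Average ranks by direct counting (ties get the mean rank)."""
    values = np.asarray(values, float)
    return np.array([
        np.sum(values < v) + (np.sum(values == v) + 1) / 2.0 for v in values
    ])


def kruskal_wallis_oracle(groups):
    """Tie-corrected Kruskal-Wallis H from first principles."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        k = len(g)
        rbar = ranks[start:start + k].mean()
        h += k * (rbar - (n + 1) / 2.0) ** 2
        start += k
    h *= 12.0 / (n * (n + 1))
    ties = sum(int(np.sum(pooled == v)) ** 3 - int(np.sum(pooled == v))
               for v in np.unique(pooled))
    correction = 1.0 - ties / float(n**3 - n)
    if correction == 0:
        return 0.0
    return h / correction


def spearman_oracle(x, y):
    """Spearman rho as the Pearson correlation of mid-ranks."""
    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
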