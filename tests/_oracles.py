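"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the DFT oracle is a
naive O(M^2) double loop, the partition oracle enumerates every labelling,
and the ARI oracle applies the textbook contingency-table formula.
"""

from __future__ import annotations

import numpy as np
from scipy.special import comb


def naive_dft_magnitude(signal: np.ndarray, n_frames: int) -> np.ndarray:
    """O(M^2) discrete Fourier transform magnitude, first n_frames bins."""
    M = signal.size
    out = np.empty(n_frames)
    for k in range(n_frames):
        acc = 0.0 + 0.0j
        for s in range(M):
            acc += signal[s] * np.exp(-2j * np.pi * k * s / M)
        out[k] = abs(acc)
    return out


def direct_variability(f: np.ndarray, k: int = 1) -> tuple[float, float, float, float, float]:
    """Straight-from-formula recomputation of the five variability features."""
    m = len(f)
    mean = sum(f) / m
    var = sum((x - mean) ** 2 for x in f) / m
    dev = var**0.5
    denom = sum((x - mean) ** 2 for x in f)
    if denom == 0:
        r = 0.0
    else:
        r = sum((f[n] - mean) * (f[n + k] - mean) for n in range(m - k)) / denom
    total = sum(f)
    if total == 0:
        s = 0.0
    else:
        s = -sum((x / total) * np.log(x / total) for x in f if x > 0)
    return mean, dev, var, r, s


def exhaustive_min_wss(X: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    """Minimum within-cluster sum of squares over *all* k-labellings of X.

    Vectorised enumeration of the k^n assignments (n small); returns the
    minimal WSS and one achieving labelling.  Labellings that leave a cluster
    empty are allowed (they are equivalent to using fewer clusters and can
    never beat the best full partition for k <= n distinct points).
    """
    n, _ = X.shape
    n_assign = k**n
    idx = np.arange(n_assign)
    labels = (idx[:, None] // (k ** np.arange(n))) % k  # mixed-radix digits
    onehot = np.eye(k)[labels]  # (A, n, k)
    counts = onehot.sum(axis=1)  # (A, k)
    sums = np.einsum("ank,nd->akd", onehot, X)  # (A, k, d)
    sq = np.einsum("akd,akd->ak", sums, sums)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_cluster = np.where(counts > 0, sq / counts, 0.0)
    wss = float(np.sum(X**2)) - per_cluster.sum(axis=1)
    best = int(np.argmin(wss))
    return float(wss[best]), labels[best]


def textbook_ari(labels_a, labels_b) -> float:
    """Adjusted Rand index from the contingency table, textbook formula."""
    a_vals = sorted(set(labels_a))
    b_vals = sorted(set(labels_b))
    table = np.array(
        [[sum(1 for x, y in zip(labels_a, labels_b) if x == u and y == v) for v in b_vals]
         for u in a_vals]
    )
    n = table.sum()
    sum_comb = sum(comb(nij, 2) for nij in table.ravel())
    sum_a = sum(comb(ni, 2) for ni in table.sum(axis=1))
    sum_b = sum(comb(nj, 2) for nj in table.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))
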