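"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the vectorized code paths they are used to
check: scalar loops for the pixel statistics and thresholding rule,
exhaustive enumeration for the matching problem.
"""

import itertools

import numpy as np


def scalar_stats(frames):
    """Naive per-pixel double-loop mean and sample std (N-1 denominator)."""
    N, H, W = frames.shape
    mean = np.empty((H, W))
    std = np.empty((H, W))
    for p in range(H):
        for q in range(W):
            vals = [frames[i, p, q] for i in range(N)]
            m = sum(vals) / N
            var = sum((v - m) ** 2 for v in vals) / (N - 1)
            mean[p, q] = m
            std[p, q] = var ** 0.5
    return mean, std


def scalar_fe1(frames, T):
    """Triple-loop implementation of the mean/std thresholding rule."""
    N, H, W = frames.shape
    mean, std = scalar_stats(frames)
    out = np.zeros((N, H, W), dtype=bool)
    for i in range(N):
        for p in range(H):
            for q in range(W):
                out[i, p, q] = abs(frames[i, p, q] - mean[p, q]) \
                    > T * std[p, q]
    return out


def brute_force_max_matching(gt, pred, threshold):
    """Maximum matching cardinality by exhaustive enumeration over all
    injective pairings of gt to predicted points."""
    gt = np.asarray(gt, float).reshape(-1, 2)
    pred = np.asarray(pred, float).reshape(-1, 2)
    n, m = len(gt), len(pred)
    for k in range(min(n, m), 0, -1):
        for gsub in itertools.combinations(range(n), k):
            for psub in itertools.permutations(range(m), k):
                if all(np.hypot(*(gt[g] - pred[p])) <= threshold
                       for g, p in zip(gsub, psub)):
                    return k
    return 0
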