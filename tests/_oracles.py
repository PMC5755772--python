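"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the spanning-tree oracle
enumerates every labelled tree via Prüfer sequences, and the truncated-normal
oracle integrates the explicit density by quadrature instead of calling the
closed-form moments used by the implementation.
"""

import heapq
import itertools
import math

import numpy as np
from scipy import integrate


def prufer_to_edges(seq: tuple[int, ...], n: int) -> list[tuple[int, int]]:
    degree = [1] * n
    for s in seq:
        degree[s] += 1
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for s in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, s))
        degree[s] -= 1
        if degree[s] == 1:
            heapq.heappush(leaves, s)
    edges.append((heapq.heappop(leaves), heapq.heappop(leaves)))
    return edges


def brute_force_mst_total(D: np.ndarray) -> float:
    """Minimum spanning-tree weight by exhaustive enumeration of all n^(n-2)
    labelled trees (Cayley's formula) via Prüfer decoding."""
    n = D.shape[0]
    if n == 2:
        return float(D[0, 1])
    best = math.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        tot = sum(D[u, v] for u, v in prufer_to_edges(seq, n))
        if tot < best:
            best = tot
    return float(best)


def truncated_normal_moments_by_quadrature(
    mu: float, sigma: float, lower: float, upper: float
) -> tuple[float, float]:
    """Mean and SD of a truncated normal by numerical integration of its
    explicit density (normalised Gaussian kernel on [lower, upper])."""

    def kernel(x):
        return math.exp(-0.5 * ((x - mu) / sigma) ** 2)

    z, _ = integrate.quad(kernel, lower, upper)
    m, _ = integrate.quad(lambda x: x * kernel(x), lower, upper)
    m /= z
    v, _ = integrate.quad(lambda x: (x - m) ** 2 * kernel(x), lower, upper)
    return m, math.sqrt(v / z)
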