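"""Numba kernels for the O(n^2) measures (entropies, LZ76 parsing)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lz76_count(binary: np.ndarray) -> int:
    """Number of sub-strings in the LZ76 parsing of a binary sequence.

    Kaspar-Schuster formulation of the Lempel-Ziv 1976 production process.
    """
    n = binary.shape[0]
    c = 1
    prefix_len = 1
    i = 0
    k = 1
    kmax = 1
    while True:
        if binary[i + k - 1] == binary[prefix_len + k - 1]:
            k += 1
            if prefix_len + k > n:
                c += 1
                break
        else:
            if k > kmax:
                kmax = k
            i += 1
            if i == prefix_len:
                c += 1
                prefix_len += kmax
                if prefix_len + 1 > n:
                    break
                i = 0
                k = 1
                kmax = 1
            else:
                k = 1
    return c


@njit(cache=True)
def sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Template-match counts for sample entropy (self-matches excluded).

    Returns (A, B): A = pairs within Chebyshev tolerance r for length m+1,
    B = pairs within tolerance for length m.
    """
    n = x.shape[0]
    a = 0
    b = 0
    n_templates = n - m
    for i in range(n_templates - 1):
        for j in range(i + 1, n_templates):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


@njit(cache=True)
def apen_phi(x: np.ndarray, m: int, r: float) -> float:
    """phi(m) for approximate entropy (self-matches included)."""
    n = x.shape[0]
    n_templates = n - m + 1
    total = 0.0
    for i in range(n_templates):
        count = 0
        for j in range(n_templates):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                count += 1
        total += np.log(count / n_templates)
    return total / n_templates
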