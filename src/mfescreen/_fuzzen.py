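"""Numba kernel for fuzzy entropy.

The kernel enumerates all unordered template pairs (self-matches excluded),
removes each template's own baseline (its mean), takes the Chebyshev distance,
and accumulates the fuzzy membership exp(-(d/r)^n) for embedding dimensions m
and m+1 in a single pass. Template count is N - m for both dimensions so the
two means are comparable.

Membership terms whose exponent argument exceeds 60 are skipped: their
contribution (< 9e-27) is far below double-precision significance for any
attainable mean.
"""

from __future__ import annotations

import numba
import numpy as np

_SKIP_ARG = 60.0


@numba.njit(cache=True, fastmath=True)
def _phi_pair(y: np.ndarray, m: int, r: float, n: float):  # pragma: no cover - jit
    N = y.shape[0]
    T = N - m
    cm = np.empty(T)
    cm1 = np.empty(T)
    for i in range(T):
        s = 0.0
        for k in range(m):
            s += y[i + k]
        cm[i] = s / m
        cm1[i] = (s + y[i + m]) / (m + 1)
    inv_r = 1.0 / r
    sum_m = 0.0
    sum_m1 = 0.0
    n_is_2 = n == 2.0
    for i in range(T):
        for j in range(i + 1, T):
            ci = cm[i] - cm[j]
            ci1 = cm1[i] - cm1[j]
            dm = 0.0
            dm1 = 0.0
            for k in range(m):
                dk = y[i + k] - y[j + k]
                d = abs(dk - ci)
                if d > dm:
                    dm = d
                d = abs(dk - ci1)
                if d > dm1:
                    dm1 = d
            d = abs(y[i + m] - y[j + m] - ci1)
            if d > dm1:
                dm1 = d
            if n_is_2:
                a = dm * inv_r
                a = a * a
            else:
                a = (dm * inv_r) ** n
            if a < _SKIP_ARG:
                sum_m += np.exp(-a)
            if n_is_2:
                a = dm1 * inv_r
                a = a * a
            else:
                a = (dm1 * inv_r) ** n
            if a < _SKIP_ARG:
                sum_m1 += np.exp(-a)
    n_pairs = T * (T - 1) / 2.0
    return sum_m / n_pairs, sum_m1 / n_pairs
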