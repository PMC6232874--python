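"""Brute-force reference implementation of the cross-entropy metrics.

Everything here recomputes the metrics by explicit enumeration of all
template pairs — no histogramming, diagonal traversal, or pruning — and
exists solely as an independent check of the optimized counting path.
Intended for modest series lengths (N <= 2000).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .entropy import (
    EntropyParams,
    SeriesTooShortError,
    znormalize,
)

__all__ = ["entropy_oracle"]


@njit(cache=True)
def _count_matches(u, v, i, j_stop, length, r):
    # number of j in [0, j_stop) whose length-`length` template in v lies
    # within Chebyshev distance r of the template at i in u
    count = 0
    for j in range(j_stop):
        d = 0.0
        for k in range(length):
            dk = abs(u[i + k] - v[j + k])
            if dk > d:
                d = dk
        if d <= r:
            count += 1
    return count


def _oracle_sampen(us, vs, m, r, exclude_self, variant, on_no_matches):
    n = us.shape[0]
    n_t = n - m
    b = np.empty(n_t, dtype=np.int64)
    a = np.empty(n_t, dtype=np.int64)
    for i in range(n_t):
        b_i = _count_matches(us, vs, i, n_t, m, r)
        a_i = _count_matches(us, vs, i, n_t, m + 1, r)
        if exclude_self:
            d = max(abs(us[i + k] - vs[i + k]) for k in range(m))
            if d <= r:
                b_i -= 1
            d = max(abs(us[i + k] - vs[i + k]) for k in range(m + 1))
            if d <= r:
                a_i -= 1
        b[i] = b_i
        a[i] = a_i
    if variant == "literal":
        b_bar = float(np.mean(np.log(np.maximum(b, 1) / n_t)))
        a_bar = float(np.mean(np.log(np.maximum(a, 1) / n_t)))
        if b_bar == 0.0 or a_bar == 0.0:
            return float("nan")
        return float(-np.log(a_bar / b_bar))
    denom = float(n_t) * float(n_t)
    b_total, a_total = int(b.sum()), int(a.sum())
    if b_total == 0:
        return float("inf") if on_no_matches == "inf" else float(2.0 * np.log(n_t))
    if a_total == 0:
        if on_no_matches == "inf":
            return float("inf")
        return float(-np.log((1.0 / denom) / (b_total / denom)))
    return float(-np.log((a_total / denom) / (b_total / denom)))


def _oracle_apen(us, vs, m, r, correction):
    n = us.shape[0]
    c_m = np.empty(n - m + 1, dtype=np.float64)
    c_m1 = np.empty(n - m, dtype=np.float64)
    for i in range(n - m + 1):
        c_m[i] = _count_matches(us, vs, i, n - m + 1, m, r) / (n - m + 1)
    for i in range(n - m):
        c_m1[i] = _count_matches(us, vs, i, n - m, m + 1, r) / (n - m)
    if correction == "bias_max":
        sub = 1.0 / (n - m + 1)
        for i in range(n - m):
            if c_m1[i] == 0.0:
                c_m1[i] = sub
        for i in range(n - m + 1):
            if c_m[i] == 0.0:
                c_m[i] = c_m1[i] if i < n - m else sub
        return float(np.mean(np.log(c_m)) - np.mean(np.log(c_m1)))
    if correction == "bias_zero":
        phi_m = sum(np.log(x) for x in c_m if x > 0.0) / c_m.shape[0]
        phi_m1 = sum(np.log(x) for x in c_m1 if x > 0.0) / c_m1.shape[0]
        return float(phi_m - phi_m1)
    if np.any(c_m == 0.0) or np.any(c_m1 == 0.0):
        return float("nan")
    return float(np.mean(np.log(c_m)) - np.mean(np.log(c_m1)))


def entropy_oracle(u: np.ndarray, v: np.ndarray, params: EntropyParams) -> float:
    """Reference value of ``cross_entropy(u, v, params)`` by explicit loops."""
    us = znormalize(np.asarray(u, dtype=np.float64))
    vs = znormalize(np.asarray(v, dtype=np.float64))
    if us.shape[0] != vs.shape[0]:
        raise ValueError("series must have equal length")
    if us.shape[0] < params.m + 2:
        raise SeriesTooShortError("series too short for requested m")
    if params.metric == "cross_sampen":
        return _oracle_sampen(
            us, vs, params.m, params.r, params.self_match_exclusion,
            params.variant, params.on_no_matches,
        )
    return _oracle_apen(us, vs, params.m, params.r, params.correction)
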