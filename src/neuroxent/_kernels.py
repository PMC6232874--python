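"""Numba counting kernels shared by the cross-entropy metrics.

The kernels walk the template-distance matrix along its diagonals so that the
Chebyshev distance of a length-L template pair can be maintained as a running
maximum of the last L scalar distances.  A single pass therefore yields the
match counts for every template length up to ``l_max`` and every tolerance in
``rs`` simultaneously, which is what makes the (metric, m, r) parameter-grid
search affordable.

Counts are exact integers obtained from ``d <= r`` comparisons on float64
values; no approximation or pruning that could change a count is applied, so
the optimized path is count-identical to naive enumeration.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["match_counts", "cumulative_counts", "grid_cell_values"]


@njit(cache=True)
def _bin_index(d, rs):
    ri = 0
    while rs[ri] < d:
        ri += 1
    return ri


@njit(cache=True)
def _edge_counts(u, v, l_max, rs, last, diag):
    # Match indicators against the final template (j = N - L) and the equal
    # index template (j = i); used to restrict j ranges without a second pass.
    N = u.shape[0]
    rmax = rs[rs.shape[0] - 1]
    for L in range(1, l_max + 1):
        n_templates = N - L + 1
        j = n_templates - 1
        for i in range(n_templates):
            d = 0.0
            for k in range(L):
                dk = abs(u[i + k] - v[j + k])
                if dk > d:
                    d = dk
            if d <= rmax:
                last[L - 1, _bin_index(d, rs), i] += 1
            d = 0.0
            for k in range(L):
                dk = abs(u[i + k] - v[i + k])
                if dk > d:
                    d = dk
            if d <= rmax:
                diag[L - 1, _bin_index(d, rs), i] += 1


@njit(cache=True)
def _match_counts3(u, v, l_max, rs):
    # Specialization for template lengths <= 3 (the m in {1, 2} grid); keeps
    # the running maxima in scalars instead of arrays.
    N = u.shape[0]
    R = rs.shape[0]
    rmax = rs[R - 1]
    full = np.zeros((l_max, R, N), dtype=np.int64)
    full_t = np.zeros((l_max, R, N), dtype=np.int64)
    for c in range(-(N - 1), N):
        i0 = -c if c < 0 else 0
        j0 = i0 + c
        length = N - (i0 if i0 > j0 else j0)
        d1p = 0.0
        d1pp = 0.0
        for t in range(length):
            i = i0 + t
            j = i + c
            d1 = abs(u[i] - v[j])
            if d1 <= rmax:
                ri = _bin_index(d1, rs)
                full[0, ri, i] += 1
                full_t[0, ri, j] += 1
            if t >= 1 and l_max >= 2:
                d2 = d1 if d1 > d1p else d1p
                if d2 <= rmax:
                    ri = _bin_index(d2, rs)
                    full[1, ri, i - 1] += 1
                    full_t[1, ri, j - 1] += 1
                if t >= 2 and l_max >= 3:
                    d3 = d2 if d2 > d1pp else d1pp
                    if d3 <= rmax:
                        ri = _bin_index(d3, rs)
                        full[2, ri, i - 2] += 1
                        full_t[2, ri, j - 2] += 1
            d1pp = d1p
            d1p = d1
    last = np.zeros((l_max, R, N), dtype=np.int64)
    diag = np.zeros((l_max, R, N), dtype=np.int64)
    _edge_counts(u, v, l_max, rs, last, diag)
    return full, full_t, last, diag


@njit(cache=True)
def _match_counts_generic(u, v, l_max, rs):
    # dmax[L-1] holds, at diagonal step t, the running Chebyshev distance of
    # the length-L template pair ending at (i, j); the recurrence is
    # dmax_L(t) = max(d1(t), dmax_{L-1}(t - 1)).
    N = u.shape[0]
    R = rs.shape[0]
    rmax = rs[R - 1]
    full = np.zeros((l_max, R, N), dtype=np.int64)
    full_t = np.zeros((l_max, R, N), dtype=np.int64)
    dmax = np.zeros(l_max, dtype=np.float64)
    prev = np.zeros(l_max, dtype=np.float64)
    for c in range(-(N - 1), N):
        i0 = -c if c < 0 else 0
        j0 = i0 + c
        length = N - (i0 if i0 > j0 else j0)
        for t in range(length):
            i = i0 + t
            j = i + c
            d1 = abs(u[i] - v[j])
            dmax[0] = d1
            if d1 <= rmax:
                ri = _bin_index(d1, rs)
                full[0, ri, i] += 1
                full_t[0, ri, j] += 1
            for L in range(2, l_max + 1):
                if t < L - 1:
                    break
                dL = prev[L - 2]
                if d1 > dL:
                    dL = d1
                dmax[L - 1] = dL
                if dL <= rmax:
                    ri = _bin_index(dL, rs)
                    full[L - 1, ri, i - L + 1] += 1
                    full_t[L - 1, ri, j - L + 1] += 1
            for L in range(l_max):
                prev[L] = dmax[L]
    last = np.zeros((l_max, R, N), dtype=np.int64)
    diag = np.zeros((l_max, R, N), dtype=np.int64)
    _edge_counts(u, v, l_max, rs, last, diag)
    return full, full_t, last, diag


def match_counts(
    u: np.ndarray, v: np.ndarray, l_max: int, rs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Template match histograms between two z-normalized series.

    Parameters
    ----------
    u, v : float64[N]
        Equal-length series (normalization is the caller's business).
    l_max : int
        Largest template length needed (m + 1 for run length m).
    rs : float64[R]
        Ascending tolerance values.

    Returns
    -------
    full, full_t, last, diag : int64[l_max, R, N]
        Histogrammed counts (bin ri holds matches with
        ``rs[ri-1] < d <= rs[ri]``; cumulate over axis 1 to get counts at each
        tolerance).  ``full[L-1, :, i]`` counts templates of length L starting
        at ``j = 0 .. N-L`` in ``v`` that match the template starting at ``i``
        in ``u``.  ``full_t`` is the transpose direction (per-j counts against
        all i).  ``last`` flags a match against the final template
        (``j = N-L``), ``diag`` a match at ``j = i``.
    """
    u = np.ascontiguousarray(u, dtype=np.float64)
    v = np.ascontiguousarray(v, dtype=np.float64)
    rs = np.ascontiguousarray(rs, dtype=np.float64)
    if l_max <= 3:
        return _match_counts3(u, v, l_max, rs)
    return _match_counts_generic(u, v, l_max, rs)


def cumulative_counts(hist: np.ndarray) -> np.ndarray:
    """Turn histogram bins into counts-at-tolerance (cumsum over the r axis)."""
    return np.cumsum(hist, axis=1)


@njit(cache=True)
def _apen_cell(full, m, ri, n):
    # Cross-ApEn phi^m - phi^(m+1) with the bias-max correction, from one
    # direction's cumulative counts; mirrors entropy.apen_phi_difference.
    short_denom = n - m + 1
    long_denom = n - m
    sub = 1.0 / short_denom
    phi_m = 0.0
    phi_m1 = 0.0
    for j in range(long_denom):
        cl = full[m, ri, j]
        c1 = cl / long_denom if cl > 0 else sub
        phi_m1 += np.log(c1)
        cs = full[m - 1, ri, j]
        cm = cs / short_denom if cs > 0 else c1
        phi_m += np.log(cm)
    # the final length-m template has no length-(m+1) counterpart: floor
    cs = full[m - 1, ri, long_denom]
    cm = cs / short_denom if cs > 0 else sub
    phi_m += np.log(cm)
    return phi_m / short_denom - phi_m1 / long_denom


@njit(cache=True)
def grid_cell_values(
    full, full_t, last, diag, ms, n,
    want_sampen, want_apen, exclude_self, inf_on_no_matches,
):
    """All (m, r) cell values for one channel pair from cumulative counts.

    Default-settings fast path (canonical Cross-SampEn, bias-max Cross-ApEn);
    numerically equivalent to entropy.sampen_value / apen_phi_difference.

    Returns ``(sampen, apen_ij, apen_ji, degenerate)`` with shape
    ``[len(ms), R]`` each; ``degenerate`` counts (B == 0, A == 0) Cross-SampEn
    fallbacks so the caller can log them.
    """
    n_m = ms.shape[0]
    R = full.shape[1]
    sampen = np.full((n_m, R), np.nan)
    apen_ij = np.full((n_m, R), np.nan)
    apen_ji = np.full((n_m, R), np.nan)
    degenerate = np.zeros(2, dtype=np.int64)
    for mi in range(n_m):
        m = ms[mi]
        nt = n - m
        for ri in range(R):
            if want_sampen:
                b = np.int64(0)
                a = np.int64(0)
                for j in range(nt):
                    b += full[m - 1, ri, j] - last[m - 1, ri, j]
                    a += full[m, ri, j]
                if exclude_self:
                    for j in range(nt):
                        b -= diag[m - 1, ri, j]
                        a -= diag[m, ri, j]
                denom = float(nt) * float(nt)
                if b == 0:
                    degenerate[0] += 1
                    sampen[mi, ri] = np.inf if inf_on_no_matches else 2.0 * np.log(nt)
                elif a == 0:
                    degenerate[1] += 1
                    sampen[mi, ri] = (
                        np.inf if inf_on_no_matches else -np.log((1.0 / denom) / (b / denom))
                    )
                else:
                    sampen[mi, ri] = -np.log((a / denom) / (b / denom))
            if want_apen:
                apen_ij[mi, ri] = _apen_cell(full, m, ri, n)
                apen_ji[mi, ri] = _apen_cell(full_t, m, ri, n)
    return sampen, apen_ij, apen_ji, degenerate
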