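"""Numba-accelerated MIC kernel.

Implements exactly the same algorithm as the reference path in
:mod:`sadnet.network` (equipartitioned fixed axis, exact interval-partition
DP over clump candidate boundaries on the free axis, both orientations).
Falls back to nothing here — :mod:`sadnet.network` dispatches to the
reference implementation when numba is unavailable.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if len(args) == 1 and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _equip_nb(values: np.ndarray, k: int) -> np.ndarray:
    n = values.shape[0]
    order = np.argsort(values)
    assign = np.empty(n, np.int64)
    i = 0
    row = 0
    row_size = 0
    desired = n / k
    while i < n:
        j = i
        while j < n and values[order[j]] == values[order[i]]:
            j += 1
        block = j - i
        if (row_size != 0
                and abs(row_size + block - desired) >= abs(row_size - desired)
                and row < k - 1):
            row += 1
            row_size = 0
            desired = (n - i) / (k - row)
        for t in range(i, j):
            assign[order[t]] = row
        row_size += block
        i = j
    return assign


@njit(cache=True)
def _axis_nb(x: np.ndarray, rows: np.ndarray, ny: int, max_nx: int,
             c: float) -> np.ndarray:
    n = x.shape[0]
    order = np.argsort(x)
    xs = x[order]
    qs = rows[order]
    # clumps: equal-x atoms, adjacent pure same-row atoms merged
    bounds_tmp = np.empty(n + 1, np.int64)
    bounds_tmp[0] = 0
    nb = 1
    i = 0
    cur_pure = -2  # -2 = not started, -1 = impure
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        pure = qs[i]
        for t in range(i + 1, j):
            if qs[t] != pure:
                pure = -1
                break
        if cur_pure == -2:
            cur_pure = pure
        elif pure == -1 or cur_pure == -1 or pure != cur_pure:
            bounds_tmp[nb] = i
            nb += 1
            cur_pure = pure
        i = j
    bounds_tmp[nb] = n
    nb += 1
    k = nb - 1
    bounds = bounds_tmp[:nb].copy()
    max_candidates = max(int(c * max_nx), max_nx)
    if k > max_candidates:
        target = n / max_candidates
        keep = np.empty(k + 1, np.int64)
        keep[0] = 0
        nk = 1
        for t in range(1, k):
            if bounds[t] >= target * nk:
                keep[nk] = bounds[t]
                nk += 1
        if keep[nk - 1] != n:
            keep[nk] = n
            nk += 1
        bounds = keep[:nk].copy()
        k = nk - 1
    # cumulative per-row counts at each candidate boundary
    cum = np.zeros((k + 1, ny), np.float64)
    for t in range(1, k + 1):
        for r in range(ny):
            cum[t, r] = cum[t - 1, r]
        for p in range(bounds[t - 1], bounds[t]):
            cum[t, qs[p]] += 1.0
    h_q = 0.0
    for r in range(ny):
        pr = cum[k, r] / n
        if pr > 0:
            h_q -= pr * np.log(pr)
    neg_inf = -1e308
    f_prev = np.full(k + 1, neg_inf)
    f_prev[0] = 0.0
    best = np.full(max_nx + 1, neg_inf)
    running = neg_inf
    out = np.full(max_nx + 1, neg_inf)
    for l in range(1, max_nx + 1):
        f_new = np.full(k + 1, neg_inf)
        for j in range(1, k + 1):
            bmax = neg_inf
            for s in range(0, j):
                if f_prev[s] <= neg_inf:
                    continue
                # additive column score f(s, j)
                cnt = (bounds[j] - bounds[s]) / n
                score = -cnt * np.log(cnt)
                for r in range(ny):
                    h = (cum[j, r] - cum[s, r]) / n
                    if h > 0:
                        score += h * np.log(h)
                val = f_prev[s] + score
                if val > bmax:
                    bmax = val
            f_new[j] = bmax
        if f_new[k] > running:
            running = f_new[k]
        out[l] = h_q + running if running > neg_inf else neg_inf
        f_prev = f_new
    return out


@njit(cache=True)
def mic_kernel(x: np.ndarray, y: np.ndarray, b: int, c: float) -> float:
    best = 0.0
    for orientation in range(2):
        if orientation == 0:
            xs, ys = x, y
        else:
            xs, ys = y, x
        for ny in range(2, b // 2 + 1):
            max_nx = b // ny
            if max_nx < 2:
                break
            rows = _equip_nb(ys, ny)
            nrows = int(rows.max()) + 1
            scores = _axis_nb(xs, rows, nrows, max_nx, c)
            for l in range(2, max_nx + 1):
                if scores[l] > -1e307:
                    val = scores[l] / np.log(min(l, ny))
                    if val > best:
                        best = val
    if best > 1.0:
        best = 1.0
    return best
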