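"""Independent oracles used to verify the package implementations.

These deliberately use different machinery from the package: direct adaptive
quadrature for the compound Poisson pmf, exhaustive partition enumeration
for the grid-based association score, and textbook closed forms elsewhere.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate, special


def pln_pmf_oracle(n: int, mu: float, sigma: float) -> float:
    """High-precision adaptive quadrature of
    integral Poisson(n; e^u) Normal(u; mu, sigma) du."""

    def integrand(u):
        return math.exp(n * u - math.exp(u) - special.gammaln(n + 1)
                        - 0.5 * ((u - mu) / sigma) ** 2) / (
                            sigma * math.sqrt(2 * math.pi))

    centre = math.log(n) if n > 0 else mu
    lo = min(mu, centre) - 15 * sigma - 10
    hi = max(mu, centre) + 15 * sigma + 10
    val, _ = integrate.quad(integrand, lo, hi, limit=800,
                            points=[mu, centre], epsabs=1e-300, epsrel=1e-12)
    return val


def _normalized_mi(x_bins, y_bins, denom_bins: int, n: int) -> float:
    nx = int(max(x_bins)) + 1
    ny = int(max(y_bins)) + 1
    table = np.zeros((nx, ny))
    for a, b in zip(x_bins, y_bins):
        table[a, b] += 1
    p = table / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for i in range(nx):
        for j in range(ny):
            if p[i, j] > 0:
                mi += p[i, j] * math.log(p[i, j] / (px[i] * py[j]))
    return mi / math.log(denom_bins)


def mic_oracle(x, y, max_bins: int, equipartition) -> float:
    """Exhaustive free-axis partition search for the MIC procedure.

    For every grid shape (nx, ny) within the budget and both orientations,
    the fixed axis is binned by the supplied equipartition function (the same
    rule the implementation uses) and ALL partitions of the other axis into
    nx intervals (cuts only between distinct values) are enumerated.  This is
    the brute-force equivalent of the dynamic program.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    best = 0.0
    for xs, ys in ((x, y), (y, x)):
        order = np.argsort(xs, kind="stable")
        x_sorted = xs[order]
        valid_cuts = [i for i in range(1, n) if x_sorted[i] != x_sorted[i - 1]]
        for ny in range(2, max_bins // 2 + 1):
            max_nx = max_bins // ny
            if max_nx < 2:
                break
            rows = equipartition(ys, ny)[order]
            for nx in range(2, max_nx + 1):
                for cuts in itertools.combinations(valid_cuts, nx - 1):
                    x_bins = np.searchsorted(cuts, np.arange(n), side="right")
                    val = _normalized_mi(x_bins, rows, min(nx, ny), n)
                    best = max(best, val)
    return min(best, 1.0)


def pearson_oracle(x, y) -> tuple[float, float]:
    """Textbook Pearson R and two-sided t-test p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    r = float(np.sum(xm * ym) / math.sqrt(np.sum(xm ** 2) * np.sum(ym ** 2)))
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r ** 2)
    p = float(2 * special.stdtr(n - 2, -abs(t)))
    return r, p


def bh_oracle(p):
    """Hand step-up Benjamini-Hochberg on a small vector."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
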