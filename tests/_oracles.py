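"""Independent reference implementations used as test oracles.

Everything here is deliberately written independently of the vectorized
code paths under test: plain Python loops with ``statistics.median`` for
the median regressions, and *exact rational arithmetic* for the
least-squares normal equations (so the oracle value carries no rounding
error of its own and 1e-9 comparisons are meaningful even for cubic
designs).
"""

from __future__ import annotations

import statistics
from fractions import Fraction

import numpy as np


def brute_theil(x, y):
    """Median of all pairwise slopes; median of pointwise residuals."""
    slopes = []
    m = len(x)
    for i in range(m):
        for j in range(i + 1, m):
            if x[j] != x[i]:
                slopes.append((y[j] - y[i]) / (x[j] - x[i]))
    slope = statistics.median(slopes)
    intercept = statistics.median([y[i] - slope * x[i] for i in range(m)])
    return intercept, slope


def brute_siegel(x, y):
    """Repeated medians of pairwise slopes and intercept terms."""
    m = len(x)
    per_slope, per_int = [], []
    for i in range(m):
        s_i, c_i = [], []
        for j in range(m):
            if j == i or x[j] == x[i]:
                continue
            s_i.append((y[j] - y[i]) / (x[j] - x[i]))
            c_i.append((x[j] * y[i] - x[i] * y[j]) / (x[j] - x[i]))
        per_slope.append(statistics.median(s_i))
        per_int.append(statistics.median(c_i))
    return statistics.median(per_int), statistics.median(per_slope)


def _solve_exact(A, b):
    """Gaussian elimination over the rationals (exact)."""
    n = len(b)
    A = [row[:] for row in A]
    b = b[:]
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(A[r][col]))
        A[col], A[piv] = A[piv], A[col]
        b[col], b[piv] = b[piv], b[col]
        for r in range(col + 1, n):
            f = A[r][col] / A[col][col]
            for c in range(col, n):
                A[r][c] -= f * A[col][c]
            b[r] -= f * b[col]
    sol = [Fraction(0)] * n
    for i in reversed(range(n)):
        s = b[i] - sum(A[i][j] * sol[j] for j in range(i + 1, n))
        sol[i] = s / A[i][i]
    return np.array([float(s) for s in sol])


def brute_ols_poly(x, y, degree):
    """Normal equations X'X b = X'y solved exactly in rational arithmetic."""
    return brute_wls(x, y, [1.0] * len(x), degree)


def brute_wls(x, y, w, degree=1):
    """Weighted normal equations X'WX b = X'Wy, exact rational solve."""
    m = len(x)
    n = degree + 1
    X = [[Fraction(float(x[k])) ** p for p in range(n)] for k in range(m)]
    wf = [Fraction(float(v)) for v in w]
    yf = [Fraction(float(v)) for v in y]
    A = [[sum(wf[k] * X[k][i] * X[k][j] for k in range(m)) for j in range(n)]
         for i in range(n)]
    b = [sum(wf[k] * X[k][i] * yf[k] for k in range(m)) for i in range(n)]
    return _solve_exact(A, b)


def brute_nssr(observed, predicted):
    return sum(
        (o - p) ** 2 / p ** 2 for o, p in zip(observed, predicted)
    )
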