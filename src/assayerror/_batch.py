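"""Vectorized coefficient solvers for many SD vectors on one concentration grid.

The combinatorial subset analysis refits the same regression on up to
C(24, 6) = 134596 resampled precision profiles.  All subsets share the
concentration grid, so the design matrix (and, for least squares, its
pseudo-inverse) is computed once and every fit reduces to a matrix product
or an axis-wise median.  Each function takes ``x`` of shape (M,) and ``Y``
of shape (n_fits, M) and returns coefficients of shape (n_fits, 4) in the
order c0..c3 of SD(C) = c0 + c1*C + c2*C^2 + c3*C^3.

These routines assume a validated design (enough points, not all x equal);
the estimator classes in :mod:`assayerror.regression` enforce that.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "batch_ols_poly",
    "batch_wls_inv_x2",
    "batch_theil",
    "batch_siegel",
    "inv_x2_weights",
]


def _pad(coef: np.ndarray) -> np.ndarray:
    """Pad (n_fits, k) coefficient blocks to (n_fits, 4) with zeros."""
    out = np.zeros((coef.shape[0], 4))
    out[:, : coef.shape[1]] = coef
    return out


def batch_ols_poly(x: np.ndarray, Y: np.ndarray, degree: int) -> np.ndarray:
    """Unweighted least-squares polynomial of the given degree (1-3)."""
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.vander(x, degree + 1, increasing=True)
    P = np.linalg.pinv(X)                 # (degree+1, M)
    return _pad(Y @ P.T)


def inv_x2_weights(x: np.ndarray, blank_policy: str = "cap") -> np.ndarray:
    """1/x^2 weights; the blank's undefined 1/0^2 is handled by policy.

    ``cap``: the blank gets the weight of the lowest nonzero level, so it
    constrains the fit as strongly as the most influential level.
    ``drop``: the blank gets weight 0 (excluded).
    """
    x = np.asarray(x, dtype=float)
    w = np.zeros_like(x)
    nz = x > 0
    w[nz] = 1.0 / x[nz] ** 2
    if (~nz).any():
        if blank_policy == "cap":
            w[~nz] = 1.0 / np.min(x[nz]) ** 2
        elif blank_policy == "drop":
            w[~nz] = 0.0
        else:
            raise ValueError(f"unknown blank_policy {blank_policy!r}")
    return w


def batch_wls_inv_x2(
    x: np.ndarray, Y: np.ndarray, blank_policy: str = "cap"
) -> np.ndarray:
    """1/x^2-weighted linear least squares."""
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    w = inv_x2_weights(x, blank_policy)
    X = np.vander(x, 2, increasing=True)
    XtW = X.T * w                          # (2, M)
    # beta = (X'WX)^-1 X'W y, with the projector computed once.
    proj = np.linalg.solve(XtW @ X, XtW)   # (2, M)
    return _pad(Y @ proj.T)


def _pair_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j), j > i, with distinct concentrations."""
    m = len(x)
    ii, jj = np.triu_indices(m, k=1)
    keep = x[jj] != x[ii]
    return ii[keep], jj[keep]


def batch_theil(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Theil's original median regression.

    slope  = median over all pairs j > i of (sd_j - sd_i)/(x_j - x_i)
    intercept = median over i of sd_i - slope * x_i
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    ii, jj = _pair_indices(x)
    slopes = (Y[:, jj] - Y[:, ii]) / (x[jj] - x[ii])
    slope = np.median(slopes, axis=1)
    intercept = np.median(Y - slope[:, None] * x[None, :], axis=1)
    return _pad(np.column_stack([intercept, slope]))


def batch_siegel(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Siegel's repeated-median regression.

    For each point i the median over j != i of the pairwise slope
    (sd_j - sd_i)/(x_j - x_i) and of the pairwise intercept term
    (x_j*sd_i - x_i*sd_j)/(x_j - x_i) is taken; the estimates are the
    medians over i of those per-point medians.  Breakdown point ~50%.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    dx = x[None, :] - x[:, None]           # (M, M): x_j - x_i at [i, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        S = (Y[:, None, :] - Y[:, :, None]) / dx[None, :, :]
        T = (x[None, None, :] * Y[:, :, None]
             - x[None, :, None] * Y[:, None, :]) / dx[None, :, :]
    mask = dx == 0                          # diagonal and duplicate-x pairs
    S[:, mask] = np.nan
    T[:, mask] = np.nan
    slope = np.median(np.nanmedian(S, axis=2), axis=1)
    intercept = np.median(np.nanmedian(T, axis=2), axis=1)
    return _pad(np.column_stack([intercept, slope]))
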