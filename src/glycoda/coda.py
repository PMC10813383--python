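"""Simplex algebra for glycan-peak compositions.

A chromatographic N-glycome profile is a 46-part composition: the peak
areas carry only relative information and are closed to 100%.  All
statistics in this package therefore operate on log-ratio coordinates.
The isometric log-ratio (ilr) transform used throughout is the *pivot*
coordinate system induced by the fixed chromatographic peak order
GP1..GP46:

    z_i = sqrt((D-i)/(D-i+1)) * ln( x_i / g(x_{i+1}, ..., x_D) ),

for i = 1..D-1, where g is the geometric mean.  The first coordinate
thus contrasts the earliest-eluting (simplest) glycan against everything
after it, which matches the biological reading of the first peaks as
simple, agalactosylated structures.  Pivot coordinates depend on the
part order; the GP1..GP46 order is part of the contract.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "N_PEAKS",
    "GP_COLUMNS",
    "close",
    "replace_zeros",
    "clr",
    "ilr",
    "ilr_inverse",
    "pivot_basis",
    "aitchison_distance",
    "spearman_ilr",
]

N_PEAKS = 46
GP_COLUMNS = [f"GP{i}" for i in range(1, N_PEAKS + 1)]


def close(raw, total: float = 100.0):
    """Close a non-negative vector (or rows of a matrix) to a constant sum.

    Parameters
    ----------
    raw : array-like
        Non-negative parts; 1-D vector or 2-D (rows = observations).
    total : float
        Target row sum, default 100 (percent units).

    Returns
    -------
    ndarray with the same shape, each row summing to ``total``.
    """
    x = np.asarray(raw, dtype=float)
    if total <= 0 or not np.isfinite(total):
        raise ValueError("total must be a positive finite number")
    if np.any(x < 0):
        raise ValueError("composition parts must be non-negative")
    s = x.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("degenerate composition: all parts zero")
    return x * (total / s)


def replace_zeros(matrix, total: float = 100.0):
    """Multiplicative zero replacement on a matrix of closed rows.

    Each zero in column j is imputed as half the smallest positive value
    observed in that column; the non-zero entries of an affected row are
    shrunk by (total - sum of imputed values)/total so ratios among them
    are preserved, then rows are re-closed.

    Raises
    ------
    ValueError if a column contains no positive value (dead peak).
    """
    x = np.array(close(np.atleast_2d(matrix), total), dtype=float)
    if not np.any(x == 0):
        return x
    col_ok = (x > 0).any(axis=0)
    if not col_ok.all():
        bad = [GP_COLUMNS[j] if j < N_PEAKS else f"col{j}"
               for j in np.nonzero(~col_ok)[0]]
        raise ValueError(f"column(s) entirely zero: {', '.join(bad)}")
    delta = np.array([x[x[:, j] > 0, j].min() / 2.0 for j in range(x.shape[1])])
    zero = x == 0
    imputed_total = (zero * delta).sum(axis=1, keepdims=True)
    out = x * (total - imputed_total) / total
    out[zero] = (zero * delta)[zero]
    return close(out, total)


def pivot_basis(d: int = N_PEAKS) -> np.ndarray:
    """Contrast matrix Psi ((d-1) x d) of the pivot ilr basis.

    Rows are orthonormal, each sums to zero; ilr(x) = Psi @ clr(x) and
    clr(x) = Psi.T @ ilr(x).
    """
    psi = np.zeros((d - 1, d))
    for i in range(1, d):
        a = np.sqrt((d - i) / (d - i + 1.0))
        psi[i - 1, i - 1] = a
        psi[i - 1, i:] = -a / (d - i)
    return psi


def clr(c):
    """Centred log-ratio: ln(x_i / g(x)); rows sum to 0."""
    x = np.asarray(c, dtype=float)
    if np.any(x <= 0):
        raise ValueError("clr requires strictly positive parts")
    lx = np.log(x)
    return lx - lx.mean(axis=-1, keepdims=True)


def ilr(c):
    """Pivot ilr coordinates of a composition (vector or rows of a matrix).

    Returns an array with trailing dimension D-1.
    """
    x = np.asarray(c, dtype=float)
    if np.any(x <= 0):
        raise ValueError("ilr requires strictly positive parts")
    d = x.shape[-1]
    return clr(x) @ pivot_basis(d).T


def ilr_inverse(z, total: float = 100.0):
    """Map ilr coordinates back to the simplex, closed to ``total``."""
    zz = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(zz)):
        raise ValueError("ilr coordinates must be finite")
    d = zz.shape[-1] + 1
    y = zz @ pivot_basis(d)
    # subtract rowwise max before exponentiating for numerical safety
    y = y - y.max(axis=-1, keepdims=True)
    return close(np.exp(y), total)


def aitchison_distance(a, b) -> float:
    """Aitchison distance: Euclidean distance between clr (= ilr) images."""
    return float(np.linalg.norm(clr(a) - clr(b)))


def spearman_ilr(ilr_matrix):
    """Spearman correlation matrix of ilr coordinates across subjects.

    Parameters
    ----------
    ilr_matrix : (n, p) array, n >= 3 subjects.

    Returns
    -------
    (p, p) symmetric matrix with unit diagonal; columns with zero
    variance yield NaN entries and a warning.
    """
    x = np.asarray(ilr_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 subjects")
    const = np.nonzero(x.std(axis=0) == 0)[0]
    if const.size:
        warnings.warn(
            f"constant ilr column(s) {const.tolist()}: correlations undefined (NaN)",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x).statistic
    rho = np.asarray(rho, dtype=float)
    if rho.ndim == 0:  # scipy collapses the two-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    return rho
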