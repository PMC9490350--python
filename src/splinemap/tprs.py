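"""Thin-plate regression spline (TPRS) bases over 2-D coordinates.

A smooth surface f(x, z) = sum_j beta_j b_j(x, z) is represented by a
low-rank eigen-approximation of the full thin-plate spline: the radial
basis eta(r) = r^2 log r is evaluated between all coordinate pairs, the
resulting matrix is eigen-truncated, and the polynomial null space (1, x, z)
is appended.  The wiggliness penalty P1 penalizes curvature and has the
linear functions as its null space; a separate null-space penalty P0 makes
the implied Gaussian prior on the coefficients proper.  A sum-to-zero
identifiability constraint is absorbed into the basis (the intercept column
is dropped and the remaining columns are centred), so each surface is
identifiable alongside a separate model intercept and other surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space
from scipy.spatial.distance import pdist, squareform

from .connectivity import ConnectivityCoordinates

__all__ = ["SplineBasis", "SmoothCoefficients", "build_tprs_basis", "prior_precision", "evaluate_smooth", "tps_eta"]


def tps_eta(r: np.ndarray) -> np.ndarray:
    """Thin-plate radial basis eta(r) = r^2 log r (order 2, dimension 2), eta(0) = 0."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


@dataclass(frozen=True)
class SplineBasis:
    """Design matrix and penalty matrices of one smooth surface.

    Attributes
    ----------
    X : (n, K-1) ndarray
        Basis evaluations after constraint absorption: K-3 wiggly columns
        followed by the centred x and z columns (the intercept is dropped).
    P1 : (K-1, K-1) ndarray
        Wiggliness penalty; symmetric PSD with rank K-3 and zero block on the
        polynomial columns.
    P0 : (K-1, K-1) ndarray
        Null-space penalty: identity on the polynomial columns, zero elsewhere.
    K : int
        Requested basis dimension (including the 3-dim polynomial null space
        before constraint absorption).
    coords_ref : ConnectivityCoordinates
        The coordinates the basis was built on.
    constraint : (K-1,) ndarray
        Column means subtracted from the unconstrained design (the absorbed
        sum-to-zero constraint).
    """

    X: np.ndarray
    P1: np.ndarray
    P0: np.ndarray
    K: int
    coords_ref: ConnectivityCoordinates
    constraint: np.ndarray

    @property
    def ncol(self) -> int:
        """Number of free coefficients (= K - 1)."""
        return self.X.shape[1]


@dataclass(frozen=True)
class SmoothCoefficients:
    beta: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float).ravel())


def _fix_signs(M: np.ndarray) -> np.ndarray:
    """Flip column signs so each column's largest-magnitude entry is positive."""
    M = M.copy()
    for j in range(M.shape[1]):
        i = np.argmax(np.abs(M[:, j]))
        if M[i, j] < 0:
            M[:, j] = -M[:, j]
    return M


def build_tprs_basis(coords: ConnectivityCoordinates, K: int = 30) -> SplineBasis:
    """Construct a rank-K thin-plate regression spline basis.

    The n x n radial matrix E (eta of pairwise distances) is eigendecomposed
    and the K leading eigenpairs (by absolute eigenvalue) retained.  The
    orthogonality constraint of the wiggly part to the polynomial space is
    absorbed, leaving K-3 wiggly columns with a PSD penalty; the polynomial
    columns (1, x, z) are appended and the sum-to-zero constraint is absorbed
    by dropping the intercept and centring the remaining columns.  With K = n
    the construction reproduces the full thin-plate spline exactly.
    """
    pts = coords.coords
    n = pts.shape[0]
    if K <= 3:
        raise ValueError("K must be at least 4 (3 dims are taken by the polynomial null space)")
    if K > n:
        raise ValueError(f"K = {K} exceeds the number of distinct coordinate rows n = {n}")
    if np.unique(pts, axis=0).shape[0] != n:
        raise ValueError("duplicate coordinate rows; the radial basis would be singular")

    E = tps_eta(squareform(pdist(pts)))
    evals, evecs = np.linalg.eigh(E)
    order = np.argsort(np.abs(evals))[::-1]
    lam = evals[order[:K]]
    U = _fix_signs(evecs[:, order[:K]])

    T = np.column_stack([np.ones(n), pts])  # (n, 3) polynomial null space
    # absorb T' U delta = 0: delta = Z @ delta_tilde
    Z = null_space(T.T @ U)  # (K, K-3)
    if Z.shape[1] != K - 3:
        raise ValueError("degenerate configuration: polynomial constraint rank-deficient")
    Z = _fix_signs(Z)

    Xw = U @ (lam[:, None] * Z)  # wiggly design block, n x (K-3)
    Pw = Z.T @ (lam[:, None] * Z)  # wiggliness penalty on delta_tilde
    Pw = 0.5 * (Pw + Pw.T)
    # numerical PSD projection (Pw is PSD in exact arithmetic)
    w, V = np.linalg.eigh(Pw)
    Pw = (V * np.clip(w, 0.0, None)) @ V.T
    Pw = 0.5 * (Pw + Pw.T)

    # full design [wiggly | 1 | x | z] -> drop intercept, centre columns
    X_un = np.column_stack([Xw, pts])
    col_means = X_un.mean(axis=0)
    X = X_un - col_means

    p = K - 1
    P1 = np.zeros((p, p))
    P1[: K - 3, : K - 3] = Pw
    P0 = np.zeros((p, p))
    P0[K - 3 :, K - 3 :] = np.eye(2)
    return SplineBasis(X=X, P1=P1, P0=P0, K=K, coords_ref=coords, constraint=col_means)


def prior_precision(basis: SplineBasis, lambda0: float, lambda1: float) -> np.ndarray:
    """Proper Gaussian prior precision for the coefficients: P0*lambda0 + P1*lambda1."""
    if lambda0 <= 0 or lambda1 <= 0:
        raise ValueError("lambda0 and lambda1 must be positive")
    return basis.P0 * lambda0 + basis.P1 * lambda1


def evaluate_smooth(basis: SplineBasis, beta) -> np.ndarray:
    """Evaluate the smooth surface X @ beta at the basis coordinates."""
    b = beta.beta if isinstance(beta, SmoothCoefficients) else np.asarray(beta, dtype=float).ravel()
    if b.shape[0] != basis.ncol:
        raise ValueError(f"beta has length {b.shape[0]}, basis expects {basis.ncol}")
    return basis.X @ b
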