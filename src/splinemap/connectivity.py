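"""Connectivity coordinate systems.

Spatially structured smooth surfaces are built over 2-D coordinates that
encode "closeness" between areas.  For geographic proximity these are the
(scaled) area centroids; for any other symmetric connectivity measure
(e.g. modelled human movement) coordinates are obtained by converting flows
to dissimilarities and embedding them with classical multidimensional
scaling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Geography",
    "ConnectivityCoordinates",
    "FlowMatrix",
    "scale_coordinates",
    "gravity_flows",
    "flows_to_dissimilarity",
    "classical_mds",
]


@dataclass(frozen=True)
class Geography:
    """Areal study region: ids, planar centroids, populations, contiguity.

    Parameters
    ----------
    area_ids : sequence of hashable
        Ordered area identifiers; all matrices/vectors follow this order.
    centroids : (n, 2) ndarray
        Planar centroid coordinates (projected units).
    populations : (n,) ndarray
        Strictly positive population counts.
    adjacency : (n, n) ndarray
        Binary symmetric contiguity matrix with zero diagonal.
    """

    area_ids: tuple
    centroids: np.ndarray
    populations: np.ndarray
    adjacency: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "area_ids", tuple(self.area_ids))
        object.__setattr__(self, "centroids", np.asarray(self.centroids, dtype=float))
        object.__setattr__(self, "populations", np.asarray(self.populations, dtype=float))
        object.__setattr__(self, "adjacency", np.asarray(self.adjacency))
        n = len(self.area_ids)
        if self.centroids.shape != (n, 2):
            raise ValueError(f"centroids must be ({n}, 2), got {self.centroids.shape}")
        if self.populations.shape != (n,):
            raise ValueError("populations length must match area_ids")
        if np.any(self.populations <= 0):
            raise ValueError("populations must be strictly positive")
        W = self.adjacency
        if W.shape != (n, n):
            raise ValueError("adjacency must be square and match area_ids")
        if not np.array_equal(W, W.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(W, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        # duplicate centroids break the radial spline basis
        uniq = np.unique(self.centroids, axis=0)
        if uniq.shape[0] != n:
            raise ValueError("duplicate centroid rows are not allowed")

    @property
    def n(self) -> int:
        return len(self.area_ids)


@dataclass(frozen=True)
class ConnectivityCoordinates:
    """n x 2 coordinates, each non-constant axis scaled to [0, 1]."""

    coords: np.ndarray
    source_label: str = "distance"

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D")

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class FlowMatrix:
    """Symmetric non-negative flow matrix with zero diagonal."""

    flows: np.ndarray

    def __post_init__(self):
        F = np.asarray(self.flows, dtype=float)
        if F.ndim != 2 or F.shape[0] != F.shape[1]:
            raise ValueError("flows must be square")
        if not np.allclose(F, F.T):
            logger.warning("asymmetric flow matrix supplied; symmetrizing as (M + M.T)/2")
            F = 0.5 * (F + F.T)
        if np.any(F < 0):
            raise ValueError("flows must be non-negative")
        F = F.copy()
        np.fill_diagonal(F, 0.0)
        object.__setattr__(self, "flows", F)

    @property
    def n(self) -> int:
        return self.flows.shape[0]


def _scale_unit(raw: np.ndarray, strict: bool) -> np.ndarray:
    raw = np.asarray(raw, dtype=float)
    out = np.empty_like(raw)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        rng = col.max() - col.min()
        if rng <= 0:
            if strict:
                raise ValueError(f"axis {j} is constant and cannot be scaled to [0, 1]")
            out[:, j] = col
        else:
            out[:, j] = (col - col.min()) / rng
    return out


def scale_coordinates(raw: np.ndarray, source_label: str = "distance") -> ConnectivityCoordinates:
    """Affinely map each coordinate axis onto [0, 1].

    Each axis is transformed as ``x -> (x - min) / (max - min)``; the ordering
    of areas is preserved.  Raises ``ValueError`` naming the degenerate axis if
    an axis is constant.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 2:
        raise ValueError("raw coordinates must have shape (n, 2)")
    if raw.shape[0] < 2:
        raise ValueError("need at least 2 areas to scale coordinates")
    return ConnectivityCoordinates(_scale_unit(raw, strict=True), source_label)


def gravity_flows(
    populations: np.ndarray,
    centroids: np.ndarray,
    gamma: float = 2.0,
    kappa: float = 1.0,
) -> FlowMatrix:
    """Gravity-model flows ``kappa * N_i * N_j / d_ij**gamma``.

    ``d_ij`` is the Euclidean centroid distance; the diagonal is zero and the
    matrix is symmetric by construction.
    """
    if gamma <= 0 or kappa <= 0:
        raise ValueError("gamma and kappa must be positive")
    N = np.asarray(populations, dtype=float)
    pts = np.asarray(centroids, dtype=float)
    if np.any(N <= 0):
        raise ValueError("populations must be positive")
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(pts))
    off = ~np.eye(len(N), dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("coincident centroids give zero distance; gravity flow undefined")
    F = np.zeros_like(d)
    F[off] = kappa * np.outer(N, N)[off] / d[off] ** gamma
    return FlowMatrix(F)


_TRANSFORMS = ("reciprocal", "max_minus", "neg_log")


def flows_to_dissimilarity(
    flows: FlowMatrix, transform: str = "reciprocal", normalize: str | None = None
) -> np.ndarray:
    """Monotone-decreasing map from flows to a dissimilarity matrix.

    ``reciprocal``: 1/(1+f); ``max_minus``: max(f) - f off-diagonal;
    ``neg_log``: -log(f / max(f)), requiring all off-diagonal flows > 0.
    The diagonal is zero and symmetry is preserved.

    ``normalize="median"`` divides off-diagonal flows by their median first.
    Flow magnitudes depend on arbitrary units (e.g. gravity-model kappa); the
    bounded transforms saturate when flows are very large or very small, so
    bringing the typical flow to order one keeps the embedding informative.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"transform must be one of {_TRANSFORMS}")
    if normalize not in (None, "median"):
        raise ValueError("normalize must be None or 'median'")
    F = flows.flows
    n = F.shape[0]
    off = ~np.eye(n, dtype=bool)
    if normalize == "median":
        med = np.median(F[off][F[off] > 0])
        F = F / med
    D = np.zeros_like(F)
    if transform == "reciprocal":
        D[off] = 1.0 / (1.0 + F[off])
    elif transform == "max_minus":
        D[off] = F[off].max() - F[off]
    else:
        if np.any(F[off] <= 0):
            raise ValueError("neg_log transform requires strictly positive off-diagonal flows")
        D[off] = -np.log(F[off] / F[off].max())
    return D


def classical_mds(
    dissimilarity: np.ndarray,
    dim: int = 2,
    source_label: str = "movement",
    rescale: bool = True,
) -> ConnectivityCoordinates:
    """Classical (Torgerson) MDS embedding of a dissimilarity matrix.

    Double-centres ``-0.5 * D**2``, takes the top ``dim`` eigenpairs with
    positive eigenvalues and returns ``eigenvectors * sqrt(eigenvalues)``.
    Dimensions corresponding to non-positive eigenvalues are clamped to zero
    columns (with a warning).  Eigenvector signs are fixed so the
    largest-magnitude entry of each retained axis is positive, making the
    embedding reproducible across linear-algebra backends.  When ``rescale``
    is true, non-constant axes are mapped onto [0, 1].
    """
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("dissimilarity diagonal must be zero")
    if np.any(D < 0):
        raise ValueError("dissimilarities must be non-negative")
    if not 0 < dim < n:
        raise ValueError("require 0 < dim < n")

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = 0.5 * (B + B.T)
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    coords = np.zeros((n, dim))
    tol = 1e-9 * max(evals.max(), 0.0)
    n_pos = 0
    for k in range(dim):
        if evals[k] > tol and evals[k] > 0:
            vec = evecs[:, k]
            # deterministic sign: largest-magnitude entry positive
            if vec[np.argmax(np.abs(vec))] < 0:
                vec = -vec
            coords[:, k] = vec * np.sqrt(evals[k])
            n_pos += 1
    if n_pos < dim:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding {dim - n_pos} zero column(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    if rescale:
        coords = _scale_unit(coords, strict=False)
    return ConnectivityCoordinates(coords, source_label)
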