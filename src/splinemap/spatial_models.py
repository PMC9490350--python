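"""Hierarchical model specification and CAR/BYM2 building blocks.

The spline model places one or more penalized smooth surfaces plus an iid
heterogeneity term in the linear predictor of a count (or binomial) model
with a log-population offset.  The comparator is the BYM2 reparametrization
of the Besag-York-Mollie model: a scaled intrinsic CAR field and an iid
field combined through a mixing parameter phi and precision-scale tau.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .tprs import SplineBasis

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "CARStructure",
    "BYM2Params",
    "DEFAULT_PRIORS",
    "build_adjacency",
    "icar_precision",
    "bym2_scaling_factor",
    "scaling_factor_from_precision",
    "bym2_combine",
    "linear_predictor",
    "morans_i",
]

FAMILIES = ("poisson", "negbin", "binomial")

#: default hyperprior settings; all overridable via ModelSpec.priors
DEFAULT_PRIORS = {
    "alpha_sd": 10.0,  # N(0, alpha_sd^2) on the intercept
    "lambda_shape": 0.05,  # Gamma(shape, rate) on each smoothing precision
    "lambda_rate": 0.005,
    "sigma_v_prec_shape": 1.0,  # Gamma on the iid-term precision 1/sigma_v^2
    "sigma_v_prec_rate": 0.01,
    "tau_shape": 1.0,  # Gamma on the BYM2 precision tau
    "tau_rate": 0.01,
    "psi_shape": 0.01,  # Gamma on the negative-binomial dispersion psi
    "psi_rate": 0.01,
    # set to a number to fix the corresponding hyperparameter instead of sampling it
    "psi_fixed": None,
    "sigma_v_fixed": None,
}


@dataclass
class ModelSpec:
    """Specification of one hierarchical disease-mapping model.

    ``smooth_terms`` is a list of (label, SplineBasis) pairs sharing the data
    dimension n.  For the Poisson / negative-binomial families ``offset`` is
    the n-vector log(xi_i); the binomial family instead requires a ``trials``
    vector (logit link, no offset).
    """

    family: str
    offset: np.ndarray | None = None
    smooth_terms: list = field(default_factory=list)
    include_iid: bool = True
    comparator: str = "none"
    priors: dict = field(default_factory=dict)
    trials: np.ndarray | None = None
    adjacency: np.ndarray | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.comparator not in ("none", "bym2"):
            raise ValueError("comparator must be 'none' or 'bym2'")
        if self.family == "binomial":
            if self.trials is None:
                raise ValueError("binomial family requires a trials vector")
            self.trials = np.asarray(self.trials, dtype=float)
        else:
            if self.offset is None:
                raise ValueError("count families require an offset vector")
            self.offset = np.asarray(self.offset, dtype=float)
        ns = {basis.X.shape[0] for _, basis in self.smooth_terms}
        if len(ns) > 1:
            raise ValueError("all smooth terms must share the same number of areas")
        if self.comparator == "bym2" and self.adjacency is None:
            raise ValueError("bym2 comparator requires an adjacency matrix")
        merged = dict(DEFAULT_PRIORS)
        merged.update(self.priors)
        self.priors = merged

    @property
    def n(self) -> int:
        base = self.offset if self.family != "binomial" else self.trials
        return int(base.shape[0])


@dataclass(frozen=True)
class CARStructure:
    W: np.ndarray
    scaling_factor: float
    num_components: int

    def __post_init__(self):
        if self.scaling_factor <= 0:
            raise ValueError("scaling_factor must be positive")


@dataclass(frozen=True)
class BYM2Params:
    phi: float
    tau: float
    u_star: np.ndarray
    v_star: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def build_adjacency(features) -> tuple[list, np.ndarray]:
    """Queen-contiguity adjacency from GeoJSON features.

    ``features`` is a GeoJSON FeatureCollection mapping (or its feature list);
    each feature needs an ``area_id`` property.  W_ij = 1 iff the two polygons
    share at least one boundary point.  Returns (area_ids, W) in feature order.
    """
    from shapely.geometry import shape

    if isinstance(features, dict):
        features = features.get("features", [])
    ids, geoms = [], []
    for feat in features:
        props = feat.get("properties") or {}
        if "area_id" not in props:
            raise ValueError("each feature needs an 'area_id' property")
        ids.append(props["area_id"])
        geoms.append(shape(feat["geometry"]))
    n = len(geoms)
    W = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if geoms[i].intersects(geoms[j]):
                W[i, j] = W[j, i] = 1
    isolated = np.flatnonzero(W.sum(axis=1) == 0)
    for i in isolated:
        warnings.warn(f"area {ids[i]!r} has no neighbours (island)", RuntimeWarning, stacklevel=2)
    return ids, W


def _check_w(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.array_equal(W, W.T):
        raise ValueError("W must be symmetric")
    if np.any(np.diag(W) != 0):
        raise ValueError("W must have a zero diagonal")
    if not np.isin(W, (0, 1)).all():
        raise ValueError("W must be binary")
    return W.astype(float)


def icar_precision(W: np.ndarray) -> np.ndarray:
    """Intrinsic CAR precision Q = D - W (up to the scale 1/sigma_s^2).

    Row sums of Q are zero; rank is n minus the number of connected
    components.  The implied conditionals have mean equal to the neighbour
    average and variance sigma_s^2 / (number of neighbours).
    """
    W = _check_w(W)
    return np.diag(W.sum(axis=1)) - W


def graph_components(W: np.ndarray) -> np.ndarray:
    """Connected-component labels of the adjacency graph."""
    _, labels = connected_components(csr_matrix(np.asarray(W)), directed=False)
    return labels


def scaling_factor_from_precision(Q: np.ndarray, labels: np.ndarray | None = None) -> float:
    """Geometric mean of the marginal variances implied by an ICAR precision.

    Marginal variances are the diagonal of the generalized inverse of Q,
    computed per connected component (islands are excluded).  Dividing the
    field by the square root of this factor - equivalently multiplying Q by
    it - gives unit generalized variance.
    """
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    if labels is None:
        W_impl = -(Q - np.diag(np.diag(Q)))
        labels = graph_components(W_impl != 0)
    diags = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            continue
        Qc = Q[np.ix_(idx, idx)]
        diags.append(np.diag(np.linalg.pinv(Qc)))
    if not diags:
        raise ValueError("graph has no connected component of size > 1")
    d = np.concatenate(diags)
    return float(np.exp(np.mean(np.log(d))))


def bym2_scaling_factor(W: np.ndarray) -> float:
    """Scaling factor making the ICAR field on W have unit generalized variance.

    Returns the geometric mean of diag(pinv(D - W)) over non-singleton
    connected components; the scaled structured field uses precision
    factor * (D - W).  Islands receive independent N(0, 1) effects instead.
    """
    W = _check_w(W)
    return scaling_factor_from_precision(icar_precision(W), graph_components(W))


def car_structure(W: np.ndarray) -> CARStructure:
    W = _check_w(W)
    labels = graph_components(W)
    return CARStructure(W=W, scaling_factor=bym2_scaling_factor(W), num_components=int(labels.max() + 1))


def bym2_combine(params: BYM2Params) -> np.ndarray:
    """Combined BYM2 field S = (1/sqrt(tau)) * (sqrt(phi) u* + sqrt(1-phi) v*).

    With u* a unit-generalized-variance ICAR field and v* standard normal,
    the marginal variance of S is 1/tau and phi is the share carried by the
    structured component.
    """
    u = np.asarray(params.u_star, dtype=float)
    v = np.asarray(params.v_star, dtype=float)
    if u.shape != v.shape:
        raise ValueError("u_star and v_star must have the same length")
    return (np.sqrt(params.phi) * u + np.sqrt(1.0 - params.phi) * v) / np.sqrt(params.tau)


def linear_predictor(spec: ModelSpec, alpha: float, term_values) -> np.ndarray:
    """Linear predictor: offset + alpha + sum of random-term vectors.

    For the binomial family the predictor is on the logit scale and carries
    no offset.
    """
    n = spec.n
    eta = np.full(n, float(alpha))
    if spec.family != "binomial":
        eta = eta + spec.offset
    for t in term_values:
        t = np.asarray(t, dtype=float)
        if t.shape != (n,):
            raise ValueError(f"term has shape {t.shape}, expected ({n},)")
        eta = eta + t
    return eta


def morans_i(x: np.ndarray, W: np.ndarray) -> float:
    """Moran's I spatial autocorrelation of x under binary weights W."""
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    z = x - x.mean()
    s0 = W.sum()
    denom = (z**2).sum()
    if s0 == 0 or denom == 0:
        return float("nan")
    return float(len(x) / s0 * (z @ W @ z) / denom)
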