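"""Data-generating processes for the simulation scenarios.

Counts are generated from a Poisson (or Bernoulli) model whose log-rate is an
intercept plus a latent spatial field S.  S mixes one or two smooth surfaces
evaluated on connectivity coordinates with iid standard-normal noise, using
linear mixing weights.  A synthetic geography generator (irregular centroid
cloud, Delaunay contiguity, log-spread populations, gravity flows) stands in
for real municipality data so every scenario runs without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay
from scipy.special import expit

from .connectivity import ConnectivityCoordinates, FlowMatrix, Geography, gravity_flows

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "sm_surface",
    "centre_field",
    "standardize_field",
    "single_source",
    "two_source",
    "binary_outcome",
    "synthetic_geography",
    "abstract_coordinates",
    "single_source_grid",
    "two_source_grid",
    "OFFSET_SCALE",
]

#: populations are divided by this to form the rate offset (incidence per 100k)
OFFSET_SCALE = 1e5

SM_SIGMA_X = 0.3
SM_SIGMA_Z = 0.4


@dataclass(frozen=True)
class SimulationConfig:
    phi: tuple
    sigma_x: float = SM_SIGMA_X
    sigma_z: float = SM_SIGMA_Z
    alpha: float = 0.0
    seed: int = 0
    family: str = "poisson"


@dataclass(frozen=True)
class SimulatedDataset:
    """Simulated counts plus the latent truth that generated them."""

    counts: np.ndarray
    offsets: np.ndarray
    true_field: np.ndarray
    true_smooths: dict
    config: SimulationConfig

    def __post_init__(self):
        c = np.asarray(self.counts)
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")


def sm_surface(x, z, sigma_x: float = SM_SIGMA_X, sigma_z: float = SM_SIGMA_Z):
    """Two-bump smooth test surface on the unit square.

    pi*sx*sz * (1.2*exp(-(x-0.2)^2/sx^2 - (z-0.3)^2/sz^2)
                + 0.8*exp(-(x-0.7)^2/sx^2 - (z-0.8)^2/sz^2))
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    pref = np.pi * sigma_x * sigma_z
    b1 = 1.2 * np.exp(-((x - 0.2) ** 2) / sigma_x**2 - (z - 0.3) ** 2 / sigma_z**2)
    b2 = 0.8 * np.exp(-((x - 0.7) ** 2) / sigma_x**2 - (z - 0.8) ** 2 / sigma_z**2)
    return pref * (b1 + b2)


def centre_field(values: np.ndarray) -> np.ndarray:
    """Subtract the overall mean so the field averages exactly zero."""
    v = np.asarray(values, dtype=float)
    return v - v.mean()


def standardize_field(values: np.ndarray) -> np.ndarray:
    """Centre a field and scale it to unit population variance.

    The mixing weight of a simulation scenario measures the share of the
    latent-field variance contributed by each component, which requires the
    smooth component to be on the same (unit) variance scale as the iid
    noise it is mixed with.
    """
    v = centre_field(values)
    sd = v.std()
    if sd == 0:
        raise ValueError("field is constant; cannot standardize")
    return v / sd


def _offsets(geog: Geography) -> np.ndarray:
    return geog.populations / OFFSET_SCALE


def _poisson_counts(rng: np.random.Generator, xi: np.ndarray, log_rate: np.ndarray) -> np.ndarray:
    return rng.poisson(xi * np.exp(log_rate))


def _check_coords(geog: Geography, coords: ConnectivityCoordinates):
    if coords.n != geog.n:
        raise ValueError("coordinates and geography differ in number of areas")


def single_source(
    geog: Geography,
    coords: ConnectivityCoordinates,
    phi: float,
    seed: int,
    alpha: float = 0.0,
) -> SimulatedDataset:
    """Counts with one spatially structured source.

    S_i = phi * centred sm(x_i, z_i) + (1 - phi) * eps_i with eps ~ N(0, 1);
    y_i ~ Poisson(xi_i * exp(alpha + S_i)), xi_i = population / 100000.
    The weights enter linearly (not as square roots).
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    _check_coords(geog, coords)
    rng = np.random.default_rng(seed)
    smooth = standardize_field(sm_surface(coords.coords[:, 0], coords.coords[:, 1]))
    eps = rng.normal(size=geog.n)
    S = phi * smooth + (1.0 - phi) * eps
    xi = _offsets(geog)
    y = _poisson_counts(rng, xi, alpha + S)
    cfg = SimulationConfig(phi=(phi,), alpha=alpha, seed=seed, family="poisson")
    return SimulatedDataset(y, xi, S, {coords.source_label: smooth}, cfg)


def two_source(
    geog: Geography,
    coords_distance: ConnectivityCoordinates,
    coords_movement: ConnectivityCoordinates,
    phi1: float,
    phi2: float,
    phi3: float,
    seed: int,
    alpha: float = 0.0,
) -> SimulatedDataset:
    """Counts with two structured sources and iid noise.

    S_i = phi1 * sm(a_i, b_i) + phi2 * sm(c_i, d_i) + phi3 * eps_i, with both
    smooth fields centred and phi1 + phi2 + phi3 = 1.
    """
    if min(phi1, phi2, phi3) < 0:
        raise ValueError("mixing weights must be non-negative")
    if abs(phi1 + phi2 + phi3 - 1.0) > 1e-9:
        raise ValueError("mixing weights must sum to 1")
    _check_coords(geog, coords_distance)
    _check_coords(geog, coords_movement)
    rng = np.random.default_rng(seed)
    sm1 = standardize_field(sm_surface(coords_distance.coords[:, 0], coords_distance.coords[:, 1]))
    sm2 = standardize_field(sm_surface(coords_movement.coords[:, 0], coords_movement.coords[:, 1]))
    eps = rng.normal(size=geog.n)
    S = phi1 * sm1 + phi2 * sm2 + phi3 * eps
    xi = _offsets(geog)
    y = _poisson_counts(rng, xi, alpha + S)
    cfg = SimulationConfig(phi=(phi1, phi2, phi3), alpha=alpha, seed=seed, family="poisson")
    labels = (coords_distance.source_label, coords_movement.source_label)
    if labels[0] == labels[1]:
        labels = (labels[0] + "_1", labels[1] + "_2")
    return SimulatedDataset(y, xi, S, {labels[0]: sm1, labels[1]: sm2}, cfg)


def binary_outcome(
    geog: Geography,
    coords: ConnectivityCoordinates,
    phi: float,
    seed: int,
    alpha: float = 0.0,
) -> SimulatedDataset:
    """Bernoulli outcomes: y_i ~ Bernoulli(logit^-1(alpha + S_i)), S as in single_source."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    _check_coords(geog, coords)
    rng = np.random.default_rng(seed)
    smooth = standardize_field(sm_surface(coords.coords[:, 0], coords.coords[:, 1]))
    eps = rng.normal(size=geog.n)
    S = phi * smooth + (1.0 - phi) * eps
    p = expit(alpha + S)
    y = rng.binomial(1, p)
    cfg = SimulationConfig(phi=(phi,), alpha=alpha, seed=seed, family="bernoulli")
    return SimulatedDataset(y, np.ones(geog.n), S, {coords.source_label: smooth}, cfg)


def synthetic_geography(
    n: int,
    seed: int,
    pop_median: float = 2e4,
    pop_sdlog: float = 1.0,
    gamma: float = 2.0,
    kappa: float = 1.0,
) -> tuple[Geography, FlowMatrix]:
    """Random study region on the unit square.

    Centroids are drawn uniformly, contiguity is the Delaunay triangulation
    graph (connected by construction), populations are log-normal with the
    given median and log-sd, and flows come from a gravity model.
    """
    if n < 10:
        raise ValueError("need at least 10 areas")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(size=(n, 2))
    tri = Delaunay(pts)
    W = np.zeros((n, n), dtype=int)
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                W[simplex[a], simplex[b]] = 1
                W[simplex[b], simplex[a]] = 1
    populations = pop_median * np.exp(rng.normal(0.0, pop_sdlog, size=n))
    geog = Geography(tuple(range(n)), pts, populations, W)
    flows = gravity_flows(populations, pts, gamma=gamma, kappa=kappa)
    return geog, flows


def abstract_coordinates(n: int, seed: int, source_label: str = "movement") -> ConnectivityCoordinates:
    """Seeded uniform scatter on the unit square as an abstract coordinate system.

    Stands in for a connectivity structure unrelated to geographic proximity
    (e.g. long-distance movement): smooth surfaces over these coordinates are
    not smooth functions of the map, which keeps multiple spatial terms in a
    model mutually identifiable.
    """
    if n < 2:
        raise ValueError("need at least 2 areas")
    rng = np.random.default_rng(seed)
    return ConnectivityCoordinates(rng.uniform(size=(n, 2)), source_label)


def single_source_grid(geog: Geography, coords: ConnectivityCoordinates, seed: int) -> list[SimulatedDataset]:
    """Eleven scenarios with phi = 0, 0.1, ..., 1; per-scenario seeds derive from `seed`."""
    phis = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 1)
    return [single_source(geog, coords, float(p), seed=seed + i) for i, p in enumerate(phis)]


def two_source_grid(
    geog: Geography,
    coords_distance: ConnectivityCoordinates,
    coords_movement: ConnectivityCoordinates,
    seed: int,
) -> list[SimulatedDataset]:
    """Ten scenarios with phi3 = 0.1 and phi1 = 0, 0.1, ..., 0.9 (phi2 = 0.9 - phi1)."""
    out = []
    for i in range(10):
        phi1 = round(0.1 * i, 1)
        phi2 = round(0.9 - phi1, 1)
        out.append(
            two_source(geog, coords_distance, coords_movement, phi1, phi2, 0.1, seed=seed + i)
        )
    return out
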