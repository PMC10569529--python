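"""Synthetic point patterns, initial conditions and count series.

Everything the analysis pipeline consumes can be generated here without a
simulation: uniform patterns on the periodic square / sphere, Gaussian
clusters of stated dispersion (the pre-polarized initial conditions use
sigma = 0.2 um), immobile Far1-GEF seed layouts, and Markov-chain cluster
count series mimicking the 120-s experimental scoring interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import Geometry

#: Dispersion of the pre-polarized Gaussian initial condition, um.
PREPOLARIZED_SIGMA = 0.2

#: Default receptor-dispersion grid for the initial-condition scans, um
#: (None stands for the uniform limit).
DISPERSION_GRID = (0.2, 0.5, 1.0, 2.0, 4.0, None)


@dataclass(frozen=True)
class InitialCondition:
    """How each conservation group is laid out at t = 0.

    ``kind`` is one of ``uniform``, ``prepolarized_cdc42``,
    ``polarized_receptors``, ``dispersed_receptors`` or ``fixed_far1_seeds``;
    ``sigma`` is the Gaussian dispersion where applicable and
    ``seed_positions`` the explicit coordinates of immobile Far1-GEF seeds.
    """

    kind: str = "uniform"
    sigma: float | None = None
    seed_positions: tuple = ()
    n_seeds: int = 0

    def __post_init__(self):
        kinds = (
            "uniform",
            "prepolarized_cdc42",
            "polarized_receptors",
            "dispersed_receptors",
            "fixed_far1_seeds",
        )
        if self.kind not in kinds:
            raise ValueError(f"unknown initial condition {self.kind!r}")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def uniform_pattern(n: int, geometry: Geometry, seed=0) -> np.ndarray:
    """i.i.d. uniform points: on the square (2D) or area-uniform on the sphere."""
    rng = _rng(seed)
    if n < 0:
        raise ValueError("n must be non-negative")
    if geometry.mode == "plane2d":
        return rng.uniform(0.0, geometry.L, size=(n, 2))
    v = rng.standard_normal(size=(n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return geometry.R * v / norms


def uniform_cytosol(n: int, geometry: Geometry, seed=0) -> np.ndarray:
    """Uniform points inside the sphere (3D cytosol)."""
    rng = _rng(seed)
    if geometry.mode == "plane2d":
        return uniform_pattern(n, geometry, rng)
    pts = rng.standard_normal(size=(n, 3))
    pts /= np.maximum(np.linalg.norm(pts, axis=1, keepdims=True), 1e-300)
    radii = geometry.R * rng.random(n) ** (1.0 / 3.0)
    return pts * radii[:, None]


def gaussian_cluster_pattern(
    n: int,
    geometry: Geometry,
    sigma: float,
    center=None,
    seed=0,
    spherical_vmf: bool = False,
) -> np.ndarray:
    """Gaussian cluster of dispersion ``sigma`` (um) around ``center``.

    2D clusters are wrapped into the periodic square; 3D clusters are drawn
    in the tangent plane at the centre and radially projected to the sphere
    (a von Mises-Fisher draw is available with ``spherical_vmf=True``).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = _rng(seed)
    if geometry.mode == "plane2d":
        if center is None:
            center = (geometry.L / 2.0, geometry.L / 2.0)
        pts = np.asarray(center, float) + sigma * rng.standard_normal(size=(n, 2))
        return np.mod(pts, geometry.L)
    R = geometry.R
    if center is None:
        center = (0.0, 0.0, R)
    c = np.asarray(center, float)
    c = c / np.linalg.norm(c)
    if spherical_vmf:
        kappa = (R / sigma) ** 2
        w = 1.0 + np.log(rng.random(n) * (1.0 - np.exp(-2.0 * kappa)) + np.exp(-2.0 * kappa)) / kappa
        phi = rng.uniform(0, 2 * np.pi, n)
        t1, t2 = _tangent_basis(c)
        s = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
        v = w[:, None] * c + s[:, None] * (np.cos(phi)[:, None] * t1 + np.sin(phi)[:, None] * t2)
        return R * v
    t1, t2 = _tangent_basis(c)
    g = sigma * rng.standard_normal(size=(n, 2))
    pts = R * c + g[:, :1] * t1 + g[:, 1:] * t2
    pts *= R / np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def _tangent_basis(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(c[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(c, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(c, t1)
    return t1, t2


def fixed_seed_layout(k: int, geometry: Geometry, arrangement="ring", positions=None) -> np.ndarray:
    """Positions of ``k`` immobile membrane Far1-GEF seeds.

    ``ring`` spaces them evenly: on a circle of radius 0.3 L around the
    domain centre (2D) or on a Fibonacci lattice over the sphere (3D).
    ``explicit`` uses the provided coordinates verbatim.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if arrangement == "explicit":
        pts = np.asarray(positions, float).reshape(k, geometry.dim)
        return pts
    if arrangement != "ring":
        raise ValueError(f"unknown arrangement {arrangement!r}")
    if k == 0:
        return np.empty((0, geometry.dim))
    if geometry.mode == "plane2d":
        ang = 2 * np.pi * np.arange(k) / k
        c = geometry.L / 2.0
        r = 0.3 * geometry.L
        return np.column_stack([c + r * np.cos(ang), c + r * np.sin(ang)])
    i = np.arange(k) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / k
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return geometry.R * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def experimental_like_count_series(
    duration: float,
    transition_matrix,
    interval: float = 120.0,
    initial_state: int = 0,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic 0/1/2+ cluster-count series from a Markov chain.

    Emulates the structure of the experimental scoring: one state label per
    ``interval`` seconds over ``duration`` (inclusive of t = 0, i.e.
    ``floor(duration/interval) + 1`` samples).  States are 0, 1, 2 with 2
    meaning "2 or more clusters".
    """
    P = np.asarray(transition_matrix, float)
    if P.shape != (3, 3) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("transition_matrix must be 3x3 row-stochastic")
    rng = _rng(seed)
    n = int(np.floor(duration / interval)) + 1
    states = np.empty(n, dtype=np.int64)
    states[0] = initial_state
    for i in range(1, n):
        states[i] = rng.choice(3, p=P[states[i - 1]])
    times = interval * np.arange(n)
    return times, states
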