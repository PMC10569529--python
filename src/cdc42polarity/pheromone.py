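"""Extracellular pheromone: uniform baths, point-source gradients, rings.

A receiver cell (sphere of radius R at the origin) can be exposed to

* a **uniform bath**: a fixed number of pheromone molecules, chosen as
  c * N_A * V for the nominal concentration c in the shell between the
  membrane and the outer boundary, replenished at a uniform random
  position whenever one is consumed;
* a **point source**: an emitter cell (second sphere) releases molecules
  from a single point on its surface as a Poisson process; molecules
  diffuse at 150 um^2/s, reflect at both cell membranes and are removed at
  an absorbing shell 7 um from the origin.

Concentrations near the receiver are summarized as a :class:`RingProfile`:
time-averaged concentration in a thin sampling shell above the membrane,
binned by polar angle from the source-facing pole.  A measured profile can
be frozen into a position-dependent receptor-activation rate
(:func:`frozen_gradient_from_profile`) so that scaled-down gradient runs
do not need explicit pheromone particles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import (
    Geometry,
    ParameterSet,
    SpeciesSpec,
    ReactionSpec,
    concentration_to_molecules,
)

#: molecules per um^3 at 1 nM
MOLEC_PER_UM3_PER_NM = 0.602214076

D_PHEROMONE = 150.0  # um^2 s^-1
R_ABSORB_DEFAULT = 7.0  # um

#: default emitter-cell placement: 5-um-diameter cell with a 0.05-um gap
EMITTER_CENTER = (5.05, 0.0, 0.0)
EMITTER_RADIUS = 2.5
SOURCE_AXIS = (1.0, 0.0, 0.0)  # receiver pole facing the emitter


@dataclass
class PheromoneProtocol:
    """How extracellular pheromone is imposed on a receiver-cell run."""

    mode: str = "uniform"  # "uniform" | "point_source"
    background_nM: float = 0.0
    emission_rate: float = 0.0  # molecules / s
    source_position: tuple | None = None
    emitter_center: tuple = EMITTER_CENTER
    emitter_radius: float = EMITTER_RADIUS
    bath_outer: float | None = None  # outer reflecting radius for the bath

    def __post_init__(self):
        if self.mode not in ("uniform", "point_source"):
            raise ValueError(f"unknown pheromone mode {self.mode!r}")
        if self.emission_rate < 0 or self.background_nM < 0:
            raise ValueError("rates and concentrations must be non-negative")

    def apply_to(self, compiled):
        """Configure a compiled kernel model (see engine._Compiled)."""
        geo: Geometry = compiled.geometry
        if compiled.ph_spec < 0:
            raise ValueError("parameter set has no Pheromone species")
        if self.mode == "uniform":
            compiled.ph_mode = _kernels.PH_BATH
            outer = self.bath_outer or geo.R_absorb or R_ABSORB_DEFAULT
            compiled.ph_Rbath = float(outer)
            vol = 4.0 / 3.0 * math.pi * (outer**3 - geo.R**3)
            compiled.bath_n = int(round(concentration_to_molecules(self.background_nM, vol)))
        else:
            compiled.ph_mode = _kernels.PH_POINT
            compiled.ph_rate_dt = self.emission_rate * compiled.params.dt
            compiled.ph_Rabs = geo.R_absorb or R_ABSORB_DEFAULT
            c = np.asarray(self.emitter_center, float)
            compiled.ph_emit_c = c
            compiled.ph_emit_R = float(self.emitter_radius)
            if self.source_position is not None:
                src = np.asarray(self.source_position, float)
            else:
                # point on the emitter surface facing the receiver
                u = -c / np.linalg.norm(c)
                src = c + (self.emitter_radius + 1e-6) * u
            compiled.ph_src = src


@dataclass
class RingProfile:
    """Time-averaged pheromone concentration in polar-angle rings.

    Rings are equal-width polar-angle bands measured from the source-facing
    pole, so the steep part of the gradient near the pole is resolved.
    """

    theta_edges: np.ndarray  # radians, ascending from 0 (pole) to pi
    mean_nM: np.ndarray
    std_nM: np.ndarray
    axis: tuple = SOURCE_AXIS
    shell: float = 0.1

    @property
    def cos_edges(self) -> np.ndarray:
        return np.cos(self.theta_edges)  # descending from 1 to -1

    @property
    def theta_centers(self) -> np.ndarray:
        return np.degrees(0.5 * (self.theta_edges[:-1] + self.theta_edges[1:]))


@dataclass
class FrozenGradient:
    """Position-dependent receptor-activation rate replacing explicit pheromone."""

    axis: np.ndarray
    cos_edges: np.ndarray  # descending
    rate_per_s: np.ndarray  # per-ring Ri_m -> Ra_m activation rate
    note: str = "frozen-field approximation of an explicit pheromone gradient"


# ---------------------------------------------------------------------------
# reference single-step operations

def emit(rate: float, dt: float, source_position, rng=None) -> np.ndarray:
    """Poisson emission for one step: n ~ Poisson(rate*dt) molecules at the source."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = rng.poisson(rate * dt)
    return np.tile(np.asarray(source_position, float), (n, 1))


def propagate_pheromone(
    positions,
    dt: float,
    D: float = D_PHEROMONE,
    r_absorb: float = R_ABSORB_DEFAULT,
    cells=((np.zeros(3), 2.5),),
    rng=None,
) -> np.ndarray:
    """Reference Brownian step for free pheromone molecules.

    Molecules crossing ``r_absorb`` (from the origin) are removed; molecules
    entering any cell sphere are reflected off its membrane.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pts = np.asarray(positions, float)
    if pts.size == 0:
        return pts.reshape(0, 3)
    pts = pts + math.sqrt(2 * D * dt) * rng.standard_normal(pts.shape)
    for center, R in cells:
        d = pts - np.asarray(center, float)
        r = np.linalg.norm(d, axis=1)
        inside = r < R
        if inside.any():
            f = (2 * R - r[inside]) / np.maximum(r[inside], 1e-12)
            pts[inside] = np.asarray(center, float) + d[inside] * f[:, None]
    if r_absorb is not None:
        pts = pts[np.linalg.norm(pts, axis=1) <= r_absorb]
    return pts


# ---------------------------------------------------------------------------
# ring concentrations

def ring_concentrations(
    position_samples,
    geometry: Geometry,
    n_rings: int = 12,
    shell: float = 0.1,
    axis=SOURCE_AXIS,
    background_nM: float = 0.0,
) -> RingProfile:
    """Per-ring time-averaged concentration from pheromone position samples.

    ``position_samples`` is a sequence of (n_i, 3) arrays (one per recorded
    time).  Counts are taken in the sampling shell R < r < R + ``shell``
    above the receiver membrane, binned into ``n_rings`` equal-width
    polar-angle rings from ``axis``, and converted to nM by dividing by the
    ring volume.  The default 15-degree rings average over the source-
    adjacent concentration singularity at the scale of the polarity-site
    footprint; much finer rings resolve arbitrarily high values right at
    the source.  ``background_nM`` is added to the mean (used when a
    uniform bath is treated analytically rather than with explicit
    particles).
    """
    samples = list(position_samples)
    if not samples:
        raise ValueError("no position samples given")
    R = geometry.R
    ax = np.asarray(axis, float)
    ax = ax / np.linalg.norm(ax)
    theta_edges = np.linspace(0.0, math.pi, n_rings + 1)
    cos_edges = np.cos(theta_edges)
    shell_factor = 2.0 * math.pi / 3.0 * ((R + shell) ** 3 - R**3)
    vol_bin = shell_factor * (cos_edges[:-1] - cos_edges[1:])
    per_t = np.zeros((len(samples), n_rings))
    for k, pts in enumerate(samples):
        pts = np.asarray(pts, float).reshape(-1, 3)
        if pts.size == 0:
            continue
        r = np.linalg.norm(pts, axis=1)
        m = (r > R) & (r < R + shell)
        if not m.any():
            continue
        theta = np.arccos(np.clip(pts[m] @ ax / r[m], -1, 1))
        idx = np.clip((theta / math.pi * n_rings).astype(int), 0, n_rings - 1)
        per_t[k] = np.bincount(idx, minlength=n_rings)
    conc = per_t / vol_bin / MOLEC_PER_UM3_PER_NM
    return RingProfile(
        theta_edges, conc.mean(axis=0) + background_nM, conc.std(axis=0), tuple(ax), shell
    )


# ---------------------------------------------------------------------------
# measurement runs (pheromone-only two-cell simulation)

def _pheromone_only_params(R_absorb: float = R_ABSORB_DEFAULT) -> ParameterSet:
    geo = Geometry.sphere(R_absorb=R_absorb)
    return ParameterSet(
        circuit="core",
        geometry=geo,
        species={"Pheromone": SpeciesSpec("Pheromone", "extracellular", D_PHEROMONE)},
        reactions=[],
        abundances={},
        conservation_groups={},
    )


def measure_gradient(
    emission_rate: float,
    duration: float = 20.0,
    warmup: float = 4.0,
    sample_interval: float = 0.05,
    n_rings: int = 12,
    shell: float = 0.1,
    background_nM: float = 0.0,
    seed: int = 0,
) -> RingProfile:
    """Simulate the two-cell pheromone field and return its ring profile.

    The emitter releases ``emission_rate`` molecules/s from the point on its
    surface facing the receiver; molecules are absorbed 7 um from the origin
    and reflect off both membranes.  A uniform background is added
    analytically (the bath is position-independent by construction).
    """
    from .engine import ParticleState, Simulation

    params = _pheromone_only_params()
    proto = PheromoneProtocol(mode="point_source", emission_rate=emission_rate)
    empty = ParticleState(
        0.0, np.zeros((0, 3)), np.zeros(0, dtype=np.int32), ("Pheromone",),
        params.geometry,
    )
    sim = Simulation(params, empty, seed=seed, pheromone=proto)
    sim.run_for(warmup)
    samples = []
    n_samp = int(round(duration / sample_interval))
    for _ in range(n_samp):
        sim.run_for(sample_interval)
        samples.append(sim.snapshot().positions)
    return ring_concentrations(
        samples, params.geometry, n_rings=n_rings, shell=shell,
        background_nM=background_nM,
    )


def frozen_gradient_from_profile(
    profile: RingProfile, lambda_11: float = 1.8, rho: float = 0.05
) -> FrozenGradient:
    """Convert a ring profile into per-ring receptor-activation rates.

    Within the reactive radius, binding fires at probability rate lambda_11;
    averaged over a well-mixed local concentration c the per-receptor rate is
    lambda_11 * V_3D * c with V_3D the half-sphere reaction volume (the
    pheromone approaches a membrane-bound receptor from outside only).
    """
    v3d = 0.5 * (4.0 / 3.0) * math.pi * rho**3
    rates = lambda_11 * v3d * np.asarray(profile.mean_nM) * MOLEC_PER_UM3_PER_NM
    return FrozenGradient(np.asarray(profile.axis, float), np.asarray(profile.cos_edges), rates)


def uniform_frozen_field(c_nM: float, n_rings: int = 4, lambda_11: float = 1.8,
                         rho: float = 0.05) -> FrozenGradient:
    """Frozen field for a uniform concentration (all rings equal)."""
    prof = RingProfile(
        np.linspace(0.0, math.pi, n_rings + 1),
        np.full(n_rings, float(c_nM)),
        np.zeros(n_rings),
    )
    return frozen_gradient_from_profile(prof, lambda_11, rho)


# ---------------------------------------------------------------------------
# receptor-pheromone affinity

def measure_receptor_kd(
    concentrations_nM=(3.0, 7.0, 14.0),
    n_receptors: int = 1000,
    duration: float = 24.0,
    equilibration: float = 12.0,
    rate_scale: float = 100.0,
    bath_outer: float = 3.5,
    seed: int = 0,
) -> float:
    """Receptor-pheromone K_D (nM) from simulated equilibrium occupancy.

    Runs membrane receptors in a uniform pheromone bath with only the
    binding (lambda_11) and dissociation (k_13) channels active.  Both rates
    are scaled up by ``rate_scale`` so equilibrium is reached quickly; the
    equilibrium constant K_D = k_13 / (lambda_11 * V_3D) is invariant under
    that joint scaling.  K_D is estimated per concentration from the bound
    fraction f as c * (1 - f) / f and averaged.
    """
    from .engine import Simulation, initial_state
    from .fixtures import InitialCondition
    from .params import load_tables

    ph_tab = load_tables()["pheromone"]
    rates = {r["symbol"]: r["rate_3d"] for r in ph_tab["reactions"]}
    geo = Geometry.sphere()
    species = {
        "Ri_m": SpeciesSpec("Ri_m", "membrane", 0.0001),
        "Ra_m": SpeciesSpec("Ra_m", "membrane", 0.0001),
        "Pheromone": SpeciesSpec("Pheromone", "extracellular", D_PHEROMONE),
    }
    reactions = [
        ReactionSpec("lambda_11", "second_order", ("Ri_m", "Pheromone"), ("Ra_m",),
                     rates["lambda_11"] * rate_scale, "s^-1", rho=0.05, anchor="Ri_m"),
        ReactionSpec("k_13", "first_order", ("Ra_m",), ("Ri_m", "Pheromone"),
                     rates["k_13"] * rate_scale, "s^-1"),
    ]
    params = ParameterSet(
        circuit="core", geometry=geo, species=species, reactions=reactions,
        abundances={"Receptor": n_receptors},
        conservation_groups={"Receptor": ("Ri_m", "Ra_m")},
    )
    kds = []
    for j, c in enumerate(concentrations_nM):
        proto = PheromoneProtocol(mode="uniform", background_nM=c, bath_outer=bath_outer)
        state = initial_state(params, InitialCondition(), seed=seed + j)
        sim = Simulation(params, state, seed=seed + 100 + j, pheromone=proto)
        sim.run_for(equilibration)
        bound = []
        n_obs = int(round((duration - equilibration) / 0.5))
        for _ in range(n_obs):
            sim.run_for(0.5)
            cnt = sim.species_counts()
            bound.append(cnt["Ra_m"] / (cnt["Ra_m"] + cnt["Ri_m"]))
        f = float(np.mean(bound))
        kds.append(c * (1.0 - f) / f)
    return float(np.mean(kds))
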