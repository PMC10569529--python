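"""Particle-based stochastic simulation engine.

Brownian dynamics with Euler-Maruyama steps (per-axis increments of
standard deviation sqrt(2*D*dt)), first-order reactions firing with
probability 1 - exp(-k*dt), and second-order reactions firing with
probability 1 - exp(-lambda*dt) whenever the partners are within the
reactive radius rho (minimum-image distance on the periodic plane,
Euclidean chord on the sphere).  Dissociation products are separated by
rho + 1e-5 um to avoid immediate reassociation.  Within a step the update
order is: diffusion, then first-order (including surface association),
then bimolecular reactions; each particle reacts at most once per step.

The heavy lifting happens in :mod:`cdc42polarity._kernels`; this module
compiles a :class:`~cdc42polarity.params.ParameterSet` into kernel tables,
manages state and recording, and exposes small pure functions for the
individual update rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import advance, seed_kernel_rng
from .fixtures import (
    InitialCondition,
    PREPOLARIZED_SIGMA,
    fixed_seed_layout,
    gaussian_cluster_pattern,
    uniform_cytosol,
    uniform_pattern,
)
from .params import Geometry, ParameterSet, ReactionSpec, concentration_to_molecules

DISSOCIATION_OFFSET = 1e-5  # um beyond rho

#: canonical species ordering for stable integer codes
_SPECIES_ORDER = (
    "Cdc42D_c", "Cdc42D_m", "Cdc42T", "Bem1GEF_c", "Bem1GEF_m",
    "Cdc42T_Bem1GEF", "Far1GEF_c", "RaGEF", "Ra_m", "Ri_c", "Ri_m",
    "Pheromone", "Far1GEF_f",
)

ACTIVE_CDC42 = ("Cdc42T", "Cdc42T_Bem1GEF")


# ---------------------------------------------------------------------------
# small pure update rules (the per-event contracts; also used in tests)

def first_order_probability(k: float, dt: float) -> float:
    """P = 1 - exp(-k*dt)."""
    return -math.expm1(-k * dt)


def second_order_probability(lam: float, dt: float) -> float:
    """P = 1 - exp(-lambda*dt), applicable when partners are within rho."""
    return -math.expm1(-lam * dt)


def attempt_first_order(reaction: ReactionSpec, dt: float, u: float) -> bool:
    """Does a first-order channel fire this step given uniform draw ``u``?"""
    return u < first_order_probability(reaction.rate, dt)


def attempt_second_order(distance: float, reaction: ReactionSpec, dt: float, u: float) -> bool:
    """Bimolecular firing rule: within rho, then probability 1-exp(-lambda*dt)."""
    if reaction.rho is None or distance > reaction.rho:
        return False
    return u < second_order_probability(reaction.rate, dt)


def place_dissociated(parent_position, rho: float, geometry: Geometry, rng=None):
    """Positions of a dissociating pair: parent stays, partner at rho + 1e-5.

    The separation direction is uniform on the circle (2D) or uniform in the
    tangent plane with radial re-projection (sphere membrane).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = np.asarray(parent_position, float)
    d = rho + DISSOCIATION_OFFSET
    if geometry.mode == "plane2d":
        th = rng.uniform(0, 2 * np.pi)
        q = np.mod(p + d * np.array([np.cos(th), np.sin(th)]), geometry.L)
        return p.copy(), q
    n = p / np.linalg.norm(p)
    g = rng.standard_normal(3)
    g -= g.dot(n) * n
    g /= np.linalg.norm(g)
    q = p + d * g
    q *= geometry.R / np.linalg.norm(q)
    return p.copy(), q


def brownian_step(positions, D: float, dt: float, geometry: Geometry, rng=None,
                  compartment: str = "membrane"):
    """Reference (numpy) Brownian update of a set of positions.

    Plane: independent Gaussian increments per axis, wrapped periodically.
    Sphere membrane: tangent-plane increment, re-projected to radius R.
    Sphere cytosol: free 3D increment, reflected at the membrane.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pts = np.array(positions, float)
    sg = math.sqrt(2.0 * D * dt)
    if geometry.mode == "plane2d":
        return np.mod(pts + sg * rng.standard_normal(pts.shape), geometry.L)
    g = sg * rng.standard_normal(pts.shape)
    if compartment == "membrane":
        n = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        g -= (g * n).sum(axis=1, keepdims=True) * n
        pts = pts + g
        pts *= geometry.R / np.linalg.norm(pts, axis=1, keepdims=True)
        return pts
    pts = pts + g
    r = np.linalg.norm(pts, axis=1)
    over = r > geometry.R
    if over.any():
        pts[over] *= ((2 * geometry.R - r[over]) / r[over])[:, None]
    return pts


# ---------------------------------------------------------------------------
# state containers

@dataclass
class ParticleState:
    """Positions and species of every molecule at one instant."""

    t: float
    positions: np.ndarray  # (N, dim)
    species: np.ndarray  # (N,) integer codes into species_names
    species_names: tuple
    geometry: Geometry
    seed: int | None = None

    def positions_of(self, names) -> np.ndarray:
        if isinstance(names, str):
            names = (names,)
        codes = [self.species_names.index(n) for n in names if n in self.species_names]
        mask = np.isin(self.species, codes)
        return self.positions[mask]

    def counts(self) -> dict:
        return {
            n: int(np.sum(self.species == i))
            for i, n in enumerate(self.species_names)
        }


@dataclass
class Trajectory:
    """Recorded snapshots (default every 10 s) and per-species count series."""

    times: np.ndarray
    snapshots: list  # list of ParticleState
    counts: pd.DataFrame  # index: time, columns: species
    meta: dict = field(default_factory=dict)

    @property
    def params(self) -> ParameterSet:
        return self.meta["params"]

    def active_cdc42(self, i: int) -> np.ndarray:
        return self.snapshots[i].positions_of(ACTIVE_CDC42)

    def k_series(self, species=ACTIVE_CDC42, nbins=None):
        """Ripley-K polarity series over the recorded snapshots."""
        from .ripley import DEFAULT_NBINS, ripley_k

        nbins = nbins or DEFAULT_NBINS
        ks, ts = [], []
        for s in self.snapshots:
            pts = s.positions_of(species)
            ks.append(ripley_k(pts, s.geometry, nbins).K if len(pts) >= 2 else 0.0)
            ts.append(s.t)
        return np.asarray(ts), np.asarray(ks)


# ---------------------------------------------------------------------------
# model compilation

class _Compiled:
    """Kernel-ready tables for one ParameterSet (+ optional pheromone mode)."""

    def __init__(self, params: ParameterSet, pheromone=None, frozen=None, capacity=None):
        geo = params.geometry
        self.params = params
        self.geometry = geo
        self.names = tuple(n for n in _SPECIES_ORDER if n in params.species)
        extra = tuple(n for n in params.species if n not in self.names)
        self.names += extra
        self.code = {n: i for i, n in enumerate(self.names)}
        S = len(self.names)
        dt = params.dt

        self.sig1 = np.zeros(S)
        self.sigM = np.zeros(S)
        self.Mint = np.ones(S, dtype=np.int64)
        self.Moff = np.zeros(S, dtype=np.int64)
        self.compart = np.zeros(S, dtype=np.int8)
        self.mobile = np.ones(S, dtype=np.int8)
        # only membrane species live in the neighbor grid: every bimolecular
        # channel has at least one membrane reactant, so reactions iterate
        # the non-membrane side and look partners up in the grid
        self.in_grid = np.zeros(S, dtype=np.int8)
        cpt = {"cytosol": 0, "membrane": 1, "extracellular": 2}
        for n, sp in params.species.items():
            i = self.code[n]
            self.compart[i] = cpt[sp.compartment]
            if sp.compartment == "membrane":
                self.in_grid[i] = 1
            if sp.D <= 0 or not sp.mobile:
                self.mobile[i] = 0
                continue
            self.sig1[i] = math.sqrt(2.0 * sp.D * dt)
            # block interval: rms move per update capped at rho/10
            M = int((params.rho / 10.0) ** 2 / (2.0 * sp.D * dt))
            M = max(1, min(M, 100))
            self.Mint[i] = M
            self.Moff[i] = i % M
            self.sigM[i] = math.sqrt(2.0 * sp.D * M * dt)

        # --- reaction tables ---
        fo_r, fo_p, fo_np, fo_p1, fo_p2 = [], [], [], [], []
        so_a, so_b, so_p, so_bind, so_pa, so_pb, so_iter = [], [], [], [], [], [], []
        self.frozen = frozen
        for r in params.reactions:
            if frozen is not None and r.symbol == "lambda_11":
                continue  # replaced by the position-modulated channel
            products = [p for p in r.products if p in self.code or p == "Pheromone"]
            if r.kind in ("first_order", "surface_association"):
                rate = r.rate
                if r.kind == "surface_association":
                    rate = r.rate * geo.A_m / geo.V_c  # equivalent well-mixed rate
                prods = list(r.products)
                if frozen is not None:
                    prods = [p for p in prods if p != "Pheromone"]
                if len(prods) == 2:
                    # membrane product inherits the parent position
                    if self.compart[self.code[prods[1]]] == 1 and self.compart[self.code[prods[0]]] != 1:
                        prods = [prods[1], prods[0]]
                fo_r.append(self.code[r.reactants[0]])
                fo_p.append(first_order_probability(rate, dt))
                fo_np.append(len(prods))
                fo_p1.append(self.code[prods[0]])
                fo_p2.append(self.code[prods[1]] if len(prods) == 2 else -1)
            else:
                p = second_order_probability(r.rate, dt)
                if len(r.products) == 1:
                    anchor = r.anchor or r.reactants[0]
                    other = r.reactants[1] if r.reactants[0] == anchor else r.reactants[0]
                    so_a.append(self.code[anchor])
                    so_b.append(self.code[other])
                    so_bind.append(1)
                    so_pa.append(self.code[r.products[0]])
                    so_pb.append(-1)
                else:
                    cat = next(s for s in r.reactants if s in r.products)
                    sub = next(s for s in r.reactants if s != cat)
                    prod = next(s for s in r.products if s != cat)
                    so_a.append(self.code[cat])
                    so_b.append(self.code[sub])
                    so_bind.append(0)
                    so_pa.append(self.code[cat])
                    so_pb.append(self.code[prod])
                so_p.append(p)
                ca = self.compart[so_a[-1]]
                cb = self.compart[so_b[-1]]
                if ca != 1 and cb == 1:
                    so_iter.append(0)
                elif cb != 1 and ca == 1:
                    so_iter.append(1)
                elif ca == 1 and cb == 1:
                    so_iter.append(2)
                else:
                    raise ValueError(
                        f"{r.symbol}: bimolecular reactions need a membrane reactant"
                    )
        self.fo = tuple(
            np.asarray(a, d) for a, d in
            ((fo_r, np.int32), (fo_p, np.float64), (fo_np, np.int8),
             (fo_p1, np.int32), (fo_p2, np.int32))
        )
        # candidate-thinning factors: a candidate is tested with
        # probability alpha and fires with (1-(1-p)^k)/alpha over its k
        # in-range partners, preserving the per-candidate compound firing
        # probability exactly (up to a clamp at ~25+ simultaneous partners)
        so_alpha = [min(1.0, 20.0 * p) for p in so_p]
        self.so = tuple(
            np.asarray(a, d) for a, d in
            ((so_a, np.int32), (so_b, np.int32), (so_p, np.float64),
             (so_bind, np.int8), (so_pa, np.int32), (so_pb, np.int32),
             (so_iter, np.int8), (so_alpha, np.float64))
        )

        # --- geometry / grid ---
        if geo.mode == "plane2d":
            self.mode = 0
            self.L = geo.L
            self.R = 0.0
            self.G = 0.0
            ncx = int(geo.L / params.rho)
            self.cell = geo.L / ncx
            self.ncx = self.ncy = ncx
            self.ncz = 1
        else:
            self.mode = 1
            self.L = 0.0
            self.R = geo.R
            self.G = geo.R + 0.2
            # cells of ~2*rho keep the 3D grid small enough to stay cache
            # resident; the +/-1 neighbourhood still covers the reaction radius
            ncx = int(2 * self.G / (2 * params.rho))
            self.cell = 2 * self.G / ncx
            self.ncx = self.ncy = self.ncz = ncx
        self.rho = params.rho
        self.rho_off = params.rho + DISSOCIATION_OFFSET

        # --- pheromone protocol ---
        self.ph_mode = _kernels.PH_NONE
        self.ph_spec = self.code.get("Pheromone", -1)
        self.ph_rate_dt = 0.0
        self.ph_src = np.zeros(3)
        self.ph_Rabs = geo.R_absorb or 0.0
        self.ph_emit_c = np.zeros(3)
        self.ph_emit_R = 0.0
        self.ph_Rbath = 0.0
        self.bath_n = 0
        if pheromone is not None:
            pheromone.apply_to(self)
        if frozen is not None:
            # releases are implicit in frozen-field mode
            self.ph_mode = _kernels.PH_BATH
            self.ph_Rbath = geo.R + 1.0
            self.pm_on = np.int8(1)
            self.pm_r = np.int32(self.code["Ri_m"])
            self.pm_prod = np.int32(self.code["Ra_m"])
            self.pm_axis = np.asarray(frozen.axis, float)
            self.pm_edges = np.asarray(frozen.cos_edges, float)
            pm_probs = -np.expm1(-np.asarray(frozen.rate_per_s, float) * dt)
            self.pm_p = pm_probs
            self.pm_pmax = float(pm_probs.max())
        else:
            self.pm_on = np.int8(0)
            self.pm_r = np.int32(0)
            self.pm_prod = np.int32(0)
            self.pm_axis = np.zeros(3)
            self.pm_edges = np.zeros(2)
            self.pm_p = np.zeros(1)
            self.pm_pmax = 0.0

        n_circuit = sum(params.abundances.values())
        cap = capacity or (n_circuit + max(2 * self.bath_n, 20000) * (self.ph_spec >= 0))
        self.capacity = int(max(cap, n_circuit + 16))

    def kernel_args(self, st):
        return (
            st["pos"], st["spec"], st["stamp"], st["members"], st["mpos"], st["count"],
            st["head"], st["nxt"], st["prv"], st["cellof"], st["free"], st["free_top"],
        )


# ---------------------------------------------------------------------------
# initial conditions

def initial_state(params: ParameterSet, init: InitialCondition | None = None, seed=0,
                  frozen=None, preequilibrate_receptors: bool = False) -> ParticleState:
    """Lay out all molecules for one run.

    Uniform runs start with Cdc42 as membrane Cdc42-GDP, Bem1-GEF and
    Far1-GEF in the cytosol, and receptors on the membrane (active in the
    constitutive circuits, inactive in the pheromone-binding circuit), all
    at uniform random positions.  ``prepolarized_cdc42`` concentrates all
    Cdc42 as a Gaussian cluster of active Cdc42 (sigma = 0.2 um);
    ``polarized_receptors``/``dispersed_receptors`` concentrate the
    receptors instead.

    With ``preequilibrate_receptors`` and a frozen pheromone gradient,
    membrane receptors start activated with their local equilibrium
    probability k_on(theta) / (k_on(theta) + k_off) instead of all
    inactive -- emulating a cell that has already been exposed to the
    gradient for several binding relaxation times.
    """
    init = init or InitialCondition()
    rng = np.random.default_rng(seed)
    geo = params.geometry
    names, codes, positions = [], [], []

    def membrane(n, clustered=False, sigma=PREPOLARIZED_SIGMA):
        if clustered:
            return gaussian_cluster_pattern(n, geo, sigma, seed=rng)
        return uniform_pattern(n, geo, rng)

    def cytosol(n):
        if geo.mode == "plane2d":
            return uniform_pattern(n, geo, rng)
        return uniform_cytosol(n, geo, rng)

    ab = params.abundances
    if "Cdc42" in ab:
        n = ab["Cdc42"]
        if init.kind == "prepolarized_cdc42":
            names.append("Cdc42T")
            positions.append(membrane(n, clustered=True, sigma=init.sigma or PREPOLARIZED_SIGMA))
        else:
            names.append("Cdc42D_m")
            positions.append(membrane(n))
    if "Bem1GEF" in ab and ab.get("Bem1GEF", 0) >= 0 and "Bem1GEF_c" in params.species:
        names.append("Bem1GEF_c")
        positions.append(cytosol(ab["Bem1GEF"]))
    if "Far1GEF" in ab and "Far1GEF_c" in params.species:
        names.append("Far1GEF_c")
        positions.append(cytosol(ab["Far1GEF"]))
    if "Receptor" in ab:
        n = ab["Receptor"]
        surface = "Ri_m" if "Ri_m" in params.species else "Ra_m"
        clustered = init.kind in ("polarized_receptors", "dispersed_receptors")
        pts = membrane(n, clustered=clustered, sigma=init.sigma or PREPOLARIZED_SIGMA)
        if preequilibrate_receptors and surface == "Ri_m":
            if frozen is None:
                raise ValueError("receptor pre-equilibration needs a frozen gradient")
            k_off = sum(r.rate for r in params.reactions
                        if r.kind == "first_order" and r.reactants == ("Ra_m",))
            mu = pts @ (np.asarray(frozen.axis, float)
                        / np.linalg.norm(frozen.axis)) / geo.R
            edges = np.asarray(frozen.cos_edges)  # descending
            idx = np.clip(np.searchsorted(-edges, -mu, side="right") - 1,
                          0, len(frozen.rate_per_s) - 1)
            k_on = np.asarray(frozen.rate_per_s)[idx]
            active = rng.random(n) < k_on / (k_on + k_off)
            names.append("Ra_m")
            positions.append(pts[active])
            pts = pts[~active]
        names.append(surface)
        positions.append(pts)
    if init.kind == "fixed_far1_seeds" or len(init.seed_positions) or init.n_seeds:
        if "Far1GEF_f" not in params.species:
            raise ValueError("fixed Far1-GEF seeds need a circuit built with "
                             "with_fixed_far1_seeds=True")
        if len(init.seed_positions):
            pts = np.asarray(init.seed_positions, float)
        else:
            pts = fixed_seed_layout(init.n_seeds, geo)
        names.append("Far1GEF_f")
        positions.append(pts)

    model = _Compiled(params)
    n_tot = sum(len(p) for p in positions)
    pos = np.zeros((n_tot, geo.dim))
    spc = np.zeros(n_tot, dtype=np.int32)
    k = 0
    for nm, pts in zip(names, positions):
        m = len(pts)
        pos[k:k + m] = pts
        spc[k:k + m] = model.code[nm]
        k += m
    return ParticleState(0.0, pos, spc, model.names, geo, seed=seed)


# ---------------------------------------------------------------------------
# simulation driver

class Simulation:
    """A compiled model bound to mutable particle state."""

    ZBUF = 4_000_000

    def __init__(self, params: ParameterSet, state: ParticleState, seed=0,
                 pheromone=None, frozen=None):
        self.model = _Compiled(params, pheromone=pheromone, frozen=frozen)
        self.params = params
        self.rng = np.random.default_rng(seed)
        seed_kernel_rng(int(self.rng.integers(1, 2**31 - 1)))
        self.step_index = 0
        self.t = state.t
        self._build_state(state)
        self.zbuf = np.empty(self.ZBUF, dtype=np.float32)
        self.zptr = np.array([self.ZBUF], dtype=np.int64)  # trigger initial fill

    # -- state plumbing ----------------------------------------------------
    def _build_state(self, state: ParticleState):
        m = self.model
        cap = max(m.capacity, len(state.positions) + 16)
        S = len(m.names)
        st = {
            "pos": np.zeros((cap, 3)),
            "spec": np.full(cap, -1, dtype=np.int32),
            "stamp": np.full(cap, -1, dtype=np.int64),
            "members": np.zeros((S, cap), dtype=np.int32),
            "mpos": np.zeros(cap, dtype=np.int32),
            "count": np.zeros(S, dtype=np.int64),
            "head": np.full(m.ncx * m.ncy * m.ncz, -1, dtype=np.int32),
            "nxt": np.full(cap, -1, dtype=np.int32),
            "prv": np.full(cap, -1, dtype=np.int32),
            "cellof": np.full(cap, -1, dtype=np.int32),
            "free": np.zeros(cap, dtype=np.int32),
            "free_top": np.zeros(1, dtype=np.int64),
            "scratch": np.zeros(cap, dtype=np.int32),
            "pbuf": np.zeros(64, dtype=np.int32),
        }
        n = len(state.positions)
        st["pos"][:n, : state.positions.shape[1]] = state.positions
        # remap species codes from the state's name table to the model's
        remap = np.array([m.code.get(nm, -1) for nm in state.species_names], dtype=np.int32)
        st["spec"][:n] = remap[state.species]
        if np.any(st["spec"][:n] < 0):
            raise ValueError("state contains species unknown to the parameter set")
        for i in range(n):
            s = st["spec"][i]
            st["members"][s, st["count"][s]] = i
            st["mpos"][i] = st["count"][s]
            st["count"][s] += 1
            if m.in_grid[s]:
                c = _kernels._cell_index(
                    st["pos"][i, 0], st["pos"][i, 1], st["pos"][i, 2],
                    m.mode, m.L, m.G, m.cell, m.ncx, m.ncy, m.ncz,
                )
                st["cellof"][i] = c
                if c >= 0:
                    h = st["head"][c]
                    st["nxt"][i] = h
                    st["prv"][i] = -1
                    if h >= 0:
                        st["prv"][h] = i
                    st["head"][c] = i
        st["free"][: cap - n] = np.arange(cap - 1, n - 1, -1, dtype=np.int32)
        st["free_top"][0] = cap - n
        self.st = st
        # bath initialization
        if self.model.ph_mode == _kernels.PH_BATH and self.model.bath_n > 0:
            self._inject_bath_particles(self.model.bath_n)

    def _inject_bath_particles(self, n):
        m, st = self.model, self.st
        R, Rb = m.R, m.ph_Rbath
        dirs = self.rng.standard_normal((n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        rad = (R**3 + self.rng.random(n) * (Rb**3 - R**3)) ** (1 / 3)
        pts = dirs * rad[:, None]
        for p in pts:
            i = int(st["free"][st["free_top"][0] - 1])
            st["free_top"][0] -= 1
            st["spec"][i] = m.ph_spec
            st["pos"][i] = p
            st["members"][m.ph_spec, st["count"][m.ph_spec]] = i
            st["mpos"][i] = st["count"][m.ph_spec]
            st["count"][m.ph_spec] += 1

    # -- advancing ---------------------------------------------------------
    def run_steps(self, n_steps: int):
        m, st = self.model, self.st
        remaining = n_steps
        while remaining > 0:
            if self.zptr[0] + 3 * int(st["count"].sum()) + 64 > self.ZBUF:
                self.rng.standard_normal(dtype=np.float32, out=self.zbuf)
                self.zptr[0] = 0
            done = advance(
                *m.kernel_args(st),
                self.step_index, remaining,
                m.mode, m.L, m.R, m.G, m.cell, m.ncx, m.ncy, m.ncz,
                m.sig1, m.sigM, m.Mint, m.Moff, m.compart, m.mobile, m.in_grid,
                *m.fo, *m.so, m.rho, m.rho_off,
                m.pm_on, m.pm_r, m.pm_prod, m.pm_axis, m.pm_edges, m.pm_p, m.pm_pmax,
                np.int8(m.ph_mode), np.int32(m.ph_spec), m.ph_rate_dt, m.ph_src,
                m.ph_Rabs, m.ph_emit_c, m.ph_emit_R, m.ph_Rbath,
                self.zbuf, self.zptr, st["scratch"], st["pbuf"],
            )
            if done == 0 and self.zptr[0] == 0:
                raise RuntimeError("kernel made no progress")
            self.step_index += done
            remaining -= done
        self.t += n_steps * self.params.dt

    def run_for(self, duration: float):
        self.run_steps(int(round(duration / self.params.dt)))

    # -- observation -------------------------------------------------------
    def snapshot(self) -> ParticleState:
        st, m = self.st, self.model
        alive = np.flatnonzero(st["spec"] >= 0)
        dim = self.params.geometry.dim
        return ParticleState(
            self.t, st["pos"][alive, :dim].copy(), st["spec"][alive].copy(),
            m.names, self.params.geometry,
        )

    def species_counts(self) -> dict:
        return {n: int(self.st["count"][i]) for i, n in enumerate(self.model.names)}

    def check_conservation(self):
        cnt = self.species_counts()
        for g, members in self.params.conservation_groups.items():
            if g not in self.params.abundances:
                continue
            tot = sum(cnt.get(s, 0) for s in members)
            if tot != self.params.abundances[g]:
                raise RuntimeError(
                    f"conservation violated for {g}: {tot} != {self.params.abundances[g]}"
                )


def step(state: ParticleState, params: ParameterSet, seed=0,
         n_steps: int = 1) -> ParticleState:
    """Advance a state by ``n_steps`` time steps (fresh kernel RNG stream)."""
    sim = Simulation(params, state, seed=seed)
    sim.run_steps(n_steps)
    out = sim.snapshot()
    return out


def run(
    params: ParameterSet,
    init: InitialCondition | None = None,
    t_end: float = 400.0,
    seed: int = 0,
    record_interval: float = 10.0,
    pheromone=None,
    frozen=None,
    preequilibrate_receptors: bool = False,
    keep_snapshots: bool = True,
    check_conservation: bool = True,
    progress: bool = False,
) -> Trajectory:
    """Simulate one trajectory and record snapshots every ``record_interval`` s.

    Reproducible for a fixed seed.  Per-species molecule counts are recorded
    with every snapshot and conservation-group totals are asserted against
    the requested abundances.
    """
    n_rec = int(round(t_end / record_interval))
    if abs(n_rec * record_interval - t_end) > 1e-9:
        raise ValueError("t_end must be a multiple of the recording interval")
    state0 = initial_state(params, init, seed=seed, frozen=frozen,
                           preequilibrate_receptors=preequilibrate_receptors)
    sim = Simulation(params, state0, seed=seed + 1, pheromone=pheromone, frozen=frozen)
    times, snaps, counts = [0.0], [sim.snapshot()], [sim.species_counts()]
    for k in range(n_rec):
        sim.run_for(record_interval)
        if check_conservation:
            sim.check_conservation()
        times.append(sim.t)
        counts.append(sim.species_counts())
        if keep_snapshots:
            snaps.append(sim.snapshot())
        if progress:
            print(f"  t = {sim.t:.0f} s", flush=True)
    cdf = pd.DataFrame(counts, index=np.asarray(times))
    return Trajectory(
        np.asarray(times), snaps if keep_snapshots else [snaps[0]], cdf,
        meta={"params": params, "seed": seed, "init": init or InitialCondition(),
              "record_interval": record_interval},
    )
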