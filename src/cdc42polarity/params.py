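"""Species, reactions and parameter tables for the polarity circuits.

The model describes the yeast mating-polarity machinery as point particles
on a periodic square membrane (2D) or on/inside a sphere (3D):

* **core** -- the Cdc42/Bem1-GEF positive-feedback circuit: inactive Cdc42
  exchanges between cytosol and membrane, Bem1-GEF activates membrane
  Cdc42-GDP, and active Cdc42 recruits further Bem1-GEF.
* **receptor_far1** -- constitutively active pheromone receptors recruit
  cytosolic Far1-GEF which activates Cdc42; active Cdc42 in turn delivers
  receptors to the membrane (actin cables abstracted as a bimolecular
  recruitment reaction), forming a second, slower positive feedback.
* **combined** -- the union of the two circuits.
* **combined_pheromone** -- 3D variant in which receptors are activated by
  explicit pheromone binding instead of constitutively.

All rate constants are read from the YAML tables shipped with the package
(`tables/*.yaml`), which are the single source of truth; circuits are
assembled from them, never hard-coded.  First-order rates ``k`` are in
s^-1 (or um s^-1 for 3D surface association); second-order probability
rates ``lambda`` apply within the reactive radius ``rho`` = 0.05 um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

N_AVOGADRO = 6.02214076e23  # mol^-1

CIRCUITS = ("core", "receptor_far1", "combined", "combined_pheromone")

#: 2D side length of the periodic square, um (sqrt of the membrane area).
L_DEFAULT = 8.8623
#: 3D cell radius, um.
R_DEFAULT = 2.5


class UnknownCircuitError(ValueError):
    pass


@dataclass(frozen=True)
class Geometry:
    """Simulation domain: periodic square membrane or spherical cell.

    ``A_m`` is the membrane area; for the sphere, ``V_c`` is the cytosolic
    volume and ``R_absorb`` the radius of the absorbing shell used in
    pheromone runs (must exceed ``R``).
    """

    mode: str  # "plane2d" | "sphere3d"
    L: float | None = None
    R: float | None = None
    R_absorb: float | None = None

    def __post_init__(self):
        if self.mode not in ("plane2d", "sphere3d"):
            raise ValueError(f"unknown geometry mode {self.mode!r}")
        if self.mode == "plane2d" and (self.L is None or self.L <= 0):
            raise ValueError("plane2d geometry requires L > 0")
        if self.mode == "sphere3d":
            if self.R is None or self.R <= 0:
                raise ValueError("sphere3d geometry requires R > 0")
            if self.R_absorb is not None and self.R_absorb <= self.R:
                raise ValueError("absorbing shell must lie outside the cell")

    @classmethod
    def plane(cls, L: float = L_DEFAULT) -> "Geometry":
        return cls(mode="plane2d", L=L)

    @classmethod
    def sphere(cls, R: float = R_DEFAULT, R_absorb: float | None = None) -> "Geometry":
        return cls(mode="sphere3d", R=R, R_absorb=R_absorb)

    @property
    def A_m(self) -> float:
        """Membrane area, um^2 (L^2 on the plane, 4*pi*R^2 on the sphere)."""
        if self.mode == "plane2d":
            return self.L * self.L
        return 4.0 * math.pi * self.R * self.R

    @property
    def V_c(self) -> float:
        """Cytosolic volume, um^3 (sphere only)."""
        if self.mode != "sphere3d":
            raise ValueError("V_c is defined only for sphere3d geometry")
        return 4.0 / 3.0 * math.pi * self.R**3

    @property
    def dim(self) -> int:
        return 2 if self.mode == "plane2d" else 3


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    compartment: str  # "cytosol" | "membrane" | "extracellular"
    D: float  # um^2 s^-1
    mobile: bool = True


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction channel.

    ``kind`` is ``first_order``, ``second_order`` or ``surface_association``
    (the 3D cytosol-to-membrane association whose rate is in um s^-1).
    ``anchor`` names the reactant whose position a binding product inherits;
    catalytic reactions list the catalyst among both reactants and products.
    """

    symbol: str
    kind: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate: float
    unit: str
    rho: float | None = None
    anchor: str | None = None

    def __post_init__(self):
        if self.kind == "second_order":
            if len(self.reactants) != 2:
                raise ValueError(f"{self.symbol}: second-order needs 2 reactants")
            if self.rho is None or self.rho <= 0:
                raise ValueError(f"{self.symbol}: second-order needs rho > 0")
        elif len(self.reactants) != 1:
            raise ValueError(f"{self.symbol}: first-order needs 1 reactant")


@dataclass
class ParameterSet:
    """Fully assembled model: geometry, species, reactions, abundances."""

    circuit: str
    geometry: Geometry
    species: dict[str, SpeciesSpec]
    reactions: list[ReactionSpec]
    abundances: dict[str, int]
    conservation_groups: dict[str, tuple[str, ...]]
    dt: float = 1.0e-4
    rho: float = 0.05

    def with_updates(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    def rate(self, symbol: str) -> float:
        for r in self.reactions:
            if r.symbol == symbol:
                return r.rate
        raise KeyError(symbol)

    def scale_rates(self, mapping: dict[str, float]) -> "ParameterSet":
        """Return a copy with the rates of the given symbols multiplied."""
        new = [
            replace(r, rate=r.rate * mapping[r.symbol]) if r.symbol in mapping else r
            for r in self.reactions
        ]
        return replace(self, reactions=new)


# ---------------------------------------------------------------------------
# table loading

def _load_table(name: str) -> dict:
    with resources.files("cdc42polarity.tables").joinpath(f"{name}.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_tables() -> dict[str, dict]:
    """Raw contents of the three shipped parameter tables."""
    return {n: _load_table(n) for n in ("core", "receptor_far1", "pheromone")}


def _species_from_table(tab: dict) -> dict[str, SpeciesSpec]:
    out = {}
    for name, row in tab.get("species", {}).items():
        out[name] = SpeciesSpec(name=name, compartment=row["compartment"], D=row["D"])
    return out


def _reactions_from_table(tab: dict, geometry_mode: str, rho: float) -> list[ReactionSpec]:
    out = []
    for row in tab["reactions"]:
        if geometry_mode == "plane2d":
            if "rate_2d" not in row:
                continue
            rate, unit, kind = row["rate_2d"], row["unit_2d"], row["kind"]
        else:
            if "rate_3d" not in row:
                continue
            rate, unit = row["rate_3d"], row["unit_3d"]
            kind = row.get("kind_3d", row["kind"])
        out.append(
            ReactionSpec(
                symbol=row["symbol"],
                kind=kind,
                reactants=tuple(row["reactants"]),
                products=tuple(row["products"]),
                rate=float(rate),
                unit=unit,
                rho=rho if row["kind"] == "second_order" else None,
                anchor=row.get("anchor"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# conversions (validation of the printed 3D columns, and unit helpers)

def convert_rate_first_order_to_3d(k2d: float, geometry: Geometry) -> float:
    """2D -> 3D rate for cytosol-to-membrane association: (V_c/A_m) * k2d.

    The result is a surface-association rate in um s^-1.  First-order rates
    between membrane states (or membrane to cytosol) are geometry-independent
    and pass through unchanged; only association picks up the volume factor.
    """
    if geometry.mode != "sphere3d":
        raise ValueError("3D conversion requires sphere3d geometry")
    return geometry.V_c / geometry.A_m * k2d


def convert_rate_second_order_to_3d(lambda2d: float, rho: float, geometry: Geometry) -> float:
    """2D -> 3D probability rate for a cytosol/membrane reactant pair.

    lambda3d = (V_c/A_m) * V2D/V3D * lambda2d with V2D = pi*rho^2 and
    V3D = (1/2)(4/3)pi*rho^3 -- the reaction volume is a half-sphere because
    one reactant is confined to the membrane.
    """
    if geometry.mode != "sphere3d":
        raise ValueError("3D conversion requires sphere3d geometry")
    if rho <= 0:
        raise ValueError("rho must be positive")
    v2d = math.pi * rho**2
    v3d = 0.5 * (4.0 / 3.0) * math.pi * rho**3
    return geometry.V_c / geometry.A_m * v2d / v3d * lambda2d


def molecules_to_concentration(n: int, geometry: Geometry) -> float:
    """Copy number in the cytosolic volume expressed in nM."""
    if n < 0:
        raise ValueError("molecule count must be non-negative")
    v_litres = geometry.V_c * 1e-15
    return n / (N_AVOGADRO * v_litres) * 1e9


def concentration_to_molecules(c_nM: float, volume_um3: float) -> float:
    """Expected molecule count for a concentration (nM) in a volume (um^3)."""
    return c_nM * 1e-9 * N_AVOGADRO * volume_um3 * 1e-15


# ---------------------------------------------------------------------------
# circuit assembly

_ABUNDANCE_KEYS = ("Cdc42", "Bem1GEF", "Far1GEF", "Receptor")

#: Reactions of the core table that survive when Bem1-GEF is absent
#: (the receptor-Far1 circuit keeps Cdc42's intrinsic cycling only).
_CDC42_ONLY = ("k_2b", "k_5a", "k_5b")


def build_circuit(
    circuit: str,
    geometry_mode: str = "plane2d",
    abundances: dict[str, int] | None = None,
    *,
    geometry: Geometry | None = None,
    with_fixed_far1_seeds: bool = False,
) -> ParameterSet:
    """Assemble a :class:`ParameterSet` for one circuit variant.

    ``abundances`` maps conservation-group names (``Cdc42``, ``Bem1GEF``,
    ``Far1GEF``, ``Receptor``) to total copy numbers; missing keys fall back
    to the table defaults.  ``with_fixed_far1_seeds`` adds an immobile
    membrane Far1-GEF species that activates Cdc42 directly (no receptors),
    used in the fixed-seed competition experiments.
    """
    if circuit not in CIRCUITS:
        raise UnknownCircuitError(f"unknown circuit {circuit!r}; choose from {CIRCUITS}")
    if circuit == "combined_pheromone" and geometry_mode != "sphere3d":
        raise ValueError("combined_pheromone is defined in sphere3d geometry only")
    tables = load_tables()
    core, rf, ph = tables["core"], tables["receptor_far1"], tables["pheromone"]

    consts = core["constants"]
    rho = consts["rho"]["value"]
    dt = consts["dt"]["value"]
    if geometry is None:
        if geometry_mode == "plane2d":
            geometry = Geometry.plane(consts["L"]["value"])
        else:
            r_abs = ph["constants"]["R_absorb"]["value"] if circuit == "combined_pheromone" else None
            geometry = Geometry.sphere(consts["R"]["value"], R_absorb=r_abs)
    if geometry.mode != geometry_mode:
        raise ValueError("geometry does not match geometry_mode")

    species = dict(_species_from_table(core))
    reactions = _reactions_from_table(core, geometry_mode, rho)
    groups: dict[str, tuple[str, ...]] = {
        k: tuple(v) for k, v in core["conservation_groups"].items()
    }
    defaults = dict(core["default_abundances"])

    if circuit == "receptor_far1":
        reactions = [r for r in reactions if r.symbol in _CDC42_ONLY]
        groups["Bem1GEF"] = tuple()

    if circuit in ("receptor_far1", "combined", "combined_pheromone"):
        species.update(_species_from_table(rf))
        rf_rx = _reactions_from_table(rf, geometry_mode, rho)
        if circuit == "combined_pheromone":
            # pheromone binding replaces constitutive activation: drop the
            # delivery (lambda_9) and endocytosis (k_10) channels of the
            # constitutive pathway in favour of the binding scheme.
            rf_rx = [r for r in rf_rx if r.symbol in ("lambda_8a", "k_8b", "lambda_2c")]
        reactions += rf_rx
        groups.update({k: tuple(v) for k, v in rf["conservation_groups"].items()})
        defaults.update(rf["default_abundances"])

    if circuit == "combined_pheromone":
        species.update(_species_from_table(ph))
        reactions += _reactions_from_table(ph, geometry_mode, rho)
        groups.update({k: tuple(v) for k, v in ph["conservation_groups"].items()})

    if with_fixed_far1_seeds:
        species["Far1GEF_f"] = SpeciesSpec("Far1GEF_f", "membrane", 0.0, mobile=False)
        reactions.append(
            ReactionSpec(
                symbol="lambda_2c",
                kind="second_order",
                reactants=("Far1GEF_f", "Cdc42D_m"),
                products=("Far1GEF_f", "Cdc42T"),
                rate=180.0,
                unit="s^-1",
                rho=rho,
            )
        )

    ab = {k: int(v) for k, v in defaults.items()}
    for k, v in (abundances or {}).items():
        if k not in _ABUNDANCE_KEYS:
            raise KeyError(f"unknown abundance group {k!r}")
        if int(v) < 0:
            raise ValueError(f"abundance {k} must be non-negative")
        ab[k] = int(v)
    for k in list(ab):
        if k not in groups or not groups[k]:
            ab.pop(k)

    return ParameterSet(
        circuit=circuit,
        geometry=geometry,
        species=species,
        reactions=reactions,
        abundances=ab,
        conservation_groups={k: v for k, v in groups.items() if v},
        dt=dt,
        rho=rho,
    )


def stoichiometry_balance(params: ParameterSet) -> dict[str, dict[str, int]]:
    """Net change of each conservation-group total per reaction (all zero)."""
    out: dict[str, dict[str, int]] = {}
    for gname, members in params.conservation_groups.items():
        mem = set(members)
        out[gname] = {}
        for i, r in enumerate(params.reactions):
            net = sum(1 for p in r.products if p in mem) - sum(
                1 for s in r.reactants if s in mem
            )
            out[gname][f"{i}:{r.symbol}"] = net
    return out
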