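"""Named, configured computational experiments and parameter scans.

An :class:`ExperimentConfig` fully determines a batch of replicate runs
(circuit, geometry, abundances, initial condition, pheromone protocol,
duration, seeds).  ``run_experiment`` executes it and returns per-replicate
K series plus a summary table; ``scan`` repeats an experiment across one
swept parameter.  A scale factor divides the duration and replicate count
for desk-scale runs -- never the time step or the reactive radius, which
would change the physics.  Scaled outputs are labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .engine import run
from .fixtures import DISPERSION_GRID, InitialCondition
from .params import ParameterSet, build_circuit
from .ripley import THRESHOLDS, fraction_time_polarized, time_to_threshold


@dataclass
class ExperimentConfig:
    name: str
    circuit: str = "core"
    geometry_mode: str = "plane2d"
    abundances: dict = field(default_factory=dict)
    init: InitialCondition = field(default_factory=InitialCondition)
    t_end: float = 4000.0
    n_replicates: int = 10
    record_interval: float = 10.0
    seed: int = 0
    scale: float = 1.0
    pheromone: object = None
    frozen: object = None
    with_fixed_far1_seeds: bool = False
    outdir: str | None = None

    @property
    def t_end_scaled(self) -> float:
        t = self.t_end / self.scale
        return max(self.record_interval, round(t / self.record_interval) * self.record_interval)

    @property
    def n_replicates_scaled(self) -> int:
        return max(1, int(round(self.n_replicates / self.scale)))

    def build_params(self) -> ParameterSet:
        return build_circuit(
            self.circuit,
            self.geometry_mode,
            self.abundances,
            with_fixed_far1_seeds=self.with_fixed_far1_seeds,
        )


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    times: np.ndarray
    k_runs: list  # per-replicate K arrays
    trajectories: list
    summary: pd.DataFrame


def run_experiment(
    config: ExperimentConfig,
    params: ParameterSet | None = None,
    keep_trajectories: bool = False,
    progress: bool = False,
) -> ExperimentResult:
    """Run all replicates of one experiment and summarize polarity."""
    params = params or config.build_params()
    pol_thr, stable_thr = THRESHOLDS[config.geometry_mode]
    t_end = config.t_end_scaled
    k_runs, trajs, rows = [], [], []
    for rep in range(config.n_replicates_scaled):
        seed = config.seed + 1000 * rep
        traj = run(
            params,
            init=config.init,
            t_end=t_end,
            seed=seed,
            record_interval=config.record_interval,
            pheromone=config.pheromone,
            frozen=config.frozen,
            progress=progress,
        )
        times, ks = traj.k_series()
        k_runs.append(ks)
        if keep_trajectories:
            trajs.append(traj)
        win = (t_end / 2.0, t_end)
        rows.append(
            {
                "replicate": rep,
                "seed": seed,
                "final_K": ks[-1],
                "max_K": ks.max(),
                "frac_polarized": fraction_time_polarized(times, ks, win, pol_thr),
                "t_polarized": time_to_threshold(times, ks, pol_thr),
                "t_stable": time_to_threshold(times, ks, stable_thr),
            }
        )
    summary = pd.DataFrame(rows)
    result = ExperimentResult(config, times, k_runs, trajs, summary)
    if config.outdir:
        _write_outputs(result, params)
    return result


def _write_outputs(result: ExperimentResult, params: ParameterSet):
    out = Path(result.config.outdir) / result.config.name
    out.mkdir(parents=True, exist_ok=True)
    for rep, ks in enumerate(result.k_runs):
        io.write_k_series(result.times, ks, result.config.geometry_mode,
                          out / f"k_series_rep{rep}.tsv")
    result.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    io.write_meta(
        {
            "config": result.config,
            "scaled_t_end": result.config.t_end_scaled,
            "scaled_replicates": result.config.n_replicates_scaled,
            "scaled": result.config.scale != 1.0,
            "circuit": params.circuit,
            "abundances": params.abundances,
        },
        out / "config.yaml",
    )


SCAN_PARAMETERS = (
    "bem1_abundance", "far1_abundance", "receptor_residence",
    "dispersion_sigma", "n_seeds",
)


def scan(config: ExperimentConfig, parameter: str, values) -> pd.DataFrame:
    """Sweep one parameter; per value report final-K statistics.

    ``receptor_residence`` (seconds) jointly scales receptor internalization
    (k_10) and delivery (lambda_9) by the same factor, which shortens the
    membrane residence time while holding the steady-state surface receptor
    number approximately fixed.
    """
    if parameter not in SCAN_PARAMETERS:
        raise ValueError(f"unsupported scan parameter {parameter!r}")
    rows = []
    for v in values:
        cfg = replace(config, name=f"{config.name}_{parameter}_{v}")
        params = None
        if parameter == "bem1_abundance":
            cfg = replace(cfg, abundances={**config.abundances, "Bem1GEF": int(v)})
        elif parameter == "far1_abundance":
            cfg = replace(cfg, abundances={**config.abundances, "Far1GEF": int(v)})
        elif parameter == "n_seeds":
            cfg = replace(cfg, with_fixed_far1_seeds=True,
                          init=replace(config.init, kind="fixed_far1_seeds", n_seeds=int(v)))
        elif parameter == "dispersion_sigma":
            if v is None or np.isinf(v):
                cfg = replace(cfg, init=InitialCondition(kind="uniform"))
            else:
                cfg = replace(cfg, init=InitialCondition(kind="dispersed_receptors", sigma=float(v)))
        elif parameter == "receptor_residence":
            params = cfg.build_params()
            factor = (1.0 / params.rate("k_10")) / float(v)
            params = params.scale_rates({"k_10": factor, "lambda_9": factor})
        res = run_experiment(cfg, params=params)
        rows.append(
            {
                "value": np.inf if v is None else v,
                "final_K_mean": res.summary["final_K"].mean(),
                "final_K_sd": res.summary["final_K"].std(ddof=0),
                "frac_polarized_mean": res.summary["frac_polarized"].mean(),
                "n": len(res.summary),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# named presets (the full study protocols; scale them down for desk runs)

def preset(name: str, seed: int = 0, scale: float = 1.0, outdir=None) -> ExperimentConfig:
    """Named experiment configurations.

    ``core_*``: core circuit at 3000 Cdc42 in the unpolarized (70 Bem1-GEF),
    transient (102) and polarized (120) regimes, uniform initial conditions.
    ``combined_*``: combined circuit at 3000/170/30/2500 with uniform,
    pre-polarized-Cdc42 and clustered-receptor initial conditions.
    ``calibration_*``: combined circuit in each geometry for the 2D/3D calibration.
    """
    registry = {
        "core_unpolarized": dict(circuit="core", abundances={"Cdc42": 3000, "Bem1GEF": 70}),
        "core_transient": dict(circuit="core", abundances={"Cdc42": 3000, "Bem1GEF": 102}),
        "core_polarized": dict(circuit="core", abundances={"Cdc42": 3000, "Bem1GEF": 120}),
        "combined_transient": dict(circuit="combined"),
        "combined_dissipate": dict(circuit="combined",
                               init=InitialCondition(kind="prepolarized_cdc42")),
        "combined_stabilize": dict(circuit="combined",
                               init=InitialCondition(kind="polarized_receptors")),
        "calibration_2d": dict(circuit="combined", t_end=4000.0),
        "calibration_3d": dict(circuit="combined", geometry_mode="sphere3d", t_end=4000.0),
    }
    if name not in registry:
        raise KeyError(f"unknown experiment {name!r}; known: {sorted(registry)}")
    kw = registry[name]
    return ExperimentConfig(name=name, seed=seed, scale=scale, outdir=outdir, **kw)


# ---------------------------------------------------------------------------
# gradient-stabilization protocol (desk-scale frozen-field variant)

def gradient_stabilization(
    frozen,
    n_replicates: int = 5,
    t_end: float = 100.0,
    seed: int = 0,
    threshold: float = 30.0,
    record_interval: float = 10.0,
):
    """Times to polarity-site formation under a frozen pheromone gradient.

    Runs the pheromone-binding combined circuit on the sphere with membrane
    receptors pre-activated at their local binding equilibrium (emulating a
    cell already exposed to the gradient), and reports, per replicate, the
    first time the polarity statistic K reaches ``threshold`` (None if it
    never does within ``t_end``) together with the angle between the
    active-Cdc42 centroid and the gradient axis at that moment (or at the
    end).  Replicates stop as soon as the threshold is crossed.
    """
    import numpy as np

    from .engine import Simulation, initial_state
    from .ripley import ripley_k

    params = build_circuit("combined_pheromone", "sphere3d")
    ax = np.asarray(frozen.axis, float)
    ax = ax / np.linalg.norm(ax)
    times_to, angles = [], []
    for rep in range(n_replicates):
        s = seed + 1000 * rep
        state = initial_state(params, seed=s, frozen=frozen,
                              preequilibrate_receptors=True)
        sim = Simulation(params, state, seed=s + 1, frozen=frozen)
        crossed = None
        n_chunks = int(round(t_end / record_interval))
        snap = None
        for _ in range(n_chunks):
            sim.run_for(record_interval)
            snap = sim.snapshot()
            act = snap.positions_of(("Cdc42T", "Cdc42T_Bem1GEF"))
            k = ripley_k(act, params.geometry).K if len(act) > 1 else 0.0
            if k >= threshold:
                crossed = sim.t
                break
        times_to.append(crossed)
        act = snap.positions_of(("Cdc42T", "Cdc42T_Bem1GEF")) if snap else []
        if len(act):
            c = act.mean(axis=0)
            nrm = np.linalg.norm(c)
            angles.append(float(np.degrees(np.arccos(np.clip(c @ ax / nrm, -1, 1))))
                          if nrm > 1e-9 else 90.0)
        else:
            angles.append(90.0)
    return times_to, angles
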