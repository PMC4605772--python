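"""Evolutionary generation of klinotaxis-competent circuit ensembles.

The electrophysiological parameters of the circuit (synaptic weights,
biases, gap conductances, time constant, sensory windows, drive weights)
are unknown; following the modelling tradition for this circuit they are
evolved with a genetic algorithm against closed-loop gradient-climbing
performance.  The genotype is a real vector in [-1, 1] mapped linearly to
documented parameter ranges; dorsal/ventral symmetry is enforced in the
encoding (dorsal and ventral motor-neuron parameters share genes) while
left/right parameters are free.  Selection is by tournament with elitism;
variation is uniform crossover plus Gaussian mutation.

Circuits whose chemotaxis index exceeds a success threshold across
independent seeded runs form the analysis ensemble.  A frozen set of such
circuits is packaged as fixtures for deterministic tests; ``"best"`` loads
the canonical high-performer used throughout the examples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path

import numpy as np

from . import _kernels
from .circuit import CircuitParams
from .environment import GradientField, Trajectory, chemotaxis_index

__all__ = [
    "EvolutionConfig",
    "EvolvedCircuit",
    "evolve_ensemble",
    "evaluate_fitness",
    "decode_genotype",
    "load_fixture",
    "list_fixtures",
    "save_ensemble",
]

# genotype layout: (gene name, parameter range key)
GENES = (
    ("w_ON_AIYL", "sensor_w"),
    ("w_ON_AIYR", "sensor_w"),
    ("w_OFF_AIYL", "sensor_w"),
    ("w_OFF_AIYR", "sensor_w"),
    ("w_AIYL_AIZL", "w"),
    ("w_AIYR_AIZR", "w"),
    ("w_AIZL_SMBL", "w"),
    ("w_AIZR_SMBR", "w"),
    ("w_SMBL_self", "w"),
    ("w_SMBR_self", "w"),
    ("g_AIY", "g"),
    ("g_AIZ", "g"),
    ("theta_AIYL", "theta"),
    ("theta_AIYR", "theta"),
    ("theta_AIZL", "theta"),
    ("theta_AIZR", "theta"),
    ("theta_SMBL", "theta"),
    ("theta_SMBR", "theta"),
    ("w_PG", "w_PG"),
    ("w_NMJ", "w_NMJ"),
    ("tau", "tau"),
    ("N", "NM"),
    ("M", "NM"),
)

DEFAULT_RANGES = {
    "sensor_w": (-500.0, 500.0),
    "w": (-15.0, 15.0),
    "g": (0.01, 2.5),
    "theta": (-15.0, 15.0),
    "w_PG": (-10.0, 10.0),
    "w_NMJ": (-3.0, 3.0),
    "tau": (0.1, 2.0),
    "NM": (1, 105),
}


@dataclass
class EvolutionConfig:
    """Settings of the genetic search (defaults are the study conditions)."""

    population: int = 40
    generations: int = 60
    n_runs: int = 12
    ranges: dict = dc_field(default_factory=lambda: dict(DEFAULT_RANGES))
    mutation_scale: float = 0.15
    crossover_rate: float = 0.5
    elitism: int = 2
    tournament: int = 3
    success_threshold: float = 0.75
    eval_duration: float = 400.0
    n_eval_poses: int = 3
    start_distance: float = 2.0
    arena_radius: float = 10.0
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for key, (lo, hi) in self.ranges.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid range for {key}")
        if self.ranges["g"][0] <= 0:
            raise ValueError("gap-conductance range must be strictly positive")
        if self.elitism < 0 or self.population < 2:
            raise ValueError("invalid population settings")


@dataclass
class EvolvedCircuit:
    params: CircuitParams
    fitness: float
    run_seed: int
    history: np.ndarray  # best fitness per generation (incl. generation 0)


def _scale(gene: float, lo: float, hi: float) -> float:
    return lo + (gene + 1.0) * 0.5 * (hi - lo)


def decode_genotype(genotype: np.ndarray, ranges: dict | None = None) -> CircuitParams:
    """Map a [-1, 1] genotype to a dorsal/ventral-symmetric CircuitParams."""
    ranges = dict(DEFAULT_RANGES) if ranges is None else ranges
    vals = {}
    for gene, (name, key) in zip(genotype, GENES):
        lo, hi = ranges[key]
        vals[name] = _scale(float(np.clip(gene, -1.0, 1.0)), lo, hi)
    n_lo, n_hi = ranges["NM"]
    N = int(round(np.clip(vals["N"], n_lo, n_hi)))
    M = int(round(np.clip(vals["M"], n_lo, n_hi)))
    return CircuitParams(
        N=max(N, 1),
        M=max(M, 1),
        tau=vals["tau"],
        w_ON_AIYL=vals["w_ON_AIYL"],
        w_ON_AIYR=vals["w_ON_AIYR"],
        w_OFF_AIYL=vals["w_OFF_AIYL"],
        w_OFF_AIYR=vals["w_OFF_AIYR"],
        w_AIYL_AIZL=vals["w_AIYL_AIZL"],
        w_AIYR_AIZR=vals["w_AIYR_AIZR"],
        w_AIZL_SMBDL=vals["w_AIZL_SMBL"],
        w_AIZL_SMBVL=vals["w_AIZL_SMBL"],
        w_AIZR_SMBDR=vals["w_AIZR_SMBR"],
        w_AIZR_SMBVR=vals["w_AIZR_SMBR"],
        w_SMBDL_self=vals["w_SMBL_self"],
        w_SMBVL_self=vals["w_SMBL_self"],
        w_SMBDR_self=vals["w_SMBR_self"],
        w_SMBVR_self=vals["w_SMBR_self"],
        g_AIY=vals["g_AIY"],
        g_AIZ=vals["g_AIZ"],
        theta_AIYL=vals["theta_AIYL"],
        theta_AIYR=vals["theta_AIYR"],
        theta_AIZL=vals["theta_AIZL"],
        theta_AIZR=vals["theta_AIZR"],
        theta_SMBDL=vals["theta_SMBL"],
        theta_SMBVL=vals["theta_SMBL"],
        theta_SMBDR=vals["theta_SMBR"],
        theta_SMBVR=vals["theta_SMBR"],
        w_PG=vals["w_PG"],
        w_NMJ=vals["w_NMJ"],
        dv_symmetric=True,
    )


def evaluate_fitness(
    params: CircuitParams,
    fld: GradientField,
    duration: float = 400.0,
    n_poses: int = 3,
    start_distance: float = 2.0,
    arena_radius: float = 10.0,
    dt: float = 0.01,
) -> float:
    """Mean chemotaxis index over a set of deterministic start poses.

    Poses are evenly spaced around the peak at ``start_distance``, headed
    tangentially, so the worm must actively steer inward.
    """
    px, py = fld.peak_position
    pv = _kernels.pack_params(params)
    n_steps = int(round(duration / dt))
    total = 0.0
    for i in range(n_poses):
        psi = 2.0 * math.pi * i / n_poses
        x0 = px + start_distance * math.cos(psi)
        y0 = py + start_distance * math.sin(psi)
        bearing = psi + math.pi / 2.0
        xs, ys, cs, ds, phis, n_done = _kernels.run_closed_loop_kernel(
            pv, params.N, params.M, dt, n_steps, x0, y0, bearing,
            px, py, fld.peak_concentration, fld.scale, fld._kind_code,
            arena_radius, False, False,
        )
        traj = Trajectory(
            t=np.arange(n_done) * dt,
            x=xs[:n_done], y=ys[:n_done], c=cs[:n_done], d=ds[:n_done],
            phi=phis[:n_done], dt=dt, truncated=n_done < n_steps,
        )
        total += chemotaxis_index(traj, fld)
    return total / n_poses


def _run_ga(
    cfg: EvolutionConfig, fld: GradientField, run_seed: int
) -> EvolvedCircuit:
    rng = np.random.default_rng(run_seed)
    n_genes = len(GENES)
    pop = rng.uniform(-1.0, 1.0, (cfg.population, n_genes))

    def fit(genotype: np.ndarray) -> float:
        return evaluate_fitness(
            decode_genotype(genotype, cfg.ranges),
            fld,
            duration=cfg.eval_duration,
            n_poses=cfg.n_eval_poses,
            start_distance=cfg.start_distance,
            arena_radius=cfg.arena_radius,
            dt=cfg.dt,
        )

    fits = np.array([fit(g) for g in pop])
    history = [float(fits.max())]
    for _ in range(cfg.generations):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(new_pop) < cfg.population:
            idx_a = max(rng.integers(cfg.population, size=cfg.tournament), key=lambda i: fits[i])
            idx_b = max(rng.integers(cfg.population, size=cfg.tournament), key=lambda i: fits[i])
            child = pop[idx_a].copy()
            mask = rng.random(n_genes) < cfg.crossover_rate
            child[mask] = pop[idx_b, mask]
            child += rng.normal(0.0, cfg.mutation_scale, n_genes)
            np.clip(child, -1.0, 1.0, out=child)
            new_pop.append(child)
        pop = np.asarray(new_pop)
        fits = np.concatenate(
            [fits[order[: cfg.elitism]], [fit(g) for g in pop[cfg.elitism:]]]
        )
        history.append(float(fits.max()))
    best = int(np.argmax(fits))
    return EvolvedCircuit(
        params=decode_genotype(pop[best], cfg.ranges),
        fitness=float(fits[best]),
        run_seed=run_seed,
        history=np.asarray(history),
    )


def evolve_ensemble(
    cfg: EvolutionConfig, fld: GradientField | None = None
) -> list[EvolvedCircuit]:
    """Run independent seeded searches; return the successful circuits.

    Each of ``cfg.n_runs`` searches is seeded with ``cfg.seed + i`` and
    contributes its best individual if it exceeds
    ``cfg.success_threshold``.  Deterministic given the config.  Returns an
    empty list (with a warning) if no run succeeds.
    """
    fld = GradientField() if fld is None else fld
    out = []
    for i in range(cfg.n_runs):
        result = _run_ga(cfg, fld, cfg.seed + i)
        if result.fitness >= cfg.success_threshold:
            out.append(result)
    if not out:
        warnings.warn("no circuit exceeded the success threshold", stacklevel=2)
    return out


def save_ensemble(ensemble: list[EvolvedCircuit], directory: str | Path) -> None:
    """One parameter file per circuit plus a manifest table."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ec in enumerate(ensemble):
        name = f"circuit_{i:03d}"
        ec.params.to_file(directory / f"{name}.params")
        rows.append({"circuit": name, "seed": ec.run_seed, "fitness": ec.fitness})
    pd.DataFrame(rows).to_csv(directory / "manifest.tsv", sep="\t", index=False)


# ---------------------------- fixtures -------------------------------- #


def _fixture_dir():
    return resources.files("klinfo") / "fixtures"


def list_fixtures() -> list[str]:
    return sorted(
        p.name[: -len(".params")]
        for p in _fixture_dir().iterdir()
        if p.name.endswith(".params")
    )


def load_fixture(name: str = "best") -> CircuitParams:
    """Load a packaged, version-frozen klinotaxis-competent circuit."""
    path = _fixture_dir() / f"{name}.params"
    if not path.is_file():
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(list_fixtures())}"
        )
    return CircuitParams.from_text(path.read_text())
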