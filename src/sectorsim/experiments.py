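"""Simulation main loop and the headline experiment drivers.

One iteration follows the quasi-steady-state scheme: sample the local
solute microenvironment of every cell, grow and divide agents (Euler step
bounded by ``dt_frac``), shove overlaps apart (this is what advances the
front), then re-solve the substrate and enzyme fields to steady state
under the updated biomass and boundary layer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import io as sio
from .agents import (
    CellGroup, divide_cells, front_height, grow_cells, init_cluster,
    init_monolayer, relax_overlaps,
)
from .kinetics import StrainPhenotype, specific_growth_rate
from .metrics import (
    SegregationParams, front_roughness, metabolic_activity,
    relative_fitness, segregation_index, strain_fitness,
)
from .parameters import ParameterSet, delta_number
from .solute import (
    BiomassField, ConstantSource, Grid2D, MichaelisMentenSink, SoluteField,
    compute_bulk_mask, rasterize_biomass, sample_concentration,
    solve_reaction_diffusion,
)

__all__ = [
    "ScenarioConfig", "SimState", "Trajectory",
    "initialize", "step", "run_simulation",
    "run_segregation_sweep", "run_competition", "summarize",
]

ACTIVITY_FLOOR = 0.01


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to reproduce a run: physics, strains, numerics."""

    params: ParameterSet = field(default_factory=ParameterSet)
    strains: tuple[StrainPhenotype, ...] = (StrainPhenotype("wild"),)
    color_fractions: dict = field(default_factory=lambda: {"RED": 0.5, "BLUE": 0.5})
    color_strain: dict = field(default_factory=lambda: {"RED": "wild", "BLUE": "wild"})
    n_cells: int = 40
    max_iterations: int = 6000
    snapshot_every: int = 0  # iterations between stored snapshots; 0 = final only
    relax_tol: float = 0.05
    solver_tol: float = 1e-6
    focal_color: Optional[str] = None

    def __post_init__(self) -> None:
        if abs(sum(self.color_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("color fractions must sum to 1")
        names = {s.name for s in self.strains}
        if set(self.color_strain) != set(self.color_fractions):
            raise ValueError("color_strain must map exactly the seeded colors")
        if not set(self.color_strain.values()) <= names:
            raise ValueError("color_strain refers to an unknown strain")

    @property
    def strain_names(self) -> list[str]:
        return [s.name for s in self.strains]

    def resolved_strains(self) -> tuple[StrainPhenotype, ...]:
        """Strains with physiology (mu_max, K_G, Y) taken from the run's
        ParameterSet; strains differ only in their social traits."""
        p = self.params
        return tuple(
            replace(s, mu_max=p.mu_max, K_G=p.K_G, Y=p.Y) for s in self.strains
        )

    def segregation_params(self) -> SegregationParams:
        # "10 cell lengths" with one cell length = the division diameter
        return SegregationParams(radius=10 * 2 * self.params.r_div,
                                 epsilon=ACTIVITY_FLOOR)

    def digest(self) -> str:
        blob = repr(dataclasses.asdict(self)).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SimState:
    cells: CellGroup
    grid: Grid2D
    substrate: SoluteField
    enzyme: Optional[SoluteField]
    biomass_field: BiomassField
    config: ScenarioConfig
    strains: tuple[StrainPhenotype, ...]
    rng: np.random.Generator
    time: float = 0.0
    iteration: int = 0
    substrate_consumed: float = 0.0  # per-cell uptake ledger [fg]
    substrate_consumed_field: float = 0.0  # node sink integral route [fg]
    sink_rate_field: float = 0.0  # current field-route consumption [fg/h]

    @property
    def has_enzyme(self) -> bool:
        return self.enzyme is not None


@dataclass
class Trajectory:
    snapshots: list  # [(time_h, DataFrame)]
    metrics: pd.DataFrame
    summary: dict


def _make_grid(params: ParameterSet) -> Grid2D:
    nx = int(round(params.width / params.spacing))
    ny = int(round(params.height / params.spacing))
    if abs(nx * params.spacing - params.width) > 1e-9:
        raise ValueError("width must be an integer multiple of spacing")
    return Grid2D(nx, ny, params.spacing, periodic_x=params.periodic_x)


def _solve_fields(state: SimState) -> None:
    """Steps 3-4: recompute the boundary layer, then both solute fields."""
    p = state.config.params
    state.biomass_field = rasterize_biomass(
        state.cells, state.grid, len(state.strains), p.slice_thickness
    )
    mask = compute_bulk_mask(state.biomass_field, p.h, p.condition, state.grid)

    # Substrate: Monod sink, with each strain's social growth multiplier
    # evaluated against the current enzyme field (quasi-steady lag of one
    # iteration in the benefit factor).
    kmax = np.zeros(state.grid.shape)
    for s_idx, strain in enumerate(state.strains):
        X = state.biomass_field.per_strain[s_idx]
        ben = strain.benefit_factor(state.enzyme.values) if state.enzyme else 1.0
        kmax += strain.mu_max * strain.cost_multiplier * ben * X / strain.Y
    state.substrate = solve_reaction_diffusion(
        SoluteField("SUBSTRATE", state.substrate.values, p.G_bulk, mask),
        MichaelisMentenSink(kmax, p.K_G),
        state.grid, p.D_G, tol=state.config.solver_tol,
    )
    node_vol = p.spacing**2 * p.slice_thickness
    G = state.substrate.values
    state.sink_rate_field = float(
        (kmax * G / (p.K_G + G))[~mask].sum() * node_vol
    )

    if state.enzyme is not None:
        # secretion scales with local metabolic activity (Monod factor of
        # the freshly solved substrate field): starved biomass is silent
        activity = G / (p.K_G + G)
        source = np.zeros(state.grid.shape)
        for s_idx, strain in enumerate(state.strains):
            if strain.cooperator:
                source += strain.R_E * activity * state.biomass_field.per_strain[s_idx]
        state.enzyme = solve_reaction_diffusion(
            SoluteField("ENZYME", state.enzyme.values, 0.0, mask),
            ConstantSource(source),
            state.grid, p.D_E, tol=state.config.solver_tol,
        )


def initialize(config: ScenarioConfig, seed: int) -> SimState:
    """Seed the monolayer and solve the initial solute fields."""
    p = config.params
    strains = config.resolved_strains()
    name_to_idx = {s.name: i for i, s in enumerate(strains)}
    strain_map = {c: name_to_idx[s] for c, s in config.color_strain.items()}
    rng = np.random.default_rng(seed)
    if p.condition == "SURFACE":
        cells = init_monolayer(
            config.n_cells, config.color_fractions, strain_map, p.width,
            rng, rho_area=p.rho_area, r_div=p.r_div,
        )
    else:  # RADIAL: immersed cluster at the domain center
        cells = init_cluster(
            config.n_cells, config.color_fractions, strain_map,
            (p.width / 2, p.height / 2), rng,
            rho_area=p.rho_area, r_div=p.r_div,
        )
    grid = _make_grid(p)
    any_secretion = any(s.cooperator and s.R_E > 0 for s in strains)
    state = SimState(
        cells=cells,
        grid=grid,
        substrate=SoluteField(
            "SUBSTRATE", np.full(grid.shape, p.G_bulk), p.G_bulk,
            np.ones(grid.shape, bool),
        ),
        enzyme=SoluteField(
            "ENZYME", np.zeros(grid.shape), 0.0, np.ones(grid.shape, bool)
        ) if any_secretion else None,
        biomass_field=BiomassField(np.zeros((len(strains), *grid.shape))),
        config=config,
        strains=strains,
        rng=rng,
    )
    _solve_fields(state)
    return state


def step(state: SimState) -> float:
    """One full iteration; returns the time step taken [h]."""
    cfg = state.config
    p = cfg.params
    cells = state.cells

    G = sample_concentration(state.substrate, state.grid, cells.x, cells.y)
    if state.enzyme is not None:
        E = sample_concentration(state.enzyme, state.grid, cells.x, cells.y)
    else:
        E = np.zeros(cells.n)

    mu = np.zeros(cells.n)
    for s_idx, strain in enumerate(state.strains):
        mask = cells.strain == s_idx
        if mask.any():
            mu[mask] = specific_growth_rate(strain, G[mask], E[mask])
    mu_top = float(mu.max()) if cells.n else 0.0
    dt = p.dt_max if mu_top <= 0 else min(p.dt_frac / mu_top, p.dt_max)

    grow_cells(cells, mu, dt)
    cells.active = metabolic_activity(G, p.K_G) >= ACTIVITY_FLOOR
    state.substrate_consumed += float((mu * cells.biomass / (1.0 + mu * dt)).sum()) * dt / p.Y
    state.substrate_consumed_field += state.sink_rate_field * dt

    divide_cells(cells, p.r_div, state.rng)
    if p.condition == "SURFACE":
        _advect_vertically(cells, dt, p.width)
    relax_overlaps(
        cells, tol=cfg.relax_tol, max_iters=2000, rng=state.rng,
        width=p.width, periodic_x=p.periodic_x,
        has_floor=(p.condition == "SURFACE"),
    )
    _solve_fields(state)
    state.time += dt
    state.iteration += 1
    return dt


def _advect_vertically(cells: CellGroup, dt: float, width: float) -> None:
    """Continuity-based vertical pre-displacement before shoving.

    Newly grown area must push everything above it upward; by 2-D mass
    conservation the laterally averaged upward displacement at height y is
    the area produced below y this step, divided by the domain width.
    Applying that mean advection first leaves the shoving sweeps only the
    local, lateral part of the rearrangement, which converges in a few
    sweeps with the physical (beta = 1) half-overlap rule. The advection
    is laterally uniform, so it cannot bias front morphology.
    """
    order = np.argsort(cells.y, kind="stable")
    mu_dt = cells.growth_rate[order] * dt
    area_added = (cells.biomass[order] / cells.rho_area) * mu_dt / (1.0 + mu_dt)
    lift = np.cumsum(area_added) / width
    cells.y[order] += lift - 0.5 * area_added / width  # exclude half of own growth


def _record_metrics(state: SimState) -> dict:
    cells = state.cells
    fr = front_roughness(cells, bin_width=2 * state.config.params.r_div,
                         width=state.config.params.width
                         if state.config.params.periodic_x else None)
    row = {
        "time_h": state.time,
        "iteration": state.iteration,
        "n_cells": cells.n,
        "front_height_um": front_height(cells),
        "total_biomass_fg": cells.total_biomass,
        "front_roughness_um": fr.roughness,
        "front_gaps": fr.gap_count,
    }
    for k, name in enumerate(state.config.strain_names):
        row[f"n_{name}"] = int((cells.strain == k).sum())
    for k, name in enumerate(cells.color_names):
        row[f"n_color_{name}"] = int((cells.color == k).sum())
    return row


def run_simulation(config: ScenarioConfig, seed: int) -> Trajectory:
    """Iterate to the stopping height (or the iteration cap) and analyse.

    The returned summary holds per-strain counts and fitness (rounds of
    division per hour), the final segregation index, δ, front statistics,
    the substrate mass balance, and provenance (config digest, seed).
    """
    state = initialize(config, seed)
    p = config.params
    strain_names = config.strain_names
    n_start = {
        name: int((state.cells.strain == k).sum())
        for k, name in enumerate(strain_names)
    }
    biomass_start = state.cells.total_biomass

    snapshots: list = []
    records = [_record_metrics(state)]
    stalled = False
    while front_height(state.cells) < p.max_front_height:
        if state.iteration >= config.max_iterations:
            stalled = True
            break
        step(state)
        if config.snapshot_every and state.iteration % config.snapshot_every == 0:
            snapshots.append(
                (state.time, sio.cells_to_frame(state.cells, state.time, strain_names))
            )
            records.append(_record_metrics(state))
    records.append(_record_metrics(state))
    snapshots.append(
        (state.time, sio.cells_to_frame(state.cells, state.time, strain_names))
    )

    cells = state.cells
    G_cells = sample_concentration(state.substrate, state.grid, cells.x, cells.y)
    seg_params = config.segregation_params()
    try:
        seg = segregation_index(
            cells, G_cells, p.K_G, seg_params, config.focal_color,
            width=p.width if p.periodic_x else None,
        )
    except ValueError:
        seg = float("nan")
    fr = front_roughness(cells, bin_width=2 * p.r_div,
                         width=p.width if p.periodic_x else None)

    duration = state.time
    fitness = {}
    for k, name in enumerate(strain_names):
        n_end = int((cells.strain == k).sum())
        fitness[name] = (
            strain_fitness(n_start[name], n_end, duration)
            if duration > 0 and n_start[name] >= 1 else float("nan")
        )
    produced = cells.total_biomass - biomass_start
    summary = {
        "seed": int(seed),
        "config_digest": config.digest(),
        "delta": delta_number(p),
        "duration_h": duration,
        "iterations": state.iteration,
        "stalled": stalled,
        "n_cells_final": cells.n,
        "front_height_um": front_height(cells),
        "front_roughness_um": fr.roughness,
        "front_gaps": fr.gap_count,
        "segregation_index": seg,
        "n_start": n_start,
        "n_end": {name: int((cells.strain == k).sum())
                  for k, name in enumerate(strain_names)},
        "fitness_per_h": fitness,
        "biomass_produced_fg": produced,
        "substrate_consumed_fg": state.substrate_consumed,
        "substrate_consumed_field_fg": state.substrate_consumed_field,
        "yield_check": produced / state.substrate_consumed / p.Y
        if state.substrate_consumed > 0 else float("nan"),
    }
    metrics = pd.DataFrame.from_records(records)
    return Trajectory(snapshots=snapshots, metrics=metrics, summary=summary)


def _spawn_seeds(base_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_segregation_sweep(
    config: ScenarioConfig,
    deltas: Sequence[float],
    vary: str = "G_bulk",
    replicates: int = 10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Grow replicate groups at each δ; tabulate the final segregation index.

    Exactly one constituent of δ (``vary``) is rescaled per condition.
    Returns one row per (δ, replicate) with the segregation index, front
    statistics and run diagnostics.
    """
    seeds = _spawn_seeds(base_seed, len(deltas) * replicates)
    rows = []
    for d_idx, delta in enumerate(deltas):
        cfg = replace(config, params=config.params.with_delta(delta, vary))
        for rep in range(replicates):
            seed = seeds[d_idx * replicates + rep]
            traj = run_simulation(cfg, seed)
            s = traj.summary
            rows.append({
                "delta": s["delta"], "vary": vary, "replicate": rep,
                "seed": seed, "segregation_index": s["segregation_index"],
                "front_roughness_um": s["front_roughness_um"],
                "front_gaps": s["front_gaps"], "n_cells": s["n_cells_final"],
                "duration_h": s["duration_h"], "stalled": s["stalled"],
                "yield_check": s["yield_check"],
            })
    return pd.DataFrame.from_records(rows)


def run_competition(
    config: ScenarioConfig,
    R_E_grid: Sequence[float],
    deltas: Sequence[float],
    replicates: int = 10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """1:1 cooperator-vs-exploiter competitions across R_E and δ.

    The cooperative strain's enzyme production rate is swept over
    ``R_E_grid``; each (δ, R_E) cell is replicated. Rows carry each
    strain's fitness and the cooperator's relative fitness.
    """
    coop = [s for s in config.strains if s.cooperator]
    expl = [s for s in config.strains if not s.cooperator]
    if len(coop) != 1 or len(expl) != 1:
        raise ValueError("competition needs exactly one cooperator and one exploiter")
    for frac in config.color_fractions.values():
        if frac <= 0:
            raise ValueError("both strains must be seeded (nonzero fractions)")
    seeds = _spawn_seeds(base_seed, len(deltas) * len(R_E_grid) * replicates)
    rows = []
    k = 0
    for delta in deltas:
        params = config.params.with_delta(delta, "G_bulk")
        for R_E in R_E_grid:
            new_coop = replace(coop[0], R_E=float(R_E))
            strains = tuple(new_coop if s.cooperator else s for s in config.strains)
            cfg = replace(config, params=params, strains=strains)
            for rep in range(replicates):
                seed = seeds[k]
                k += 1
                traj = run_simulation(cfg, seed)
                s = traj.summary
                W1 = s["fitness_per_h"][coop[0].name]
                W2 = s["fitness_per_h"][expl[0].name]
                rows.append({
                    "delta": delta, "R_E": float(R_E), "replicate": rep,
                    "seed": seed, "W_cooperator": W1, "W_exploiter": W2,
                    "relative_fitness": relative_fitness(W1, W2)
                    if W2 > 0 else float("nan"),
                    "segregation_index": s["segregation_index"],
                    "duration_h": s["duration_h"], "stalled": s["stalled"],
                })
    return pd.DataFrame.from_records(rows)


def summarize(
    table: pd.DataFrame, value: str, by: Sequence[str], ci: float = 0.95
) -> pd.DataFrame:
    """Mean and Student-t confidence interval of ``value`` per group."""
    def _agg(g: pd.Series) -> pd.Series:
        vals = g.dropna().to_numpy()
        mean = vals.mean() if vals.size else float("nan")
        if vals.size > 1:
            half = scipy.stats.t.ppf(0.5 + ci / 2, vals.size - 1) * \
                vals.std(ddof=1) / math.sqrt(vals.size)
        else:
            half = 0.0
        return pd.Series({
            "mean": mean, "ci_low": mean - half, "ci_high": mean + half,
            "n": vals.size,
        })
    out = table.groupby(list(by))[value].apply(_agg).unstack()
    return out.reset_index()
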