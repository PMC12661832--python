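"""Spatial individual-based dynamic-FBA simulation of the cecum.

Each bacterium is an individual with a species model, a grid cell and a
biomass. Every hourly iteration: (1) dietary influx is added and the
metabolite pools are fully mixed; (2) individuals, in seeded-random order,
compute local uptake bounds from the shared pools (fair-share rationing),
solve FBA and move metabolites between themselves and the pools while
growing at the predicted rate; (3) individuals above twice the reference
biomass divide into a free neighboring cell; (4) each individual takes one
random-walk step; (5) on schedule, a random fraction of grid cells is
emptied — their occupants removed and the pools reduced by the emptied
cell share — mimicking the periodic release of cecal contents.

Oxygen is represented as a fixed uptake cap derived from the configured
near-anaerobic concentration rather than as a tracked pool; pH is carried
as metadata only. FBA solutions are memoized per (species, quantized
bounds), which keeps the per-individual loop cheap: identical individuals
facing the same environment share one LP solve.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import config
from .gem_core import GEM, solve_fba
from .synthetic_community import CommunitySample, DietSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ArenaParams",
    "ArenaState",
    "SimulationResult",
    "scale_abundances",
    "compute_uptake_bounds",
    "apply_emptying",
    "run_simulation",
]


# ---------------------------------------------------------------------------
# Parameters and state
# ---------------------------------------------------------------------------


@dataclass
class ArenaParams:
    """Physical and numerical parameters of the in-silico cecum.

    Defaults reflect the simulated cecal conditions: a 100 x 100 grid, 16
    hourly iterations (one feeding cycle) in 5 replicates, 25% of grid
    cells emptied every 4th iteration, near-anaerobic oxygen (1e-8 mM),
    neutral pH, and communities rescaled to 1000-5000 individuals with at
    least 5 individuals per species.
    """

    grid_width: int = 100
    grid_height: int = 100
    iterations: int = 16
    replicates: int = 5
    empty_every: int = 4
    empty_fraction: float = 0.25
    o2_mM: float = 1e-8
    ph: float = 7.0  # metadata only; no kinetic effect
    community_size_range: tuple[int, int] = (1000, 5000)
    min_individuals_per_species: int = 5
    cell_volume_l: float = 1e-4
    timestep_h: float = 1.0
    vmax_uptake: float = config.VMAX_UPTAKE
    ref_biomass_gdw: float = 1e-12
    preload_influx: bool = True
    mixing: str = "full"  # "full" (default) or "local" per-cell diffusion

    def __post_init__(self) -> None:
        if not 0 <= self.empty_fraction <= 1:
            raise ValueError(f"empty_fraction {self.empty_fraction} outside [0, 1]")
        lo, hi = self.community_size_range
        if lo > hi:
            raise ValueError(f"community_size_range {self.community_size_range} inverted")
        for name in ("grid_width", "grid_height", "iterations", "replicates", "empty_every"):
            if getattr(self, name) < 0 or (name.startswith("grid") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.mixing not in {"full", "local"}:
            raise ValueError(f"unknown mixing mode {self.mixing!r}")

    @property
    def n_cells(self) -> int:
        return self.grid_width * self.grid_height

    @property
    def arena_volume_l(self) -> float:
        return self.n_cells * self.cell_volume_l


@dataclass
class ArenaState:
    """Mutable simulation state for one replicate."""

    species: list[str]
    cells: list[int]
    biomass: list[float]
    pools: dict[str, float]
    iteration: int
    rng: np.random.Generator
    occupied: np.ndarray  # bool per grid cell

    @property
    def n_individuals(self) -> int:
        return len(self.species)


@dataclass
class SimulationResult:
    """All outputs of a multi-replicate run.

    ``records``: per (replicate, iteration, species, metabolite) net
    exchange flux (mmol/gDW/h, positive = export) and amount moved (mmol).
    ``population``: per (replicate, iteration, species) individual counts
    and total biomass. ``pools``: per (replicate, iteration, metabolite)
    pool after the iteration. ``emptying``: metabolite amounts removed by
    each emptying event. ``accounting``: per-iteration mass balance terms.
    """

    records: pd.DataFrame
    population: pd.DataFrame
    pools: pd.DataFrame
    emptying: pd.DataFrame
    accounting: pd.DataFrame
    params: ArenaParams


# ---------------------------------------------------------------------------
# Abundance scaling
# ---------------------------------------------------------------------------


def scale_abundances(
    qpcr_totals: Mapping[str, float],
    sample: CommunitySample,
    params: ArenaParams,
) -> dict[str, int]:
    """Map a sample's qPCR total onto individual counts per species.

    The cohort's log-transformed totals are rescaled linearly onto
    ``community_size_range`` (the cohort minimum maps to the low endpoint,
    the maximum to the high endpoint); per-species counts are the rescaled
    total times relative abundance, floored at
    ``min_individuals_per_species``.
    """
    if any(t <= 0 for t in qpcr_totals.values()):
        raise ValueError("all qPCR totals must be positive")
    for sp, ab in sample.members.items():
        if ab <= 0:
            raise ValueError(f"species {sp!r} has zero abundance")
    lo, hi = params.community_size_range
    logs = {s: math.log(t) for s, t in qpcr_totals.items()}
    lmin, lmax = min(logs.values()), max(logs.values())
    if math.isclose(lmin, lmax):
        logger.warning("single qPCR total in cohort; using midpoint community size")
        total = (lo + hi) / 2
    else:
        frac = (math.log(sample.qpcr_total) - lmin) / (lmax - lmin)
        total = lo + frac * (hi - lo)
    return {
        sp: max(params.min_individuals_per_species, round(total * ab))
        for sp, ab in sample.members.items()
    }


# ---------------------------------------------------------------------------
# Uptake bounds
# ---------------------------------------------------------------------------


def _quantize_down(x: float) -> float:
    """Round a bound down to a power of two (rationing granularity).

    Keeps the solved uptake within the truly available share while
    collapsing near-identical environments onto one memoized LP solve.
    """
    if x <= 0:
        return 0.0
    return 2.0 ** math.floor(math.log2(x))


def compute_uptake_bounds(
    pools: Mapping[str, float],
    biomass: float,
    n_individuals: int,
    params: ArenaParams,
    metabolites: frozenset[str] | None = None,
) -> dict[str, float]:
    """Per-metabolite maximal uptake rates (mmol/gDW/h) for one individual.

    Each individual may take at most its fair share (pool / current number
    of individuals) during the timestep, capped at ``vmax_uptake``. Oxygen
    is bounded by the fixed near-anaerobic cap instead of a pool.
    """
    dt = params.timestep_h
    mets = metabolites if metabolites is not None else frozenset(pools)
    bounds: dict[str, float] = {}
    for met in mets:
        if met == "o2":
            cap = params.o2_mM * params.cell_volume_l / (biomass * dt)
            bounds[met] = min(params.vmax_uptake, cap)
            continue
        pool = pools.get(met, 0.0)
        if pool <= 0:
            bounds[met] = 0.0
            continue
        share = pool / max(n_individuals, 1)
        bounds[met] = min(params.vmax_uptake, share / (biomass * dt))
    return bounds


# ---------------------------------------------------------------------------
# Emptying
# ---------------------------------------------------------------------------


def apply_emptying(
    state: ArenaState, fraction: float, rng: np.random.Generator, params: ArenaParams
) -> dict[str, float]:
    """Empty a random set of grid cells; returns pool amounts removed.

    Exactly ``round(fraction * n_cells)`` distinct cells are chosen
    uniformly; their occupants are removed and every (fully mixed) pool is
    reduced by the emptied cell share.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    n_remove = round(fraction * params.n_cells)
    if n_remove == 0:
        return {m: 0.0 for m in state.pools}
    removed_cells = rng.choice(params.n_cells, size=n_remove, replace=False)
    removed_set = set(int(c) for c in removed_cells)
    keep = [i for i, c in enumerate(state.cells) if c not in removed_set]
    state.species = [state.species[i] for i in keep]
    state.cells = [state.cells[i] for i in keep]
    state.biomass = [state.biomass[i] for i in keep]
    state.occupied[:] = False
    state.occupied[state.cells] = True
    cell_share = n_remove / params.n_cells
    losses = {}
    for met in state.pools:
        losses[met] = state.pools[met] * cell_share
        state.pools[met] -= losses[met]
    return losses


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _neighbors(cell: int, params: ArenaParams) -> list[int]:
    w, h = params.grid_width, params.grid_height
    x, y = cell % w, cell // w
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            nx, ny = x + dx, y + dy
            if 0 <= nx < w and 0 <= ny < h:
                out.append(ny * w + nx)
    return out


def _seed_state(
    models: Mapping[str, GEM],
    counts: Mapping[str, int],
    diet: DietSpec,
    params: ArenaParams,
    rng: np.random.Generator,
) -> ArenaState:
    total = sum(counts.values())
    if total > params.n_cells:
        raise ValueError(
            f"{total} individuals exceed grid capacity {params.n_cells}"
        )
    cells = rng.choice(params.n_cells, size=total, replace=False)
    species: list[str] = []
    for sp in sorted(counts):
        species.extend([sp] * counts[sp])
    occupied = np.zeros(params.n_cells, dtype=bool)
    occupied[cells] = True
    all_mets = sorted(set().union(*(m.exchange_metabolites for m in models.values())))
    pools = {m: 0.0 for m in all_mets}
    if params.preload_influx:
        for m in all_mets:
            pools[m] += diet.influx(m) * params.arena_volume_l
    return ArenaState(
        species=species,
        cells=[int(c) for c in cells],
        biomass=[params.ref_biomass_gdw] * total,
        pools=pools,
        iteration=0,
        rng=rng,
        occupied=occupied,
    )


class _LocalPools:
    """Per-cell metabolite pools with conservative neighbor diffusion.

    Optional spatial mode: influx is spread evenly over cells, uptake and
    secretion act on the individual's own cell, and one explicit diffusion
    step (no-flux boundaries, exactly mass-conserving) runs per iteration.
    """

    def __init__(self, met_ids: list[str], params: ArenaParams, diffusion: float = 0.2):
        self.met_index = {m: i for i, m in enumerate(met_ids)}
        self.met_ids = met_ids
        self.params = params
        self.diffusion = diffusion
        self.grid = np.zeros((params.grid_height, params.grid_width, len(met_ids)))

    def add_influx(self, amounts: Mapping[str, float]) -> None:
        for m, amt in amounts.items():
            self.grid[:, :, self.met_index[m]] += amt / self.params.n_cells

    def diffuse(self) -> None:
        d = self.diffusion
        g = self.grid
        fx = d * (g[:, 1:, :] - g[:, :-1, :])
        g[:, :-1, :] += fx
        g[:, 1:, :] -= fx
        fy = d * (g[1:, :, :] - g[:-1, :, :])
        g[:-1, :, :] += fy
        g[1:, :, :] -= fy

    def local_amounts(self, cell: int) -> dict[str, float]:
        y, x = divmod(cell, self.params.grid_width)
        vals = self.grid[y, x, :]
        return {m: float(vals[i]) for m, i in self.met_index.items()}

    def add(self, cell: int, met: str, amount: float) -> float:
        y, x = divmod(cell, self.params.grid_width)
        i = self.met_index[met]
        new = self.grid[y, x, i] + amount
        if new < 0:
            amount = -float(self.grid[y, x, i])
            new = 0.0
        self.grid[y, x, i] = new
        return amount

    def empty_cells(self, cells: set[int]) -> dict[str, float]:
        idx = np.array(sorted(cells), dtype=int)
        ys, xs = idx // self.params.grid_width, idx % self.params.grid_width
        removed = self.grid[ys, xs, :].sum(axis=0)
        self.grid[ys, xs, :] = 0.0
        return {m: float(removed[i]) for m, i in self.met_index.items()}

    def totals(self) -> dict[str, float]:
        sums = self.grid.sum(axis=(0, 1))
        return {m: float(sums[i]) for m, i in self.met_index.items()}


def _run_replicate(
    models: Mapping[str, GEM],
    counts: Mapping[str, int],
    diet: DietSpec,
    params: ArenaParams,
    seed: int,
    replicate: int,
) -> tuple[list, list, list, list, list]:
    rng = np.random.default_rng(seed + replicate)
    state = _seed_state(models, counts, diet, params, rng)
    dt = params.timestep_h
    local = params.mixing == "local"
    cell_pools = None
    if local:
        met_ids = sorted(state.pools)
        cell_pools = _LocalPools(met_ids, params)
        if params.preload_influx:
            cell_pools.add_influx(dict(state.pools))
    fba_cache: dict[tuple, tuple[float, dict[str, float]]] = {}
    ex_mets = {sp: sorted(m.exchange_metabolites) for sp, m in models.items()}

    records, population, pool_rows, empty_rows, acct_rows = [], [], [], [], []

    def snapshot_population(iteration: int) -> None:
        per_sp_count: dict[str, int] = defaultdict(int)
        per_sp_bio: dict[str, float] = defaultdict(float)
        for sp, b in zip(state.species, state.biomass):
            per_sp_count[sp] += 1
            per_sp_bio[sp] += b
        for sp in sorted(per_sp_count):
            population.append(
                (replicate, iteration, sp, per_sp_count[sp], per_sp_bio[sp])
            )

    snapshot_population(0)

    for iteration in range(1, params.iterations + 1):
        state.iteration = iteration
        pool_start = dict(state.pools)

        # (1) influx, then mixing (full mix or one local diffusion step)
        influx_amounts = {}
        for m in state.pools:
            amt = diet.influx(m) * params.arena_volume_l
            influx_amounts[m] = amt
        if local:
            cell_pools.add_influx(influx_amounts)
            cell_pools.diffuse()
            state.pools = cell_pools.totals()
        else:
            for m, amt in influx_amounts.items():
                state.pools[m] += amt

        # (2) metabolism in seeded-random order
        prod = defaultdict(float)  # (species, met) -> net amount
        sp_biomass_hour = defaultdict(float)
        order = state.rng.permutation(state.n_individuals)
        n_now = state.n_individuals
        for idx in order:
            sp = state.species[idx]
            b = state.biomass[idx]
            cell = state.cells[idx]
            mets = ex_mets[sp]
            if local:
                here = cell_pools.local_amounts(cell)
                bounds = compute_uptake_bounds(
                    here, b, 1, params, metabolites=frozenset(mets)
                )
            else:
                bounds = compute_uptake_bounds(
                    state.pools, b, n_now, params, metabolites=frozenset(mets)
                )
            qb = tuple(_quantize_down(bounds[m]) for m in mets)
            key = (sp, qb)
            if key not in fba_cache:
                sol = solve_fba(models[sp], dict(zip(mets, qb)))
                if sol.optimal:
                    ex_fluxes = {
                        m: sol.fluxes.get(f"EX_{m}", _exchange_flux(models[sp], sol, m))
                        for m in mets
                    }
                    fba_cache[key] = (sol.objective_value, ex_fluxes)
                else:
                    fba_cache[key] = (0.0, {m: 0.0 for m in mets})
            mu, ex_fluxes = fba_cache[key]
            sp_biomass_hour[sp] += b
            if mu <= 0 and all(abs(v) < 1e-15 for v in ex_fluxes.values()):
                continue
            for m, v in ex_fluxes.items():
                if v == 0.0:
                    continue
                amount = v * b * dt  # positive = export to pool
                if local:
                    amount = cell_pools.add(cell, m, amount)
                else:
                    new_pool = state.pools[m] + amount
                    if new_pool < 0:
                        amount = -state.pools[m]
                        new_pool = 0.0
                    state.pools[m] = new_pool
                prod[(sp, m)] += amount
            state.biomass[idx] = b + mu * b * dt
        if local:
            state.pools = cell_pools.totals()

        for (sp, m), amount in sorted(prod.items()):
            bio = sp_biomass_hour[sp]
            flux = amount / (bio * dt) if bio > 0 else 0.0
            records.append((replicate, iteration, sp, m, flux, amount))

        # (3) division
        ref2 = 2.0 * params.ref_biomass_gdw
        n_before = state.n_individuals
        for idx in range(n_before):
            if state.biomass[idx] < ref2:
                continue
            free = [c for c in _neighbors(state.cells[idx], params) if not state.occupied[c]]
            if not free:
                continue
            target = free[int(state.rng.integers(len(free)))]
            half = state.biomass[idx] / 2.0
            state.biomass[idx] = half
            state.species.append(state.species[idx])
            state.cells.append(target)
            state.biomass.append(half)
            state.occupied[target] = True

        # (4) movement: one random-walk step, blocked moves are skipped
        for idx in state.rng.permutation(state.n_individuals):
            nbrs = _neighbors(state.cells[idx], params)
            target = nbrs[int(state.rng.integers(len(nbrs)))]
            if not state.occupied[target]:
                state.occupied[state.cells[idx]] = False
                state.cells[idx] = target
                state.occupied[target] = True

        # (5) emptying on schedule
        losses = {m: 0.0 for m in state.pools}
        if params.empty_every > 0 and iteration % params.empty_every == 0:
            if local:
                n_remove = round(params.empty_fraction * params.n_cells)
                removed = set(
                    int(c)
                    for c in state.rng.choice(params.n_cells, size=n_remove, replace=False)
                )
                keep = [i for i, c in enumerate(state.cells) if c not in removed]
                state.species = [state.species[i] for i in keep]
                state.cells = [state.cells[i] for i in keep]
                state.biomass = [state.biomass[i] for i in keep]
                state.occupied[:] = False
                state.occupied[state.cells] = True
                losses = cell_pools.empty_cells(removed)
                state.pools = cell_pools.totals()
            else:
                losses = apply_emptying(state, params.empty_fraction, state.rng, params)
            for m, amt in sorted(losses.items()):
                if amt > 0:
                    empty_rows.append((replicate, iteration, m, amt))

        snapshot_population(iteration)
        net_by_met = defaultdict(float)
        for (sp, mm), amt in prod.items():
            net_by_met[mm] += amt
        for m in sorted(state.pools):
            pool_rows.append((replicate, iteration, m, state.pools[m]))
            acct_rows.append(
                (
                    replicate,
                    iteration,
                    m,
                    pool_start[m],
                    influx_amounts[m],
                    net_by_met[m],
                    losses[m],
                    state.pools[m],
                )
            )

    return records, population, pool_rows, empty_rows, acct_rows


def _exchange_flux(model: GEM, sol, met: str) -> float:
    for rxn in model.exchange_reactions:
        if rxn.exchange_metabolite == met:
            return sol.fluxes.get(rxn.id, 0.0)
    return 0.0


def run_simulation(
    models: Mapping[str, GEM],
    counts: Mapping[str, int],
    diet: DietSpec,
    params: ArenaParams,
    seed: int,
) -> SimulationResult:
    """Run all replicates of the arena and collect flux/population series.

    Replicate ``r`` uses RNG seed ``seed + r``; everything is deterministic
    for fixed inputs. Species without a model raise before the run starts;
    individuals whose LP is infeasible idle for that hour.
    """
    missing = sorted(set(counts) - set(models))
    if missing:
        raise ValueError(f"species without a model: {missing}")
    records, population, pool_rows, empty_rows, acct_rows = [], [], [], [], []
    for r in range(params.replicates):
        rr, pp, pl, er, ar = _run_replicate(models, counts, diet, params, seed, r)
        records.extend(rr)
        population.extend(pp)
        pool_rows.extend(pl)
        empty_rows.extend(er)
        acct_rows.extend(ar)
    return SimulationResult(
        records=pd.DataFrame(
            records,
            columns=["replicate", "iteration", "species", "metabolite", "flux", "amount"],
        ),
        population=pd.DataFrame(
            population, columns=["replicate", "iteration", "species", "count", "biomass"]
        ),
        pools=pd.DataFrame(
            pool_rows, columns=["replicate", "iteration", "metabolite", "pool"]
        ),
        emptying=pd.DataFrame(
            empty_rows, columns=["replicate", "iteration", "metabolite", "amount_removed"]
        ),
        accounting=pd.DataFrame(
            acct_rows,
            columns=[
                "replicate",
                "iteration",
                "metabolite",
                "pool_start",
                "influx",
                "net_exchange",
                "emptied",
                "pool_end",
            ],
        ),
        params=params,
    )
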