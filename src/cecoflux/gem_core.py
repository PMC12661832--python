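"""Genome-scale metabolic model (GEM) core: types, IO, FBA, minimal media.

A GEM is a species' reaction network: stoichiometry, flux bounds, exchange
reactions (one boundary metabolite each; positive flux = secretion, negative
= uptake) and a biomass objective whose flux is the growth rate in 1/h.

Two on-disk formats are supported: a compact JSON dialect (lossless
round-trip, schema in ``docs/model_schema.md``) and SBML Level 3 with the
``fbc`` extension, read through cobrapy. FBA itself is solved with scipy's
HiGHS backend; after maximizing growth a parsimonious secondary objective
(minimize the sum of absolute fluxes at the fixed optimum) removes the LP
degeneracy that would otherwise make exchange fluxes solver-dependent.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from . import config

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "GEM",
    "FluxSolution",
    "ModelError",
    "read_model",
    "write_model",
    "solve_fba",
    "minimal_medium",
]


class ModelError(ValueError):
    """Raised for malformed models or infeasible model operations."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in the shared metabolite universe.

    ``is_dietary`` marks metabolites that enter the system through dietary
    influx (nonzero influx concentration); everything else is exclusively
    of microbial origin.
    """

    id: str
    name: str = ""
    is_dietary: bool = False


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with flux bounds and annotations.

    Stoichiometry maps metabolite id to a signed coefficient (negative =
    consumed). Exchange reactions touch exactly one metabolite; their flux
    convention is positive = secretion, negative = uptake.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    ec_numbers: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ModelError(
                f"exchange reaction {self.id!r} must touch exactly one metabolite"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        object.__setattr__(self, "ec_numbers", frozenset(self.ec_numbers))
        object.__setattr__(self, "pathways", frozenset(self.pathways))

    @property
    def exchange_metabolite(self) -> str:
        if not self.is_exchange:
            raise ModelError(f"reaction {self.id!r} is not an exchange reaction")
        return next(iter(self.stoichiometry))


@dataclass
class GEM:
    """One species' metabolic network with a biomass objective."""

    species_id: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_reaction_id: str

    def __post_init__(self) -> None:
        if self.biomass_reaction_id not in self.reactions:
            raise ModelError(
                f"model {self.species_id!r}: no biomass reaction "
                f"{self.biomass_reaction_id!r}"
            )
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelError(
                        f"model {self.species_id!r}: reaction {rxn.id!r} references "
                        f"unknown metabolite {met_id!r}"
                    )

    @property
    def ec_set(self) -> frozenset[str]:
        return frozenset().union(*(r.ec_numbers for r in self.reactions.values()))

    @property
    def pathway_set(self) -> frozenset[str]:
        return frozenset().union(*(r.pathways for r in self.reactions.values()))

    @property
    def reaction_id_set(self) -> frozenset[str]:
        return frozenset(self.reactions)

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    @property
    def exchange_metabolites(self) -> frozenset[str]:
        return frozenset(r.exchange_metabolite for r in self.exchange_reactions)


@dataclass
class FluxSolution:
    """Result of an FBA solve.

    ``objective_value`` is the growth rate (1/h) when status is optimal;
    ``fluxes`` maps reaction id to mmol/gDW/h.
    """

    status: str  # "optimal" | "infeasible"
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _model_to_dict(model: GEM) -> dict:
    return {
        "species_id": model.species_id,
        "biomass_reaction_id": model.biomass_reaction_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "is_dietary": m.is_dietary}
            for m in sorted(model.metabolites.values(), key=lambda m: m.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "ec_numbers": sorted(r.ec_numbers),
                "pathways": sorted(r.pathways),
                "is_exchange": r.is_exchange,
            }
            for r in sorted(model.reactions.values(), key=lambda r: r.id)
        ],
    }


def _model_from_dict(data: dict) -> GEM:
    metabolites = {
        m["id"]: Metabolite(
            id=m["id"], name=m.get("name", ""), is_dietary=bool(m.get("is_dietary", False))
        )
        for m in data["metabolites"]
    }
    reactions = {
        r["id"]: Reaction(
            id=r["id"],
            stoichiometry=r["stoichiometry"],
            lower_bound=float(r["lower_bound"]),
            upper_bound=float(r["upper_bound"]),
            ec_numbers=frozenset(r.get("ec_numbers", ())),
            pathways=frozenset(r.get("pathways", ())),
            is_exchange=bool(r.get("is_exchange", False)),
        )
        for r in data["reactions"]
    }
    if "biomass_reaction_id" not in data or data["biomass_reaction_id"] is None:
        raise ModelError(f"model {data.get('species_id')!r}: no biomass reaction")
    return GEM(
        species_id=data["species_id"],
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=data["biomass_reaction_id"],
    )


def _read_sbml(path: Path) -> GEM:
    # cobrapy handles SBML L3 + fbc (bounds, objective, MIRIAM annotations).
    from cobra.io import read_sbml_model

    cmodel = read_sbml_model(str(path))
    objective_rxns = [
        r.id
        for r in cmodel.reactions
        if abs(r.objective_coefficient) > 0
    ]
    if not objective_rxns:
        raise ModelError(f"model {cmodel.id!r}: no biomass reaction")
    metabolites = {
        m.id: Metabolite(id=m.id, name=m.name or "") for m in cmodel.metabolites
    }
    reactions: dict[str, Reaction] = {}
    for r in cmodel.reactions:
        ec = r.annotation.get("ec-code", ())
        if isinstance(ec, str):
            ec = (ec,)
        pathways = frozenset((r.subsystem,)) if r.subsystem else frozenset()
        reactions[r.id] = Reaction(
            id=r.id,
            stoichiometry={m.id: coeff for m, coeff in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            ec_numbers=frozenset(ec),
            pathways=pathways,
            is_exchange=bool(r.boundary),
        )
    model = GEM(
        species_id=cmodel.id or path.stem,
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=objective_rxns[0],
    )
    if not model.ec_set:
        logger.warning(
            "SBML model %s carries no EC annotations; ec_set is empty", model.species_id
        )
    return model


def read_model(path: str | Path, format: str | None = None) -> GEM:
    """Read a GEM from ``path`` in ``format`` ("json" or "sbml").

    The format is inferred from the file suffix when not given. The JSON
    dialect round-trips losslessly through :func:`write_model`.
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "json":
        with open(path) as fh:
            return _model_from_dict(json.load(fh))
    if format == "sbml":
        return _read_sbml(path)
    raise ModelError(f"unknown model format {format!r}")


def write_model(model: GEM, path: str | Path) -> None:
    """Write ``model`` to ``path`` in the JSON dialect (sorted, lossless)."""
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Flux balance analysis
# ---------------------------------------------------------------------------


def _effective_bounds(
    model: GEM, uptake_bounds: Mapping[str, float]
) -> list[tuple[float, float]]:
    for met, val in uptake_bounds.items():
        if val < 0:
            raise ModelError(f"negative uptake bound for {met!r}: {val}")
    bounds = []
    for rxn in model.reactions.values():
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if rxn.is_exchange:
            # Tighten uptake (negative direction) to what the environment offers.
            lb = max(lb, -float(uptake_bounds.get(rxn.exchange_metabolite, 0.0)))
            if lb > ub:
                raise ModelError(
                    f"reaction {rxn.id!r}: tightened bounds are empty ({lb} > {ub})"
                )
        bounds.append((lb, ub))
    return bounds


def _stoichiometric_matrix(model: GEM) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    met_ids = sorted(model.metabolites)
    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for met, coeff in model.reactions[rid].stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(float(coeff))
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )
    return S, met_ids, rxn_ids


def solve_fba(
    model: GEM,
    uptake_bounds: Mapping[str, float] | None = None,
    parsimonious: bool = True,
) -> FluxSolution:
    """Maximize biomass flux subject to steady state and bounds.

    ``uptake_bounds`` maps metabolite id to the maximal uptake rate
    (mmol/gDW/h, >= 0); exchange lower bounds are tightened to the negated
    value, and metabolites absent from the mapping cannot be taken up.
    With ``parsimonious`` (default) a second LP minimizes the total
    absolute flux at the fixed growth optimum, making the reported
    exchange fluxes reproducible across solver runs.
    """
    uptake_bounds = uptake_bounds or {}
    S, _, rxn_ids = _stoichiometric_matrix(model)
    bounds = _effective_bounds(model, uptake_bounds)
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(model.biomass_reaction_id)] = -1.0
    b_eq = np.zeros(S.shape[0])

    res = linprog(c, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        return FluxSolution(status="infeasible")
    mu = -res.fun

    if not parsimonious:
        return FluxSolution(
            status="optimal",
            objective_value=mu,
            fluxes=dict(zip(rxn_ids, (float(v) for v in res.x))),
        )

    # pFBA: min sum(t) s.t. S v = 0, |v_i| <= t_i, v_bio >= mu (within tolerance).
    bio = rxn_ids.index(model.biomass_reaction_id)
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq2 = sparse.hstack([S, sparse.csr_matrix(S.shape)])
    eye = sparse.identity(n)
    A_ub = sparse.vstack([sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])])
    b_ub = np.zeros(2 * n)
    lb2 = [bnd[0] for bnd in bounds] + [0.0] * n
    ub2 = [bnd[1] for bnd in bounds] + [None] * n
    lb2[bio] = max(lb2[bio], mu - 10 * config.FEASIBILITY_TOL)
    res2 = linprog(
        c2,
        A_eq=A_eq2,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb2, ub2)),
        method="highs",
    )
    if not res2.success:  # pragma: no cover - fallback for solver corner cases
        logger.warning(
            "pFBA stage failed for %s; returning first-stage fluxes", model.species_id
        )
        return FluxSolution(
            status="optimal",
            objective_value=mu,
            fluxes=dict(zip(rxn_ids, (float(v) for v in res.x))),
        )
    return FluxSolution(
        status="optimal",
        objective_value=mu,
        fluxes=dict(zip(rxn_ids, (float(v) for v in res2.x[:n]))),
    )


# ---------------------------------------------------------------------------
# Minimal medium
# ---------------------------------------------------------------------------


def _grows_on(
    model: GEM, nutrients: Iterable[str], growth_threshold: float, vmax: float
) -> bool:
    sol = solve_fba(
        model, {m: vmax for m in nutrients}, parsimonious=False
    )
    return sol.optimal and sol.objective_value >= growth_threshold


def minimal_medium(
    model: GEM,
    candidate_nutrients: Iterable[str],
    growth_threshold: float = config.GROWTH_THRESHOLD,
    exact: bool = False,
    vmax: float = config.VMAX_UPTAKE,
) -> frozenset[str]:
    """Smallest nutrient subset supporting growth >= ``growth_threshold``.

    The default algorithm is deterministic greedy elimination in
    lexicographic metabolite order: each candidate is dropped if growth
    survives without it. With ``exact=True`` all subsets are enumerated by
    increasing cardinality (intended for <= 12 candidates), guaranteeing a
    minimal-cardinality answer and providing the reference the greedy mode
    is validated against.
    """
    candidates = sorted(set(candidate_nutrients))
    if not _grows_on(model, candidates, growth_threshold, vmax):
        raise ModelError(
            f"model {model.species_id!r} cannot grow on medium "
            f"(candidates={candidates}, threshold={growth_threshold})"
        )
    if exact:
        if len(candidates) > 12:
            raise ModelError(
                "exact minimal-medium search is limited to 12 candidates; "
                f"got {len(candidates)}"
            )
        for k in range(len(candidates) + 1):
            for subset in itertools.combinations(candidates, k):
                if _grows_on(model, subset, growth_threshold, vmax):
                    return frozenset(subset)
        raise AssertionError("unreachable: full candidate set grows")  # pragma: no cover
    kept = list(candidates)
    for met in candidates:
        trial = [m for m in kept if m != met]
        if _grows_on(model, trial, growth_threshold, vmax):
            kept = trial
    return frozenset(kept)
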