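"""Shared fixtures: tiny hand-checkable models and seeded simulations."""

from __future__ import annotations

import pytest

from cecoflux.cecum_arena import ArenaParams, run_simulation, scale_abundances
from cecoflux.gem_core import GEM, Metabolite, Reaction
from cecoflux.synthetic_community import (
    CommunityConfig,
    generate_cohort,
    generate_community,
    generate_diet,
)


def make_gem(
    species_id: str,
    reactions: dict[str, dict],
    biomass_id: str = "biomass",
    dietary: frozenset[str] = frozenset(),
) -> GEM:
    """Build a GEM from {rxn_id: {"stoich": ..., "lb": ..., "ub": ..., "exchange": ...}}."""
    mets = set()
    for spec in reactions.values():
        mets.update(spec["stoich"])
    return GEM(
        species_id=species_id,
        metabolites={
            m: Metabolite(id=m, is_dietary=m in dietary) for m in sorted(mets)
        },
        reactions={
            rid: Reaction(
                id=rid,
                stoichiometry=spec["stoich"],
                lower_bound=spec.get("lb", 0.0),
                upper_bound=spec.get("ub", 1000.0),
                is_exchange=spec.get("exchange", False),
            )
            for rid, spec in reactions.items()
        },
        biomass_reaction_id=biomass_id,
    )


@pytest.fixture
def chain_model() -> GEM:
    """Linear chain: glucose uptake -> intermediate -> biomass, yield 0.5/glc."""
    return make_gem(
        "chain",
        {
            "EX_glc": {"stoich": {"glc": -1.0}, "lb": -1000.0, "exchange": True},
            "conv": {"stoich": {"glc": -1.0, "x": 1.0}},
            "biomass": {"stoich": {"x": -2.0}},
        },
    )


@pytest.fixture
def two_nutrient_model() -> GEM:
    """Grows only when both glucose and ammonium are supplied."""
    return make_gem(
        "dual",
        {
            "EX_glc": {"stoich": {"glc": -1.0}, "lb": -1000.0, "exchange": True},
            "EX_nh4": {"stoich": {"nh4": -1.0}, "lb": -1000.0, "exchange": True},
            "EX_urea": {"stoich": {"urea": -1.0}, "lb": -1000.0, "exchange": True},
            "biomass": {"stoich": {"glc": -1.0, "nh4": -1.0}},
        },
    )


@pytest.fixture(scope="session")
def six_species_fixture():
    """The default seeded 6-species keystone community with planted truth."""
    cfg = CommunityConfig(n_species=6, keystone=True)
    return generate_community(cfg, seed=7)


@pytest.fixture(scope="session")
def default_diet():
    return generate_diet()


@pytest.fixture(scope="session")
def small_arena_params() -> ArenaParams:
    """A scaled-down arena for fast test runs (same rules, smaller grid)."""
    return ArenaParams(
        grid_width=25,
        grid_height=25,
        iterations=10,
        replicates=2,
        community_size_range=(100, 300),
    )


@pytest.fixture(scope="session")
def six_species_simulation(six_species_fixture, default_diet, small_arena_params):
    """One seeded simulation of the 6-species fixture, reused across tests."""
    models, sample, truth = six_species_fixture
    counts = scale_abundances(
        {sample.sample_id: sample.qpcr_total, "other": sample.qpcr_total * 10},
        sample,
        small_arena_params,
    )
    result = run_simulation(models, counts, default_diet, small_arena_params, seed=11)
    return result, truth, sample


@pytest.fixture(scope="session")
def small_cohort():
    """A 3+3-sample paired cohort sharing one model catalog."""
    cfg = CommunityConfig(n_species=6)
    return generate_cohort(3, 3, cfg, seed=5)
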