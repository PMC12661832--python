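"""Synthetic toy communities with planted cross-feeding structure.

This module generates everything the downstream pipeline consumes — toy
genome-scale models, a cecal diet table, per-sample community profiles —
with known ground truth, so that interaction inference and community
metrics can be validated without any external data.

The motif library is closed and hand-checkable: each motif converts
substrates into an internal ``energy`` currency plus obligate byproducts,
and a biomass reaction consumes energy and ammonium. Byproduct secretion
is wired into the catabolic stoichiometry, so every planted
producer->consumer edge is realizable by construction: a growing producer
necessarily exports the metabolite, and the consumer grows whenever it is
supplied.

Motifs
------
``keystone_degrader``
    Primary polysaccharide degrader (the *Bacteroides*-like keystone).
    Degrades starch and cellulose, liberating glucose for the rest of the
    community. Its substrate niche (dietary fiber) barely overlaps the
    other members' nutrient requirements, so its presence dilutes both the
    community's metabolic resource overlap and, because it consumes no
    bacterial products, its cross-feeding density.
``cellulolytic_degrader``
    Backup fiber degrader with lower yield; liberates glucose and acetate.
``lactic_fermenter``
    Glucose -> lactate fermenter.
``butyrate_producer``
    Acetate + lactate -> butyrate (classic SCFA cross-feeding motif).
``generalist``
    Uses glucose and mucin-derived sialic acid; secretes propionate and
    some acetate.
``auxotroph``
    Grows on lactate but additionally requires external acetate for
    biomass — a strictly dependent terminal consumer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gem_core import GEM, Metabolite, Reaction

logger = logging.getLogger(__name__)

__all__ = [
    "CommunitySample",
    "DietSpec",
    "PlantedTruth",
    "CommunityConfig",
    "MOTIF_LIBRARY",
    "KEYSTONE_MOTIF",
    "generate_diet",
    "build_motif_gem",
    "generate_community",
    "generate_cohort",
    "generate_ec_profiles",
    "generate_measured_scfa",
    "write_diet_table",
    "read_diet_table",
    "write_sample_sheet",
    "read_sample_sheet",
]

SCFA_METABOLITES = ("ac", "ppa", "but")

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CommunitySample:
    """One sample: its group, member relative abundances and qPCR total."""

    sample_id: str
    group_label: str  # "HB" (keystone present) or "NB"
    members: dict[str, float]
    qpcr_total: float

    def __post_init__(self) -> None:
        if self.group_label not in {"HB", "NB"}:
            raise ValueError(f"unknown group label {self.group_label!r}")
        total = sum(self.members.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"sample {self.sample_id!r}: abundances sum to {total}, not 1"
            )
        for sp, ab in self.members.items():
            if not 0 < ab <= 1:
                raise ValueError(f"sample {self.sample_id!r}: abundance of {sp!r} is {ab}")
        if self.qpcr_total <= 0:
            raise ValueError(f"sample {self.sample_id!r}: non-positive qPCR total")


@dataclass
class DietSpec:
    """Diet table: metabolite -> (raw concentration mM, absorption fraction).

    The influx concentration reaching the cecum is raw * (1 - absorption),
    reflecting upstream small-intestinal absorption.
    """

    entries: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for met, (raw, absorbed) in self.entries.items():
            if raw < 0:
                raise ValueError(f"diet entry {met!r}: negative concentration {raw}")
            if not 0 <= absorbed <= 1:
                raise ValueError(
                    f"diet entry {met!r}: absorption fraction {absorbed} outside [0, 1]"
                )

    def influx(self, metabolite_id: str) -> float:
        """Influx concentration (mM) entering the cecum."""
        if metabolite_id not in self.entries:
            return 0.0
        raw, absorbed = self.entries[metabolite_id]
        return raw * (1.0 - absorbed)

    @property
    def influx_metabolites(self) -> frozenset[str]:
        """Metabolites with nonzero influx (the dietary metabolites)."""
        return frozenset(m for m in self.entries if self.influx(m) > 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metabolite": met,
                "raw_concentration_mM": raw,
                "absorption_fraction": absorbed,
                "influx_mM": raw * (1 - absorbed),
            }
            for met, (raw, absorbed) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class PlantedTruth:
    """Ground-truth producer -> metabolite -> consumer edges for a sample."""

    edges: frozenset[tuple[str, str, str]]  # (producer, metabolite, consumer)
    keystone_species_id: str | None


@dataclass
class CommunityConfig:
    """Knobs for the synthetic generator.

    ``motif_mix`` lists the non-keystone motifs cycled through to fill the
    community; the keystone (when enabled) is always the first member.
    """

    n_species: int = 6
    keystone: bool = True
    motif_mix: Sequence[str] = (
        "cellulolytic_degrader",
        "lactic_fermenter",
        "butyrate_producer",
        "generalist",
        "auxotroph",
    )
    ec_overlap: float = 0.5
    n_ec_per_species: int = 20
    n_pathways_per_species: int = 8
    qpcr_range: tuple[float, float] = (1.62e9, 3.02e11)
    keystone_abundance_weight: float = 6.0
    abundance_weight: float = 2.0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError(f"need at least 2 species, got {self.n_species}")
        unknown = set(self.motif_mix) - set(MOTIF_LIBRARY)
        if unknown:
            raise ValueError(f"unknown motifs in mix: {sorted(unknown)}")
        if not 0 <= self.ec_overlap <= 1:
            raise ValueError(f"ec_overlap {self.ec_overlap} outside [0, 1]")


# ---------------------------------------------------------------------------
# Diet
# ---------------------------------------------------------------------------

#: Default cecal influx diet. Starch is heavily absorbed upstream (~97%),
#: cellulose passes mostly intact as the primary fiber, glucose is fully
#: absorbed before reaching the cecum, and urea plus mucin-derived sialic
#: acid represent host-derived inputs.
DEFAULT_DIET_ENTRIES: dict[str, tuple[float, float]] = {
    "starch": (100.0, 0.97),
    "cellulose": (20.0, 0.10),
    "glc": (50.0, 1.0),
    "nh4": (20.0, 0.50),
    "urea": (10.0, 0.0),
    "neu5ac": (5.0, 0.0),
}


def generate_diet(overrides: Mapping[str, tuple[float, float]] | None = None) -> DietSpec:
    """Build the default cecal diet, optionally overriding or adding entries."""
    entries = dict(DEFAULT_DIET_ENTRIES)
    if overrides:
        entries.update({k: (float(v[0]), float(v[1])) for k, v in overrides.items()})
    return DietSpec(entries=entries)


def write_diet_table(diet: DietSpec, path: str | Path) -> None:
    diet.to_frame().to_csv(path, sep="\t", index=False)


def read_diet_table(path: str | Path) -> DietSpec:
    df = pd.read_csv(path, sep="\t")
    entries = {
        row["metabolite"]: (float(row["raw_concentration_mM"]), float(row["absorption_fraction"]))
        for _, row in df.iterrows()
    }
    return DietSpec(entries=entries)


# ---------------------------------------------------------------------------
# Motif library
# ---------------------------------------------------------------------------

_MET_NAMES = {
    "starch": "starch (dietary polysaccharide)",
    "cellulose": "cellulose (dietary fiber)",
    "glc": "D-glucose",
    "ac": "acetate",
    "lac": "D-lactate",
    "but": "butyrate",
    "ppa": "propionate",
    "nh4": "ammonium",
    "urea": "urea",
    "neu5ac": "N-acetylneuraminate (mucin-derived)",
    "energy": "internal energy currency",
}

#: Catabolic reactions per motif: id -> stoichiometry. Byproducts are
#: obligate (wired into the catabolic stoichiometry), so growth implies
#: secretion. The biomass reaction consumes energy plus ammonium (plus, for
#: the auxotroph, external acetate).
MOTIF_LIBRARY: dict[str, dict] = {
    "keystone_degrader": {
        "catabolism": {
            "cat_starch": {"starch": -1.0, "energy": 1.0, "glc": 2.0},
            "cat_cellulose": {"cellulose": -1.0, "energy": 1.0, "glc": 2.0},
        },
        "biomass": {"energy": -10.0, "nh4": -5.0},
    },
    "cellulolytic_degrader": {
        "catabolism": {
            "cat_cellulose": {"cellulose": -1.0, "energy": 0.5, "glc": 1.0, "ac": 0.5},
        },
        "biomass": {"energy": -10.0, "nh4": -5.0},
    },
    "lactic_fermenter": {
        "catabolism": {
            "cat_glc": {"glc": -1.0, "energy": 1.0, "lac": 1.5},
        },
        "biomass": {"energy": -10.0, "nh4": -5.0},
    },
    "butyrate_producer": {
        "catabolism": {
            "cat_ac_lac": {"ac": -1.0, "lac": -1.0, "energy": 1.0, "but": 1.0},
        },
        "biomass": {"energy": -10.0, "nh4": -5.0},
    },
    "generalist": {
        "catabolism": {
            "cat_glc": {"glc": -1.0, "energy": 1.0, "ppa": 0.5},
            "cat_neu5ac": {"neu5ac": -1.0, "energy": 1.0, "ppa": 0.5, "ac": 0.3},
        },
        "biomass": {"energy": -10.0, "nh4": -5.0},
    },
    "auxotroph": {
        "catabolism": {
            "cat_lac": {"lac": -2.0, "energy": 1.0},
        },
        "biomass": {"energy": -10.0, "nh4": -5.0, "ac": -2.0},
    },
}

KEYSTONE_MOTIF = "keystone_degrader"


def motif_exchange_metabolites(motif: str) -> frozenset[str]:
    spec = MOTIF_LIBRARY[motif]
    mets: set[str] = set()
    for stoich in spec["catabolism"].values():
        mets.update(stoich)
    mets.update(spec["biomass"])
    mets.discard("energy")
    return frozenset(mets)


def motif_products(motif: str) -> frozenset[str]:
    """External metabolites a growing instance of the motif must secrete."""
    spec = MOTIF_LIBRARY[motif]
    out: set[str] = set()
    for stoich in spec["catabolism"].values():
        out.update(m for m, c in stoich.items() if c > 0 and m != "energy")
    return frozenset(out)


def motif_substrates(motif: str) -> frozenset[str]:
    """External metabolites the motif can consume (catabolism + biomass)."""
    spec = MOTIF_LIBRARY[motif]
    out: set[str] = set()
    for stoich in spec["catabolism"].values():
        out.update(m for m, c in stoich.items() if c < 0)
    out.update(m for m, c in spec["biomass"].items() if c < 0 and m != "energy")
    return frozenset(out)


def build_motif_gem(
    motif: str, species_id: str, dietary_metabolites: frozenset[str] = frozenset()
) -> GEM:
    """Assemble a toy GEM for ``motif`` under the name ``species_id``."""
    if motif not in MOTIF_LIBRARY:
        raise ValueError(f"unknown motif {motif!r}")
    spec = MOTIF_LIBRARY[motif]
    external = motif_exchange_metabolites(motif)
    met_ids = sorted(external | {"energy"})
    metabolites = {
        m: Metabolite(id=m, name=_MET_NAMES.get(m, m), is_dietary=m in dietary_metabolites)
        for m in met_ids
    }
    reactions: dict[str, Reaction] = {}
    for rid, stoich in spec["catabolism"].items():
        reactions[rid] = Reaction(
            id=rid, stoichiometry=stoich, lower_bound=0.0, upper_bound=1000.0
        )
    reactions["biomass"] = Reaction(
        id="biomass", stoichiometry=spec["biomass"], lower_bound=0.0, upper_bound=1000.0
    )
    for m in sorted(external):
        reactions[f"EX_{m}"] = Reaction(
            id=f"EX_{m}",
            stoichiometry={m: -1.0},
            lower_bound=-1000.0,
            upper_bound=1000.0,
            is_exchange=True,
        )
    return GEM(
        species_id=species_id,
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id="biomass",
    )


# ---------------------------------------------------------------------------
# EC / pathway annotation profiles
# ---------------------------------------------------------------------------


def _annotate(model: GEM, ec_numbers: Sequence[str], pathways: Sequence[str]) -> GEM:
    """Return a copy of ``model`` with annotations spread over internal reactions."""
    internal = sorted(r.id for r in model.reactions.values() if not r.is_exchange)
    new_reactions = dict(model.reactions)
    assignments: dict[str, tuple[set[str], set[str]]] = {r: (set(), set()) for r in internal}
    for i, ec in enumerate(ec_numbers):
        assignments[internal[i % len(internal)]][0].add(ec)
    for i, pw in enumerate(pathways):
        assignments[internal[i % len(internal)]][1].add(pw)
    for rid, (ecs, pws) in assignments.items():
        new_reactions[rid] = replace(
            new_reactions[rid], ec_numbers=frozenset(ecs), pathways=frozenset(pws)
        )
    return GEM(
        species_id=model.species_id,
        metabolites=dict(model.metabolites),
        reactions=new_reactions,
        biomass_reaction_id=model.biomass_reaction_id,
    )


def generate_ec_profiles(
    models: Mapping[str, GEM],
    overlap: float,
    seed: int,
    n_ec: int = 20,
    n_pathways: int = 8,
) -> dict[str, GEM]:
    """Attach per-species EC/pathway sets with controlled pairwise overlap.

    Each species receives a shared core of annotations plus a private
    remainder sized so the pairwise Jaccard similarity of any two species'
    sets equals ``overlap`` up to rounding: with per-species set size t and
    shared core s, similarity is s / (2t - s), so s = round(2*t*o / (1+o)).
    The seed shuffles which core elements are used but the overlap is exact.
    """
    if not 0 <= overlap <= 1:
        raise ValueError(f"overlap {overlap} outside [0, 1]")
    rng = np.random.default_rng(seed)

    def _sets(n_per: int, tag: str) -> dict[str, list[str]]:
        n_core = round(2 * n_per * overlap / (1 + overlap)) if overlap > 0 else 0
        universe_core = [f"{tag}core.{i}" for i in range(max(n_core * 2, 1))]
        core = list(rng.choice(universe_core, size=n_core, replace=False)) if n_core else []
        out = {}
        for sp in sorted(models):
            private = [f"{tag}{sp}.{i}" for i in range(n_per - n_core)]
            out[sp] = core + private
        return out

    ec_sets = _sets(n_ec, "1.1.")
    pw_sets = _sets(n_pathways, "PWY-")
    return {
        sp: _annotate(models[sp], ec_sets[sp], pw_sets[sp]) for sp in sorted(models)
    }


# ---------------------------------------------------------------------------
# Community / cohort generation
# ---------------------------------------------------------------------------


def _roster(config: CommunityConfig) -> list[tuple[str, str]]:
    """(species_id, motif) pairs; the keystone (if any) comes first."""
    roster: list[tuple[str, str]] = []
    if config.keystone:
        roster.append(("keystone_degrader_1", KEYSTONE_MOTIF))
    counts: dict[str, int] = {}
    i = 0
    while len(roster) < config.n_species:
        motif = config.motif_mix[i % len(config.motif_mix)]
        counts[motif] = counts.get(motif, 0) + 1
        roster.append((f"{motif}_{counts[motif]}", motif))
        i += 1
    return roster


def _planted_edges(
    roster: Sequence[tuple[str, str]]
) -> frozenset[tuple[str, str, str]]:
    edges = set()
    for sp_p, motif_p in roster:
        for sp_c, motif_c in roster:
            if sp_p == sp_c:
                continue
            for met in motif_products(motif_p) & motif_substrates(motif_c):
                edges.add((sp_p, met, sp_c))
    return frozenset(edges)


def _sample_abundances(
    rng: np.random.Generator, roster: Sequence[tuple[str, str]], config: CommunityConfig
) -> dict[str, float]:
    alphas = np.array(
        [
            config.keystone_abundance_weight
            if motif == KEYSTONE_MOTIF
            else config.abundance_weight
            for _, motif in roster
        ]
    )
    ab = rng.dirichlet(alphas)
    ab = np.maximum(ab, 1e-3)
    ab = ab / ab.sum()
    return {sp: float(a) for (sp, _), a in zip(roster, ab)}


def _sample_qpcr(rng: np.random.Generator, config: CommunityConfig) -> float:
    lo, hi = config.qpcr_range
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_community(
    config: CommunityConfig, seed: int
) -> tuple[dict[str, GEM], CommunitySample, PlantedTruth]:
    """Generate one community: models, a sample profile, and planted truth.

    Deterministic for a fixed (config, seed). HB-like samples contain the
    keystone degrader; NB-like samples do not.
    """
    rng = np.random.default_rng(seed)
    diet = generate_diet()
    roster = _roster(config)
    models = {
        sp: build_motif_gem(motif, sp, diet.influx_metabolites) for sp, motif in roster
    }
    models = generate_ec_profiles(
        models,
        config.ec_overlap,
        seed,
        n_ec=config.n_ec_per_species,
        n_pathways=config.n_pathways_per_species,
    )
    sample = CommunitySample(
        sample_id=f"S{seed}",
        group_label="HB" if config.keystone else "NB",
        members=_sample_abundances(rng, roster, config),
        qpcr_total=_sample_qpcr(rng, config),
    )
    truth = PlantedTruth(
        edges=_planted_edges(roster),
        keystone_species_id=roster[0][0] if config.keystone else None,
    )
    return models, sample, truth


def generate_cohort(
    n_hb: int,
    n_nb: int,
    config: CommunityConfig,
    seed: int,
) -> tuple[dict[str, GEM], list[CommunitySample], PlantedTruth]:
    """Generate a paired HB/NB cohort sharing one model catalog.

    All samples draw from the same species roster; NB samples differ from
    HB samples only in the removal of the keystone member (abundances are
    renormalized over the remaining species). Per-sample abundances and
    qPCR totals vary with the sample index.
    """
    cfg_hb = replace(config, keystone=True)
    rng = np.random.default_rng(seed)
    diet = generate_diet()
    roster = _roster(cfg_hb)
    keystone_id = roster[0][0]
    models = {
        sp: build_motif_gem(motif, sp, diet.influx_metabolites) for sp, motif in roster
    }
    models = generate_ec_profiles(
        models,
        config.ec_overlap,
        seed,
        n_ec=config.n_ec_per_species,
        n_pathways=config.n_pathways_per_species,
    )
    samples: list[CommunitySample] = []
    for i in range(n_hb + n_nb):
        group = "HB" if i < n_hb else "NB"
        members = _sample_abundances(rng, roster, cfg_hb)
        if group == "NB":
            members.pop(keystone_id)
            total = sum(members.values())
            members = {sp: a / total for sp, a in members.items()}
        samples.append(
            CommunitySample(
                sample_id=f"{group}{i + 1 if group == 'HB' else i - n_hb + 1}",
                group_label=group,
                members=members,
                qpcr_total=_sample_qpcr(rng, config),
            )
        )
    truth = PlantedTruth(edges=_planted_edges(roster), keystone_species_id=keystone_id)
    return models, samples, truth


# ---------------------------------------------------------------------------
# Sample sheets and synthetic measurements
# ---------------------------------------------------------------------------


def write_sample_sheet(samples: Sequence[CommunitySample], path: str | Path) -> None:
    rows = []
    for s in samples:
        for sp, ab in sorted(s.members.items()):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "group": s.group_label,
                    "species_id": sp,
                    "rel_abundance": ab,
                    "qpcr_total": s.qpcr_total,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[CommunitySample]:
    df = pd.read_csv(path, sep="\t")
    samples = []
    for sid, grp in df.groupby("sample_id", sort=False):
        samples.append(
            CommunitySample(
                sample_id=str(sid),
                group_label=str(grp["group"].iloc[0]),
                members=dict(zip(grp["species_id"], grp["rel_abundance"])),
                qpcr_total=float(grp["qpcr_total"].iloc[0]),
            )
        )
    return samples


def generate_measured_scfa(
    predicted: pd.DataFrame, seed: int, noise_sd: float = 0.15
) -> pd.DataFrame:
    """Synthetic 'measured' SCFA concentrations for validation exercises.

    Applies multiplicative log-normal noise to predicted concentrations
    (samples x metabolites), emulating assay variability while preserving
    rank structure on average. Purely synthetic stand-in data for pipeline
    demonstrations; not an experimental measurement.
    """
    rng = np.random.default_rng(seed)
    noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=predicted.shape)
    return predicted * noise
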