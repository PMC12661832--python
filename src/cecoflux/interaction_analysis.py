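"""Cross-feeding inference and interaction statistics from flux records.

A species is a *producer* of a metabolite when its run-aggregated export
flux exceeds a noise threshold, and a *consumer* when its aggregated
uptake does; every (producer, consumer, metabolite) combination with
distinct species is a cross-feeding interaction. From the per-sample
interaction tables this module derives the cross-feeding coefficient
(CFC), group-level normalized interaction weights, metabolic-hub calls,
interaction-profile cliques, per-metabolite contribution shares, and the
keystone-metabolite filters.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping


import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import config
from .synthetic_community import DietSpec

logger = logging.getLogger(__name__)

__all__ = [
    "extract_interactions",
    "cross_feeding_coefficient",
    "normalize_across_samples",
    "identify_hubs",
    "cluster_cliques",
    "contribution_shares",
    "top_contributors",
    "filter_nondietary",
    "select_keystone_metabolites",
]

INTERACTION_COLUMNS = ["producer", "consumer", "metabolite"]


def extract_interactions(
    records: pd.DataFrame, flux_threshold: float = config.FLUX_THRESHOLD
) -> pd.DataFrame:
    """Derive the (producer, consumer, metabolite) table for one sample.

    ``records`` holds one sample's flux records (all replicates). Per
    species and metabolite, positive fluxes (export) and negative fluxes
    (uptake) are aggregated separately over the whole run; the species
    counts as producer/consumer of the metabolite when the respective
    total exceeds ``flux_threshold``. A species may hold both roles for
    the same metabolite but never pairs with itself.
    """
    if records.empty:
        return pd.DataFrame(columns=INTERACTION_COLUMNS)
    flux = records["flux"]
    agg = (
        records.assign(
            produced=flux.clip(lower=0.0), consumed=(-flux).clip(lower=0.0)
        )
        .groupby(["species", "metabolite"], sort=True)[["produced", "consumed"]]
        .sum()
        .reset_index()
    )
    rows = []
    for met, grp in agg.groupby("metabolite", sort=True):
        producers = sorted(grp.loc[grp["produced"] > flux_threshold, "species"])
        consumers = sorted(grp.loc[grp["consumed"] > flux_threshold, "species"])
        for p in producers:
            for c in consumers:
                if p != c:
                    rows.append((p, c, met))
    return pd.DataFrame(rows, columns=INTERACTION_COLUMNS)


def cross_feeding_coefficient(table: pd.DataFrame, n_species: int) -> float:
    """Realized ordered producer->consumer pairs over all possible pairs.

    The numerator counts ordered species pairs linked by at least one
    metabolite; the denominator is S*(S-1), so the coefficient lies in
    [0, 1].
    """
    if n_species < 2:
        raise ValueError(f"need at least 2 species, got {n_species}")
    if table.empty:
        return 0.0
    pairs = set(zip(table["producer"], table["consumer"]))
    return len(pairs) / (n_species * (n_species - 1))


def normalize_across_samples(
    tables: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Merge per-sample interaction tables into group-level weights.

    Output rows are (producer, consumer, metabolite) with:

    ``occurrences``
        number of samples in which this exact (pair, metabolite)
        interaction was seen;
    ``n_samples_present``
        number of samples in which the species pair interacted through
        any metabolite;
    ``weight``
        the pair's total interaction events across samples divided by
        ``n_samples_present`` (the pair-level normalized interaction
        count, repeated on each of the pair's metabolite rows).
    """
    frames = []
    for sample_id, tbl in tables.items():
        if tbl.empty:
            continue
        frames.append(tbl.assign(sample_id=sample_id))
    if not frames:
        return pd.DataFrame(
            columns=INTERACTION_COLUMNS + ["occurrences", "n_samples_present", "weight"]
        )
    long = pd.concat(frames, ignore_index=True)
    occ = (
        long.groupby(INTERACTION_COLUMNS)["sample_id"]
        .nunique()
        .rename("occurrences")
        .reset_index()
    )
    pair_events = (
        long.groupby(["producer", "consumer"])
        .size()
        .rename("pair_events")
        .reset_index()
    )
    pair_samples = (
        long.groupby(["producer", "consumer"])["sample_id"]
        .nunique()
        .rename("n_samples_present")
        .reset_index()
    )
    out = occ.merge(pair_events, on=["producer", "consumer"]).merge(
        pair_samples, on=["producer", "consumer"]
    )
    out["weight"] = out["pair_events"] / out["n_samples_present"]
    return out.drop(columns="pair_events").sort_values(INTERACTION_COLUMNS).reset_index(
        drop=True
    )


def identify_hubs(
    table: pd.DataFrame,
    min_partners: int = 10,
    min_metabolites: int = 12,
) -> pd.DataFrame:
    """Tally partners and exchanged metabolites per species; flag hubs.

    A species' partners are the distinct taxa it interacts with in either
    role; its metabolite count is the number of distinct metabolites it
    exchanges. A hub needs at least ``min_partners`` partners and
    ``min_metabolites`` metabolites.
    """
    species = sorted(set(table.get("producer", ())) | set(table.get("consumer", ())))
    rows = []
    for sp in species:
        mask_p = table["producer"] == sp
        mask_c = table["consumer"] == sp
        partners = set(table.loc[mask_p, "consumer"]) | set(table.loc[mask_c, "producer"])
        partners.discard(sp)
        mets = set(table.loc[mask_p | mask_c, "metabolite"])
        rows.append(
            {
                "species": sp,
                "n_partners": len(partners),
                "n_metabolites": len(mets),
                "is_hub": len(partners) >= min_partners and len(mets) >= min_metabolites,
            }
        )
    return pd.DataFrame(rows, columns=["species", "n_partners", "n_metabolites", "is_hub"])


def interaction_profile_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon interaction profiles (taxa x taxa summed pair weights)."""
    if table.empty:
        return pd.DataFrame()
    pair = (
        table.groupby(["producer", "consumer"])["weight"].first().reset_index()
        if "weight" in table
        else table.groupby(["producer", "consumer"]).size().rename("weight").reset_index()
    )
    taxa = sorted(set(pair["producer"]) | set(pair["consumer"]))
    mat = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for _, row in pair.iterrows():
        mat.loc[row["producer"], row["consumer"]] += row["weight"]
        mat.loc[row["consumer"], row["producer"]] += row["weight"]
    return mat


def cluster_cliques(profiles: pd.DataFrame, k: int = 8) -> pd.Series:
    """Cut a complete-linkage Euclidean dendrogram of taxa profiles into k cliques.

    ``profiles`` holds one row per taxon (e.g. its interaction profile).
    Returns integer cluster labels indexed by taxon. The fixed-size tree
    cut replaces visual clique selection for reproducibility.
    """
    n = len(profiles)
    if n < 2:
        raise ValueError(f"need at least 2 taxa, got {n}")
    if k > n:
        raise ValueError(f"cannot cut {n} taxa into {k} cliques")
    with warnings.catch_warnings():
        # Interaction profiles are square taxa x taxa observation matrices;
        # scipy's heuristic mistakes them for uncondensed distance matrices.
        warnings.simplefilter("ignore")
        Z = linkage(profiles.to_numpy(dtype=float), method="complete", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=profiles.index, name="clique")


def contribution_shares(records: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite production/consumption shares per species.

    Aggregates the recorded amounts over the whole run and expresses each
    species' contribution as a percentage of the metabolite's total per
    role; shares sum to 100 within each (metabolite, role). Metabolites
    with zero total in a role are omitted for that role.
    """
    if records.empty:
        return pd.DataFrame(columns=["metabolite", "species", "role", "amount", "share_pct"])
    amt = records["amount"]
    agg = (
        records.assign(
            produced=amt.clip(lower=0.0), consumed=(-amt).clip(lower=0.0)
        )
        .groupby(["species", "metabolite"], sort=True)[["produced", "consumed"]]
        .sum()
        .reset_index()
    )
    rows = []
    for role, col in (("producer", "produced"), ("consumer", "consumed")):
        for met, grp in agg.groupby("metabolite", sort=True):
            total = grp[col].sum()
            if total <= 0:
                continue
            for _, r in grp[grp[col] > 0].iterrows():
                rows.append(
                    {
                        "metabolite": met,
                        "species": r["species"],
                        "role": role,
                        "amount": r[col],
                        "share_pct": 100.0 * r[col] / total,
                    }
                )
    return pd.DataFrame(rows, columns=["metabolite", "species", "role", "amount", "share_pct"])


def top_contributors(
    shares: pd.DataFrame, top_n: int = 3, min_share_pct: float = 5.0
) -> pd.DataFrame:
    """Keep the top ``top_n`` species per (metabolite, role) above a share cutoff."""
    if shares.empty:
        return shares
    return (
        shares.sort_values("share_pct", ascending=False)
        .groupby(["metabolite", "role"], sort=True, group_keys=False)
        .head(top_n)
        .query("share_pct >= @min_share_pct")
        .sort_values(["metabolite", "role", "share_pct"], ascending=[True, True, False])
        .reset_index(drop=True)
    )


def filter_nondietary(table: pd.DataFrame, diet: DietSpec) -> pd.DataFrame:
    """Drop interactions involving metabolites with nonzero dietary influx."""
    if table.empty:
        return table
    dietary = diet.influx_metabolites
    return table[~table["metabolite"].isin(dietary)].reset_index(drop=True)


def select_keystone_metabolites(
    shares_hb: pd.DataFrame,
    shares_nb: pd.DataFrame,
    keystone_ids: Iterable[str],
    min_keystone_share_pct: float = 30.0,
    min_crossfeed_fraction: float = 0.01,
    require_keystone_share: bool = True,
    require_crossfeeding: bool = True,
    exclude_same_top_producer: bool = True,
) -> list[str]:
    """Metabolites whose exchange pattern hinges on the keystone taxa.

    Three filters, individually toggleable: (1) a single keystone taxon
    accounts for at least ``min_keystone_share_pct`` of a metabolite's
    production or consumption in some group; (2) at least
    ``min_crossfeed_fraction`` of the produced amount is consumed by a
    non-keystone taxon (the metabolite is genuinely cross-fed); (3)
    metabolites whose top producer is the same taxon in both groups are
    excluded, to emphasize shifted metabolic roles.
    """
    keystones = set(keystone_ids)
    known = set(shares_hb.get("species", ())) | set(shares_nb.get("species", ()))
    missing = keystones - known
    if missing:
        raise ValueError(f"unknown keystone taxa: {sorted(missing)}")

    mets = sorted(
        set(shares_hb.get("metabolite", ())) | set(shares_nb.get("metabolite", ()))
    )
    selected = []
    for met in mets:
        sub = {
            "HB": shares_hb[shares_hb["metabolite"] == met],
            "NB": shares_nb[shares_nb["metabolite"] == met],
        }
        if require_keystone_share:
            ok = any(
                (
                    (g["species"].isin(keystones))
                    & (g["share_pct"] >= min_keystone_share_pct)
                ).any()
                for g in sub.values()
            )
            if not ok:
                continue
        if require_crossfeeding:
            ok = False
            for g in sub.values():
                produced = g.loc[g["role"] == "producer", "amount"].sum()
                if produced <= 0:
                    continue
                others = g[(g["role"] == "consumer") & (~g["species"].isin(keystones))]
                if (others["amount"] >= min_crossfeed_fraction * produced).any():
                    ok = True
                    break
            if not ok:
                continue
        if exclude_same_top_producer:
            tops = {}
            for label, g in sub.items():
                prod = g[g["role"] == "producer"]
                tops[label] = (
                    prod.loc[prod["amount"].idxmax(), "species"] if len(prod) else None
                )
            if tops["HB"] is not None and tops["HB"] == tops["NB"]:
                continue
        selected.append(met)
    return selected
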