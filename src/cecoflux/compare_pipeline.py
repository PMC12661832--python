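"""Group comparison of exchange fluxes, SCFA validation, and orchestration.

Per sample, community exchange fluxes are summed per metabolite at every
hour, normalized by the total number of individuals alive at that hour,
aggregated over the simulated feeding cycle and averaged over replicates.
Group differences (keystone-positive "HB" vs keystone-negative "NB") are
tested per metabolite with the Wilcoxon rank-sum test, corrected with
Benjamini-Hochberg FDR, and classified into six exchange-direction
categories (increased production/consumption in either group, or a
production<->consumption switch between groups).

``run_pipeline`` wires the full analysis end to end on synthetic
communities: generate -> simulate -> interactions -> metrics -> group
comparison, writing one reproducible report directory.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from . import __version__ as _pkg_version
from . import config
from .cecum_arena import ArenaParams, run_simulation, scale_abundances
from .community_metrics import (
    build_incidence,
    cmd_score,
    dissimilarity,
    mi_pairs,
    mro_score,
    pcoa,
)
from .interaction_analysis import (
    cluster_cliques,
    contribution_shares,
    cross_feeding_coefficient,
    extract_interactions,
    filter_nondietary,
    identify_hubs,
    interaction_profile_matrix,
    normalize_across_samples,
    select_keystone_metabolites,
    top_contributors,
)
from .synthetic_community import (
    SCFA_METABOLITES,
    CommunityConfig,
    generate_cohort,
    generate_diet,
    generate_measured_scfa,
    write_diet_table,
    write_sample_sheet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "PipelineConfig",
    "aggregate_exchange_fluxes",
    "wilcoxon_rank_sum",
    "compare_groups",
    "validate_scfa",
    "run_pipeline",
]

CATEGORIES = (
    "increased consumption in HB",
    "increased production in HB",
    "increased consumption in NB",
    "increased production in NB",
    "production in NB to consumption in HB",
    "consumption in NB to production in HB",
    "not significant",
)

#: Pseudo-count added to flux magnitudes before taking log2 fold changes.
LOG2FC_EPS = 1e-9

#: Largest per-group size for which the rank-sum test enumerates exactly.
EXACT_TEST_MAX_N = 8


# ---------------------------------------------------------------------------
# Flux aggregation
# ---------------------------------------------------------------------------


def aggregate_exchange_fluxes(
    records: pd.DataFrame, population: pd.DataFrame
) -> pd.Series:
    """Community-size-normalized total exchange flux per metabolite.

    For each replicate and hour, species fluxes are summed per metabolite
    and divided by the total individual count at that hour; the hourly
    values are summed over the simulation and averaged across replicates.
    Positive values are net community production, negative net consumption.
    """
    if records.empty:
        return pd.Series(dtype=float)
    pop = population.groupby(["replicate", "iteration"])["count"].sum()
    flux = records.groupby(["replicate", "iteration", "metabolite"])["flux"].sum()
    per_rep: dict[int, dict[str, float]] = {}
    for (rep, it, met), val in flux.items():
        n = pop.get((rep, it))
        if n is None or n <= 0:
            raise ValueError(
                f"no population recorded for replicate {rep}, iteration {it}"
            )
        per_rep.setdefault(rep, {}).setdefault(met, 0.0)
        per_rep[rep][met] += val / n
    frame = pd.DataFrame(per_rep).fillna(0.0)
    return frame.mean(axis=1).sort_index()


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses exact enumeration for untied samples of at most
    ``EXACT_TEST_MAX_N`` per group, and the tie-corrected normal
    approximation (with continuity correction) otherwise.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = max(len(x), len(y)) <= EXACT_TEST_MAX_N and not has_ties
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def _category(mean_hb: float, mean_nb: float, significant: bool) -> str:
    if not significant:
        return "not significant"
    if mean_nb > 0 and mean_hb < 0:
        return "production in NB to consumption in HB"
    if mean_nb < 0 and mean_hb > 0:
        return "consumption in NB to production in HB"
    if mean_hb <= 0 and mean_nb <= 0:
        return (
            "increased consumption in HB"
            if abs(mean_hb) > abs(mean_nb)
            else "increased consumption in NB"
        )
    return (
        "increased production in HB"
        if abs(mean_hb) > abs(mean_nb)
        else "increased production in NB"
    )


def compare_groups(
    values: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    fc_label_threshold: float = 0.7,
) -> pd.DataFrame:
    """Per-metabolite group comparison of normalized exchange fluxes.

    ``values`` is samples x metabolites; ``groups`` maps sample id to
    "HB" or "NB". Each metabolite gets a Wilcoxon rank-sum p-value, a
    BH-FDR q-value, a log2 fold change of group-mean flux magnitudes
    (HB over NB, with a pseudo-count), one of the six exchange-direction
    categories, and a labeling flag for |log2FC| above the threshold.
    """
    hb = [s for s in values.index if groups[s] == "HB"]
    nb = [s for s in values.index if groups[s] == "NB"]
    if len(hb) < 2 or len(nb) < 2:
        raise ValueError(f"need >=2 samples per group (HB={len(hb)}, NB={len(nb)})")
    rows = []
    for met in values.columns:
        xv, yv = values.loc[hb, met].to_numpy(), values.loc[nb, met].to_numpy()
        mean_hb, mean_nb = float(xv.mean()), float(yv.mean())
        p = wilcoxon_rank_sum(xv, yv)
        log2fc = math.log2(
            (abs(mean_hb) + LOG2FC_EPS) / (abs(mean_nb) + LOG2FC_EPS)
        )
        rows.append(
            {
                "metabolite": met,
                "mean_flux_hb": mean_hb,
                "mean_flux_nb": mean_nb,
                "log2fc": log2fc,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = out["category"] = out["labeled"] = None
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["category"] = [
        _category(r.mean_flux_hb, r.mean_flux_nb, r.q < alpha)
        for r in out.itertuples()
    ]
    out["labeled"] = (out["q"] < alpha) & (out["log2fc"].abs() > fc_label_threshold)
    return out.sort_values("metabolite").reset_index(drop=True)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p-value for Spearman's rho (n <= 9)."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rhos = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def validate_scfa(
    predicted: pd.DataFrame, measured: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rank correlation between predicted and measured SCFAs.

    Both inputs are samples x metabolites with matching labels. Tie
    corrections are applied; p-values come from exact permutation for
    n <= 9 and the t approximation otherwise. Constant vectors yield an
    undefined (NaN) correlation, reported as such.
    """
    mets = [m for m in predicted.columns if m in measured.columns]
    common = predicted.index.intersection(measured.index)
    if len(common) < 3:
        raise ValueError(f"need at least 3 paired samples, got {len(common)}")
    rows = []
    for met in mets:
        xv = predicted.loc[common, met].to_numpy(dtype=float)
        yv = measured.loc[common, met].to_numpy(dtype=float)
        if np.allclose(xv, xv[0]) or np.allclose(yv, yv[0]):
            rows.append({"metabolite": met, "rho": float("nan"), "p": float("nan"),
                         "n": len(common), "note": "constant vector; rho undefined"})
            continue
        rho, p = scipy.stats.spearmanr(xv, yv)
        if len(common) <= 9:
            rx = scipy.stats.rankdata(xv)
            ry = scipy.stats.rankdata(yv)
            p = _exact_spearman_p(rx, ry, rho)
        rows.append({"metabolite": met, "rho": float(rho), "p": float(p),
                     "n": len(common), "note": ""})
    return pd.DataFrame(rows, columns=["metabolite", "rho", "p", "n", "note"])


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration with a versioned schema.

    Unknown keys are rejected up front; every numeric default can be
    overridden from YAML. ``arena`` holds overrides for
    :class:`~cecoflux.cecum_arena.ArenaParams` fields.
    """

    schema_version: int = 1
    n_hb_samples: int = 6
    n_nb_samples: int = 6
    community: dict = field(default_factory=dict)  # CommunityConfig overrides
    arena: dict = field(default_factory=dict)  # ArenaParams overrides
    flux_threshold: float = config.FLUX_THRESHOLD
    alpha: float = 0.05
    fc_label_threshold: float = 0.7
    min_partners: int = 10
    min_metabolites: int = 12
    clique_k: int = 8
    scfa_noise_sd: float = 0.15
    out_dir: str = "cecoflux_report"

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        # Validate nested overrides eagerly, before any compute.
        CommunityConfig(**cfg.community)
        ArenaParams(**{**cfg.arena})
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _write(df: pd.DataFrame, path: Path, name: str) -> None:
    df.to_csv(path / name, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig, seed: int) -> dict:
    """Run the full synthetic-community analysis and write a report bundle.

    Stages: cohort generation, per-sample arena simulation, interaction
    extraction and CFC, group-level interaction tables/hubs/cliques/
    shares, community metrics (incidence, dissimilarity, PCoA, MI, CMD,
    MRO), exchange-flux group comparison and SCFA validation against
    synthetic measurements. Rerunning with the same config and seed
    reproduces every table exactly. Returns the in-memory results keyed
    by stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        community_cfg = CommunityConfig(**cfg.community)
        params = ArenaParams(**cfg.arena)
        diet = generate_diet()
        models, samples, truth = generate_cohort(
            cfg.n_hb_samples, cfg.n_nb_samples, community_cfg, seed
        )
        groups = {s.sample_id: s.group_label for s in samples}
        qpcr = {s.sample_id: s.qpcr_total for s in samples}

        stage = "simulate"
        sims, cfc_rows, flux_rows, scfa_rows = {}, [], [], []
        tables: dict[str, pd.DataFrame] = {}
        for i, sample in enumerate(samples):
            sub_models = {sp: models[sp] for sp in sample.members}
            counts = scale_abundances(qpcr, sample, params)
            sim = run_simulation(sub_models, counts, diet, params, seed=seed + 1000 * (i + 1))
            sims[sample.sample_id] = sim

            stage = f"interactions:{sample.sample_id}"
            tbl = extract_interactions(sim.records, cfg.flux_threshold)
            tables[sample.sample_id] = tbl
            cfc_rows.append(
                {
                    "sample_id": sample.sample_id,
                    "group": sample.group_label,
                    "n_species": len(sample.members),
                    "cfc": cross_feeding_coefficient(tbl, len(sample.members)),
                }
            )
            agg = aggregate_exchange_fluxes(sim.records, sim.population)
            for met, val in agg.items():
                flux_rows.append(
                    {"sample_id": sample.sample_id, "metabolite": met, "flux": val}
                )
            final_pools = (
                sim.pools[sim.pools["iteration"] == params.iterations]
                .groupby("metabolite")["pool"]
                .mean()
            )
            for met in SCFA_METABOLITES:
                scfa_rows.append(
                    {
                        "sample_id": sample.sample_id,
                        "metabolite": met,
                        "predicted_mM": final_pools.get(met, 0.0) / params.arena_volume_l,
                    }
                )

        stage = "group tables"
        cfc = pd.DataFrame(cfc_rows)
        group_tables, hub_frames, clique_frames, shares = {}, [], [], {}
        for label in ("HB", "NB"):
            sub = {sid: t for sid, t in tables.items() if groups[sid] == label}
            norm = normalize_across_samples(sub)
            norm_nd = filter_nondietary(norm, diet)
            group_tables[label] = norm
            hubs = identify_hubs(norm, cfg.min_partners, cfg.min_metabolites)
            hub_frames.append(hubs.assign(group=label))
            profiles = interaction_profile_matrix(norm_nd)
            if len(profiles) >= 2:
                k = min(cfg.clique_k, len(profiles))
                cliques = cluster_cliques(profiles, k)
                clique_frames.append(
                    cliques.rename_axis("species").reset_index().assign(group=label)
                )
            recs = pd.concat(
                [sims[sid].records for sid in sub], ignore_index=True
            )
            shares[label] = contribution_shares(recs)
        hubs = pd.concat(hub_frames, ignore_index=True)
        cliques = (
            pd.concat(clique_frames, ignore_index=True)
            if clique_frames
            else pd.DataFrame(columns=["species", "clique", "group"])
        )
        keystone_mets = select_keystone_metabolites(
            shares["HB"], shares["NB"], [truth.keystone_species_id]
        )

        stage = "community metrics"
        incidence_rxn = build_incidence(samples, models, "binary", "reaction")
        incidence_ec_w = build_incidence(samples, models, "weighted", "EC")
        dist_jac = dissimilarity(incidence_rxn, "jaccard")
        dist_bc = dissimilarity(incidence_ec_w, "bray_curtis")
        coords, pct = pcoa(dist_bc)
        mi = mi_pairs(incidence_rxn)
        mi["same_group"] = [
            groups[a] == groups[b] for a, b in zip(mi["sample_i"], mi["sample_j"])
        ]
        mi["group_pair"] = [
            "-".join(sorted((groups[a], groups[b])))
            for a, b in zip(mi["sample_i"], mi["sample_j"])
        ]
        candidates = set(diet.influx_metabolites)
        for gem in models.values():
            candidates |= gem.exchange_metabolites
        metric_rows = []
        for sample in samples:
            member_models = {sp: models[sp] for sp in sample.members}
            mro, _ = mro_score(member_models, candidates)
            cmd, mean_dist = cmd_score(
                {sp: models[sp].ec_set for sp in sample.members}
            )
            metric_rows.append(
                {
                    "sample_id": sample.sample_id,
                    "group": sample.group_label,
                    "mro": mro,
                    "cmd": cmd,
                    "cmd_unadjusted": mean_dist,
                }
            )
        metrics = pd.DataFrame(metric_rows).merge(
            cfc[["sample_id", "cfc"]], on="sample_id"
        )

        stage = "group comparison"
        flux_table = (
            pd.DataFrame(flux_rows)
            .pivot(index="sample_id", columns="metabolite", values="flux")
            .fillna(0.0)
        )
        comparison = compare_groups(
            flux_table, groups, cfg.alpha, cfg.fc_label_threshold
        )
        predicted = pd.DataFrame(scfa_rows).pivot(
            index="sample_id", columns="metabolite", values="predicted_mM"
        )
        measured = generate_measured_scfa(predicted, seed + 77, cfg.scfa_noise_sd)
        scfa_validation = validate_scfa(predicted, measured)

        stage = "report"
        write_diet_table(diet, out / "diet.tsv")
        write_sample_sheet(samples, out / "samples.tsv")
        all_records = pd.concat(
            [sims[s.sample_id].records.assign(sample_id=s.sample_id) for s in samples],
            ignore_index=True,
        )
        _write(all_records, out, "records.tsv")
        _write(pd.DataFrame(flux_rows), out, "fluxes.tsv")
        _write(cfc, out, "cfc.tsv")
        for label in ("HB", "NB"):
            _write(group_tables[label], out, f"interactions_{label}.tsv")
            _write(shares[label], out, f"shares_{label}.tsv")
            _write(
                top_contributors(shares[label]), out, f"top_contributors_{label}.tsv"
            )
        _write(hubs, out, "hubs.tsv")
        _write(cliques, out, "cliques.tsv")
        _write(metrics, out, "metrics.tsv")
        _write(mi, out, "mi_pairs.tsv")
        coords.assign(sample_id=coords.index).to_csv(
            out / "pcoa.tsv", sep="\t", index=False, float_format="%.10g"
        )
        _write(comparison, out, "comparison.tsv")
        _write(scfa_validation, out, "scfa_validation.tsv")
        predicted.reset_index().to_csv(
            out / "scfa_predicted.tsv", sep="\t", index=False, float_format="%.10g"
        )
        (out / "run_info.json").write_text(
            json.dumps(
                {
                    "config": asdict(cfg),
                    "seed": seed,
                    "version": _pkg_version,
                    "keystone_metabolites": keystone_mets,
                    "pcoa_pct_variance": [float(v) for v in pct],
                },
                indent=1,
                sort_keys=True,
            )
            + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "samples": samples,
        "truth": truth,
        "sims": sims,
        "cfc": cfc,
        "tables": tables,
        "group_tables": group_tables,
        "hubs": hubs,
        "cliques": cliques,
        "shares": shares,
        "keystone_metabolites": keystone_mets,
        "metrics": metrics,
        "mi": mi,
        "pcoa": (coords, pct),
        "comparison": comparison,
        "flux_table": flux_table,
        "scfa_predicted": predicted,
        "scfa_validation": scfa_validation,
        "report_dir": out,
    }
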