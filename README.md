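# cecoflux

Individual-based dynamic flux-balance modeling of cecal microbial
communities, with cross-feeding inference and community-metabolism
statistics.

## The problem

Gut communities — here, the chicken cecum — are shaped by metabolic
interactions: primary fiber degraders liberate sugars and short-chain
fatty acid (SCFA) precursors that other taxa consume. Keystone taxa such
as *Bacteroides* species can monopolize these roles, and their loss
reorganizes who feeds whom. `cecoflux` provides a desk-scale platform to
study this: a spatial individual-based simulator in which every
bacterium runs flux balance analysis (FBA) on its genome-scale metabolic
model (GEM) each hour, plus the statistics used to compare communities
with and without a keystone degrader ("HB" vs "NB" groups).

It is aimed at microbiome researchers who want to prototype and validate
community-modeling analyses on fully synthetic communities with *known*
planted cross-feeding structure before committing to hundreds of
MAG-derived models.

## The model

**Arena.** Individuals live on a `W x H` grid (default 100 x 100, at
most one per cell). Each hourly iteration: dietary influx is added and
metabolite pools are fully mixed; individuals, in seeded-random order,
get uptake bounds `min(Vmax, fair share / (biomass * dt))`, solve

```
max  v_biomass    s.t.  S v = 0,  lb <= v <= ub
```

followed by a parsimonious second stage (minimize total |v| at the
fixed optimum) so exchange fluxes are solver-stable; biomass grows by
`mu * biomass * dt`, cells divide above twice the reference biomass and
take one random-walk step. Every 4th iteration 25% of grid cells are
emptied (individuals and pool share) to mimic periodic cecal release.
Oxygen is capped at a near-anaerobic level (1e-8 mM) and pH 7 is carried
as metadata.

**Statistics.** From the recorded exchange fluxes (threshold 1e-6
mmol/gDW/h on run totals):

- **CFC** (cross-feeding coefficient): realized ordered
  producer→consumer pairs over `S(S-1)`.
- **MRO** (metabolic resource overlap): mean over member pairs of
  `|Mi ∩ Mj| / min(|Mi|, |Mj|)`, where `Mi` is species *i*'s minimal
  nutrient requirement (deterministic greedy minimal medium).
- **CMD** (community metabolic dissimilarity): mean pairwise Jaccard
  distance between member EC-number sets, scaled by `log2(S)`.
- **MI**: mutual information between samples' binary reaction-content
  vectors (nats).
- Hub calls (≥10 partners and ≥12 exchanged metabolites), complete-
  linkage cliques, per-metabolite contribution shares, keystone-
  metabolite filters (30% keystone share, 1% cross-fed, shifted top
  producer), and Wilcoxon + Benjamini-Hochberg group comparison of
  community-size-normalized exchange fluxes with six exchange-direction
  categories.

The synthetic generator plants a closed motif library (keystone starch/
cellulose degrader, backup cellulolytic degrader, lactic fermenter,
butyrate producer, generalist, acetate-requiring auxotroph) whose
byproduct secretion is stoichiometrically obligatory, so every planted
producer→metabolite→consumer edge is realizable by construction.

## Worked example

```python
from cecoflux import PipelineConfig, run_pipeline

cfg = PipelineConfig.from_dict({
    "n_hb_samples": 4, "n_nb_samples": 4,
    "arena": {"grid_width": 30, "grid_height": 30, "iterations": 16,
              "replicates": 2, "community_size_range": (150, 500)},
    "out_dir": "demo_report",
})
res = run_pipeline(cfg, seed=1)
print(res["metrics"].groupby("group")[["mro", "cmd", "cfc"]].mean())
```

prints

```
            mro       cmd       cfc
group
HB     0.533333  1.340351  0.333333
NB     0.550000  1.203963  0.400000
```

Keystone-free (NB) communities show the higher cross-feeding coefficient
(0.40 vs 0.33) and higher metabolic resource overlap (0.550 vs 0.533):
with the keystone degrader absent, its low-overlap fiber niche
disappears and the remaining taxa both compete more for the same
resources and trade more among themselves — the qualitative signature
this package is built to expose. The report directory contains every
table (interactions, hubs, cliques, contribution shares, PCoA
coordinates, MI pairs, the six-category flux comparison, predicted SCFA
concentrations) as TSV, plus `run_info.json` with the config echo and
seed; rerunning with the same config and seed reproduces every table
byte for byte.

A command-line interface mirrors the stages:

```bash
cecoflux generate --n-hb 6 --n-nb 6 --seed 0 --out synthetic/
cecoflux simulate --models synthetic/models --diet synthetic/diet.tsv \
    --samples synthetic/samples.tsv --grid 30x30 --community-size 150:500 \
    --seed 0 --out records.tsv
cecoflux analyze --records records.tsv --n-species 6
cecoflux run --seed 0 --out report/
```

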