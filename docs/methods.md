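# Methods

This note documents the models, parameters and design choices behind
`cecoflux`, in the order the pipeline runs.

## Flux balance analysis core

Each species is a genome-scale metabolic model (GEM): reactions with
signed stoichiometry, flux bounds in mmol/gDW/h, exchange reactions
touching exactly one metabolite (positive flux = secretion), and a
biomass reaction whose flux is the growth rate (1/h). FBA maximizes
biomass flux under the steady-state constraint `S v = 0`, solved with
scipy's HiGHS backend. Because the optimal flux vector of an LP is
generally degenerate — and the exchange fluxes are the raw data for all
downstream statistics — a second, parsimonious stage minimizes the sum
of absolute fluxes with the growth optimum pinned (within 1e-8). This
makes reported exchange fluxes a deterministic function of the model
and its bounds.

Tolerances (defined once in `cecoflux.config`): solver feasibility
1e-9, optimality comparisons 1e-6, growth threshold 1e-4 1/h, default
uptake cap `Vmax = 10` mmol/gDW/h.

**Minimal media.** The minimal nutrient requirement of a model is
computed by deterministic greedy elimination in lexicographic
metabolite order: starting from the full candidate set, each nutrient
is dropped if growth stays above the threshold without it. Greedy
elimination is not guaranteed to reach the global minimum cardinality;
an exact mode enumerates all subsets by increasing cardinality for up
to 12 candidates, and the test suite checks that greedy and exact
answers agree in cardinality on all fixture models. Determinism was
preferred over guaranteed minimality to avoid a MILP dependency; the
choice is isolated in `minimal_medium`.

## Synthetic communities

The generator is first-class, tested code: it emits the same model
(JSON/SBML), diet (TSV) and sample-sheet (TSV) formats the pipeline
consumes, so synthetic data is indistinguishable from user data.

**Motif library.** Six closed motifs with hand-checkable stoichiometry;
no random stoichiometry is ever generated, so growth optima remain
analytic. Catabolic reactions convert substrates into an internal
`energy` currency plus *obligate* byproducts (byproducts sit in the
catabolic stoichiometry, not in optional side reactions), and the
biomass reaction consumes 10 energy + 5 ammonium. With the default
uptake cap this puts maximal growth rates in the 0.5–2 /h range. The
keystone degrader converts starch or cellulose to glucose; the backup
cellulolytic degrader does the same at half yield while also releasing
acetate; the fermenter converts glucose to lactate; the butyrate
producer requires acetate + lactate; the generalist uses glucose and
mucin-derived sialic acid, releasing propionate and acetate; the
auxotroph grows on lactate but needs external acetate in its biomass
reaction. Planted truth edges are all (producer, metabolite, consumer)
triples implied by the motif product/substrate sets.

This design gives the keystone a *low-overlap* niche (its minimal
medium is {starch, ammonium}, shared with no other member beyond
ammonium) and makes it a pure upstream producer that consumes no
bacterial metabolite. Removing it therefore necessarily (i) raises the
community's mean pairwise minimal-medium overlap (all keystone pairs
sit at the overlap minimum) and (ii) raises the cross-feeding
coefficient (the keystone contributes 2 realized pairs but 2S possible
ordered pairs) — the synthetic analogue of the keystone-present vs
keystone-absent community contrast the statistics are designed to
detect. These are constructed, qualitative properties; passing the
directional tests shows the statistics respond correctly to a planted
contrast, not that real communities behave this way.

**Diet.** Raw concentrations are reduced by literature-style upstream
absorption: starch 100 mM with 97% absorption (3 mM reaches the
cecum), cellulose 20 mM with 10% (primary fiber), glucose fully
absorbed upstream (0 influx — hence a strictly microbial currency in
the cecum), ammonium 20 mM at 50%, urea and sialic acid host-derived
and unabsorbed. A metabolite is "dietary" iff its influx is nonzero;
the non-dietary filter for interaction tables keys off this.

**Samples.** Cohorts share one model catalog; HB samples contain the
keystone, NB samples are the same roster with the keystone removed and
abundances renormalized. Relative abundances are Dirichlet-distributed
(keystone weight 6, others 2 — the keystone is typically dominant);
qPCR totals are drawn log-uniformly over 1.62e9–3.02e11 16S copies/g,
spanning the two orders of magnitude that make the log-rescaling path
meaningful. EC/pathway annotation sets have an exactly controlled
pairwise Jaccard similarity: per species size `t` with a shared core of
`s = round(2 t o / (1 + o))` gives similarity `s / (2t - s) = o`.

## Arena simulation

Parameters (defaults): 100 x 100 grid, 16 hourly iterations, 5
replicates, 25% of cells emptied every 4th iteration, oxygen 1e-8 mM
(a fixed uptake cap, not a pool), pH 7 (metadata only), community sizes
rescaled onto 1000–5000 individuals with a 5-individual floor per
species, cell volume 1e-4 L, reference biomass 1e-12 gDW per seeded
individual.

Abundance scaling: cohort qPCR totals are log-transformed and linearly
rescaled so the cohort minimum maps to the low endpoint and the maximum
to the high endpoint; a single-sample cohort gets the midpoint with a
logged warning.

Per iteration: (1) influx `concentration x arena volume` is added and
pools are fully mixed — full mixing is the default because influx is
distributed evenly over the grid and it makes conservation and emptying
exactly testable; a per-cell mode (`mixing="local"`) keeps pools per
cell with one conservative neighbor-diffusion step per hour. (2)
Individuals are processed in a seeded-random order; each receives
fair-share uptake bounds `min(Vmax, (pool / n_individuals) / (biomass
dt))`. Bounds are quantized down to the nearest power of two before
solving, which bounds the solved uptake by the truly available share
and lets identical individuals share one memoized LP solve (the
rationing granularity is at most a factor 2 and only matters when a
pool is nearly depleted). Infeasible individuals idle for the hour.
(3) Division: biomass ≥ 2x the reference splits half the biomass into
a uniformly chosen free neighboring cell (skipped when none is free);
there is no death rule beyond emptying — fewer rules, fewer hidden
parameters. (4) Movement: one random-walk step to a random neighbor,
skipped if occupied. (5) Emptying removes exactly `round(f x n_cells)`
distinct uniformly chosen cells (their occupants) and the same fraction
of every mixed pool. Replicate r uses seed + r.

Records hold, per (replicate, iteration, species, metabolite), the net
amount moved and the biomass-normalized net flux; a per-iteration
accounting table (pool_start, influx, net exchange, emptied, pool_end)
lets mass conservation be asserted to < 1e-9 relative at every step.

## Interaction statistics

Thresholding at 1e-6 mmol/gDW/h is applied to run-aggregated totals of
export and import flux separately, so a species can hold both roles
for one metabolite (but never pairs with itself). The cross-feeding
coefficient counts *ordered* producer→consumer pairs over `S(S-1)` —
the printed per-metabolite event count is exported alongside, since
heatmap-style analyses may want pair x metabolite events instead.
Group-level tables normalize each pair's total interaction events by
the number of samples in which the pair occurs. Hubs need ≥10 distinct
partners (either role) and ≥12 distinct exchanged metabolites; both
thresholds are configurable. Cliques come from a complete-linkage
Euclidean dendrogram over per-taxon interaction profiles cut at a fixed
k (default 8) — a reproducible replacement for visual clique selection.

Keystone-metabolite filters (all toggleable): ≥30% of a metabolite's
production or consumption attributable to one keystone taxon in some
group; ≥1% of the produced amount consumed by a non-keystone taxon;
metabolites with the same top producer in both groups excluded.

## Community metrics

Incidence matrices are binary unions or abundance-weighted sums of
member feature sets (reactions, pathways, EC numbers). Jaccard /
Bray-Curtis dissimilarities come from scipy. PCoA is classical scaling:
double-center the squared distance matrix, eigendecompose, keep
positive eigenvalues; percent variance is eigenvalue over the positive
sum. MI uses the plug-in estimator on the 2x2 joint distribution of two
binary vectors, in nats. CMD is the mean off-diagonal pairwise Jaccard
distance between member EC sets times `log2(S)`; the logarithmic factor
reads "diminishing contribution of additional species" as logarithmic
reward for community size, and the unadjusted mean is exported so users
can substitute their own adjustment. MRO normalizes the pairwise
minimal-medium intersection by the smaller requirement set; a species
with an empty requirement competes for nothing and scores 0 against any
partner. Both the CMD adjustment and the MRO normalization are
documented decisions isolated behind single functions.

## Group comparison

Exchange fluxes are summed per metabolite each hour, divided by the
total individual count at that hour, summed over the 16-h run and
averaged over replicates. Wilcoxon rank-sum tests are exact (full
enumeration) for untied groups of ≤8, tie-corrected normal
approximation otherwise; BH-FDR is applied across metabolites. The
log2 fold change uses group means of flux *magnitudes* with a 1e-9
pseudo-count — net fluxes cross zero between groups, so a signed ratio
is ill-defined; the sign structure instead drives the six-category
classifier (increased production/consumption in either group, or a
production↔consumption switch). Spearman validation of predicted vs
measured SCFA concentrations uses exact permutation p-values for n ≤ 9.
The bundled "measured" SCFA table is synthetic: multiplicative
log-normal noise on the predictions (`generate_measured_scfa`), present
so the validation path is exercised end to end, never a real assay.

## Problem sizes

Full-size defaults (100 x 100 grid, 1000–5000 individuals, 16 h, 5
replicates) are the simulated cecal conditions and remain the
`ArenaParams` defaults. The bundled demo, test suite and acceptance
script run the same rules on reduced instances — 15x15 to 30x30 grids,
60–500 individuals, 1–2 replicates — chosen so the whole suite
completes in about a minute while every qualitative property (edge
recovery, keystone contrast, conservation, determinism) is preserved.

## Known limitations

- Toy motif models (≤ ~20 reactions) do not emulate gapseq-scale
  networks (~3000 reactions); runtimes and statistical granularity on
  real models will differ.
- With a shared motif catalog, binary reaction content is coarse:
  keystone-present samples contain every catalog reaction, so their
  pairwise MI degenerates to 0 while keystone-absent samples retain a
  positive MI. The direction of the group contrast is preserved but its
  magnitude is an artifact of catalog sharing; EC-based incidence is
  the richer synthetic signal.
- No host uptake of metabolites (butyrate in particular accumulates),
  no mucosal adhesion, no pH kinetics, no death rule beyond emptying.
- Sequential fair-share rationing makes early-processed individuals
  see marginally larger pools within an hour; the seeded shuffle
  removes any systematic bias across iterations.
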