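# JSON model dialect

A compact, lossless on-disk format for genome-scale metabolic models,
read and written by `cecoflux.gem_core.read_model` / `write_model`.
Exchange reactions are identified by an explicit boolean rather than an
id naming convention, because naming conventions differ across
toolchains.

```json
{
 "species_id": "lactic_fermenter_1",
 "biomass_reaction_id": "biomass",
 "metabolites": [
  {"id": "glc", "name": "D-glucose", "is_dietary": false},
  {"id": "lac", "name": "D-lactate", "is_dietary": false}
 ],
 "reactions": [
  {
   "id": "EX_glc",
   "stoichiometry": {"glc": -1.0},
   "lower_bound": -1000.0,
   "upper_bound": 1000.0,
   "ec_numbers": [],
   "pathways": [],
   "is_exchange": true
  },
  {
   "id": "biomass",
   "stoichiometry": {"glc": -1.0, "lac": 1.5},
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "ec_numbers": ["1.1.1.27"],
   "pathways": ["PWY-heterolactic"],
   "is_exchange": false
  }
 ]
}
```

Rules:

- `species_id` and `biomass_reaction_id` are required; the biomass
  reaction must exist in `reactions`.
- metabolite ids are unique; every key in a reaction's `stoichiometry`
  must resolve to a listed metabolite. Negative coefficients are
  consumed, positive produced.
- `lower_bound <= upper_bound`, in mmol/gDW/h. For exchange reactions
  the convention is positive flux = secretion, negative = uptake.
- exchange reactions have exactly one metabolite in their stoichiometry.
- `ec_numbers` and `pathways` are optional sorted string lists; writing
  a model sorts all lists and object keys, so write -> read -> write is
  byte-identical.

SBML Level 3 (+fbc) files are also accepted (suffix `.xml`/`.sbml`):
bounds and the objective come from fbc, exchange status from boundary
reactions, EC numbers from MIRIAM-style `ec-code` annotations (absent
annotations yield an empty EC set with a logged warning).
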