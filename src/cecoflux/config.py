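"""Numeric tolerances and shared defaults.

All tolerance values used across the package are defined here once so that
solver feasibility, optimality and growth decisions are consistent between
the FBA core, the arena simulator and the downstream statistics.
"""

#: Feasibility tolerance handed to the LP solver (steady-state residual).
FEASIBILITY_TOL = 1e-9

#: Optimality tolerance: two objective values closer than this are equal.
OPTIMALITY_TOL = 1e-6

#: Default growth-rate threshold (1/h) below which a model counts as not growing.
GROWTH_THRESHOLD = 1e-4

#: Default cap on uptake rates (mmol/gDW/h) when a nutrient is "freely" available.
VMAX_UPTAKE = 10.0

#: Flux threshold (mmol/gDW/h, applied to run-aggregated totals) below which
#: exchange activity is treated as numerical noise in interaction extraction.
FLUX_THRESHOLD = 1e-6
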