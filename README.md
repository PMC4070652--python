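# oenoflux

Quantitative physiology of anaerobic wine fermentations: specific-rate
estimation from batch and chemostat cultures, elemental-balance data
reconciliation with chi-square consistency testing, and metabolic flux
analysis (MFA) on a reconstructed central-carbon network of *Saccharomyces
cerevisiae* growing on synthetic grape must.

## Who this is for

A wine fermentation is a batch process that walks the yeast through a
sequence of physiological states — exponential growth on abundant sugar and
nitrogen, a transition as ammonium runs out, and a long ethanol-producing
near-stationary phase.  Chemostats run at dilution rates D = 0.27, 0.04,
0.02 and 0.007 h⁻¹ (with feed media whose nitrogen content mirrors each
stage) freeze those states for measurement.  This package implements the
full numerical workflow for analysing such experiments, plus a synthetic-
data generator so every stage of the pipeline can be verified against known
ground truth without any external data.

## The core methods

**Rates.**  Batch growth rates come from the log-linear fit
μ = slope of ln X(t) on a phase window; conversion rates from polynomial or
linear fits of concentration, q(t) = (dC/dt)/X(t), reported as the min–max
envelope over the window.  Chemostat rates follow the steady-state balances
q_s = −D·(C_feed − C_res)/X and q_p = D·C_p/X with first-order error
propagation, and μ = D.

**Reconciliation.**  Measured exchange-rate vectors r_m (with covariance F)
never close the element balances exactly.  With R the conservation
constraints projected onto the measured rates (R = E_m − E_c·E_c⁺·E_m),

    ε = R·r_m,  r̂ = r_m − F·Rᵀ(R F Rᵀ)⁺·ε,  h = εᵀ(R F Rᵀ)⁺·ε.

Under correct Gaussian noise, h ~ χ²(rank R): h below the 95% quantile
(7.81 at redundancy 3, 9.49 at 4) means no gross measurement error; above
it, serial elimination ranks the suspects.

**MFA.**  On the stoichiometric matrix N (45 balanced metabolites × 67
reactions, succinyl-CoA synthetase pinned to zero under anaerobiosis so the
TCA cycle runs as separate oxidative and reductive branches), the internal
fluxes solve N_c·v_c = −N_m·v_m; surplus balances give a flux-level
consistency index, and fluxes are also reported as % C-mol per C-mol of
glucose uptake.

## Worked example

```python
import oenoflux as of

model = of.load_wine_model()            # anaerobic network + biomass reaction
rv = of.load_chemostat_rates("II")      # steady state at D = 0.04 1/h

fs = of.solve_fluxes(model, rv)
print(round(fs.h_flux, 2), fs.df)       # 4.21 2
s = of.stage_summaries(fs, rv, model)
print(round(s["glucose_share_pct"]))    # 68
print(round(s["glycolysis_share_pct"])) # 97
```

The flux consistency index 4.21 at 2 degrees of freedom is well below the
5.99 critical value: the late-exponential rate set is compatible with the
network.  Glucose carries ~70% of the hexose carbon at this stage (falling
to ~60% at D = 0.007 h⁻¹, rising to ~90% at 0.27 h⁻¹), and ~97% of the
hexose-phosphate carbon passes the glycolytic branch at the G6P node, the
rest feeding the oxidative pentose phosphate pathway for NADPH.

The `examples/` directory holds four short narrative scripts — batch rate
estimation, chemostat reconciliation, four-stage MFA, and the synthetic
generate→corrupt→reconcile→localize round trip — each printing the numbers
it computes and a line on what they mean.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the size of the redundancy-3 consistency test: it
generates 10,000 exactly balanced synthetic chemostat measurement sets with
correctly specified 5% Gaussian noise, reconciles each against the carbon,
nitrogen and degree-of-reduction balances, and reports the percentage whose
consistency index stays below the 95% chi-square critical value at 3 degrees
of freedom.

## Layout

```
src/oenoflux/
  network.py    reaction-file parsing, stoichiometric model, biomass assembly,
                amino-acid pathway selection, elemental matrices, feed presets
  rates.py      batch/chemostat rate estimation, balance errors
  reconcile.py  redundancy matrix, reconciliation, chi-square test, gross errors
  mfa.py        flux solving, anaerobic constraints, normalisation, summaries
  simulate.py   ground-truth flux states, noisy measurement sets, batch profiles
  datasets.py   packaged network / composition / published rate tables
  io.py, pipeline.py   TSV/JSON/YAML IO, run configuration, end-to-end pipeline
docs/methods.md  the model, its assumptions, defaults and limitations
```
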