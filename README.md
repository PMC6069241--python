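# pyrewash

Basin-scale modelling of pyrethroid insecticide wash-off from residential
surfaces. Pyrethroids (bifenthrin, cyfluthrin, cypermethrin) applied for
structural pest control and landscape maintenance are strongly
particle-associated; storm runoff from urban catchments carries them
off-site mostly on suspended sediment, where they drive invertebrate
toxicity in receiving waters. `pyrewash` is for environmental modellers
and stormwater-quality researchers who need to link county-level
pesticide-use reporting, event hydrology and sediment transport into
per-storm predictions of pesticide export — and to test that whole chain
against monitoring campaigns.

## The model

Four pieces, run per storm event:

1. **Mass ledger.** Monthly use reports are scaled by the
   catchment-to-county developed-area ratio `A_F/A_S`, spread uniformly
   over their month, and accumulated with first-order surface
   degradation, over a 90-day lookback:

   `M_avail(t) = M_app(t) + M_avail(t−1)·exp(−k_deg·Δt) − M_w(t−1)`

   The mass available at the start of the event day is what a storm can
   mobilise.

2. **Event hydrology and sediment.** An event-lumped catchment: the
   impervious fraction loses depression storage, the pervious fraction
   loses Horton infiltration `f(t) = f_c + (f_0−f_c)e^{−kt}`; sediment
   builds up during dry weather, `M = M_max(1 − e^{−C·ADP})`, and washes
   off with effective runoff depth, `M_w,TSS = M_avail,TSS(1 −
   e^{−c·d})`.

3. **Threshold-switched pesticide wash-off** (the core). If the storm's
   sediment load `M_w,TSS` is at or below a threshold (default 10 mg),
   dissolution controls transport and the entire available pesticide
   mass is washed off. Strictly above the threshold, transport is
   particle-bound and the washed fraction follows a fitted transfer
   function `M_w/M_avail = a + b·log₁₀(M_w,TSS)` (linear-space variant
   available), clipped to [0, 1]. Equilibrium partitioning
   `f_diss = 1/(1 + K_d·C_TSS)` gives the dissolved share of the export.

4. **Evaluation.** Event mean concentration `EMC = ΣC_iV_i / ΣV_i` and
   load `EML = EMC·V`; skill scores RMSE, NSE and
   `KGE = 1 − √((r−1)² + (α−1)² + (β−1)²)` with `α = σ_sim/σ_obs`,
   `β = μ_sim/μ_obs`; PCA of the event × variable monitoring matrix with
   complete-case handling; OLS regressions between sediment and
   pesticide loads.

A synthetic-data module generates whole monitoring campaigns (wet-season
storm arrivals, summer-weighted use reports, sediment and pesticide loads
from the forward model plus observation noise) with the generating truth
stored alongside, so closed-loop identities and parameter recovery are
testable end to end.

## Worked example

```python
from pyrewash import RunConfig, SyntheticTruth, generate_campaign, run_forward

truth = SyntheticTruth(seed=1)                      # study conditions + parameters
campaign = generate_campaign(truth, n_events=20, seed=1)
result = run_forward(campaign.table, campaign.use_records,
                     RunConfig.from_truth(truth))
g = result.gof_eml["pooled"]
print(f"RMSE={g.rmse:.2e} g  NSE={g.nse:.4f}  KGE={g.kge:.4f}")
```

prints

```
RMSE=1.35e-16 g  NSE=1.0000  KGE=1.0000
```

— the forward model exactly reproduces a noise-free campaign generated by
its own equations (the closed-loop identity). With multiplicative
observation noise `σ = 0.3` on the loads the same run reports
`RMSE=1.240 g NSE=0.755 KGE=0.821`: the skill loss then measures only the
injected noise. The `examples/` directory has one short script per
capability (ledger, hydrology/sediment, threshold wash-off and fitting,
full campaign); each prints the numbers it computes and what they mean.

A thin CLI wraps the same functions:

```
pyrewash synth --n-events 20 --seed 1 --out campaign/
pyrewash run --config config.yaml --campaign campaign/campaign.csv \
             --use-reports campaign/use_reports.csv --out run/
pyrewash fit --config config.yaml --campaign campaign/campaign.csv \
             --use-reports campaign/use_reports.csv --out fit/
```

Externally compiled storm-monitoring tables load through
`pyrewash.io.read_campaign_csv` as long as they follow the documented CSV
dialect (one row per event; per-analyte `emc_*_ng_l` / `eml_*_ug`
columns).

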