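# Methods

## Scope and model structure

`pyrewash` predicts per-storm pyrethroid export from small residential
catchments as a chain of four components: a daily pesticide
mass-availability ledger, an event-lumped rainfall–runoff and sediment
surrogate, a threshold-switched wash-off rule, and an evaluation layer.
Everything operates on event totals (EMC/EML); within-event pollutograph
shapes, sewer routing and hydraulic transport are deliberately out of
scope, as are GIS/land-use processing and mechanistic dissolved-phase
extraction kinetics.

## Mass ledger

Monthly county-level use records (dated the first of the month, as
use-reporting databases conventionally do) are assumed uniform in time
and space: each record contributes `mass × (A_F/A_S) / n_days` g/day over
its month, where `A_F` is catchment area and `A_S` the county's developed
area. Daily recursion over a lookback window (default 90 days, long
enough to carry summer accumulation into the first wet-season storms):

```
M_avail(t) = M_app(t) + M_avail(t−1)·e^(−k_deg·Δt) − M_w(t−1)
```

Degradation is applied to the previous day's availability before the
previous day's wash-off is subtracted, i.e. wash-off on day *t−1*
depletes the ledger at the step into day *t*. The value attributed to a
storm is the state at the start of the event day, before that day's
wash-off. Multi-day storms are treated as single-day events; their whole
load is subtracted at the following step.

Because the dissolved regime washes the *entire* pre-degradation
availability, the literal recursion can go slightly negative (by at most
one day's degradation loss). The ledger clips to zero; small deficits
(≤ 5% of the prior availability) are logged at DEBUG, larger ones — which
indicate noisy washed-load inputs — at WARNING. Washed masses exceeding
the prior availability are rejected outright (mass creation).

**Defaults.** `k_deg` per analyte: bifenthrin 0.0077, cyfluthrin 0.0139,
cypermethrin 0.0173 d⁻¹ (half-lives of ~90/50/40 days). First-order decay
on concrete is reported over weeks-to-months in field and laboratory
studies; these are order-of-magnitude defaults, ranked by the analytes'
relative persistence, and should be replaced by site-specific values for
publication-grade runs. `A_S` must always be supplied explicitly — no
default county area is credible across users.

## Catchment surrogate

One lumped bucket per basin. Impervious fraction: runoff depth =
max(0, rain − depression storage). Pervious fraction: per-step rainfall
excess over Horton capacity `f_c + (f_0−f_c)e^(−kt)`, clock starting at
the event's first timestamp; there is no inter-event Horton recovery
bookkeeping — each event restarts the dry-capacity clock, which
overestimates infiltration for closely spaced storms (conservative for
runoff). Depression storage applies to the impervious fraction only.

Sediment: saturating-exponential build-up over the antecedent dry period
and exponential-in-depth wash-off (the standard urban-quality functional
forms), with the post-storm residual carried into the next dry period.
The coefficients are configuration, not physics: defaults
(`M_max = 500 mg`, `C = 0.03 d⁻¹`, `c = 0.02 mm⁻¹`, exponent 1) were
chosen once so that a typical wet-season campaign spans sediment loads on
both sides of the 10 mg regime threshold (roughly a 25/75 dissolved/
particle-bound split), matching the qualitative structure of the
monitoring data the model is meant for.

## Threshold-switched wash-off

The regime switch is a strict inequality: sediment load exactly at the
threshold (default 10 mg) is dissolved-controlled; only strictly larger
loads are particle-bound. The threshold is configurable — a fixed value
is a simplification, and a transition range would be the natural
refinement.

*Dissolved regime*: the whole available mass is exported. This is a
deliberate conservative upper bound standing in for first-order
rainfall-extraction kinetics, which are out of scope; it overpredicts
low-sediment storms and users should treat dissolved-regime EMCs as
bounding values.

*Particle-bound regime*: washed fraction `a + b·g(M_w,TSS)` with `g`
either identity or log₁₀ (default log₁₀ — sediment loads span orders of
magnitude, and a flat-then-rising fraction is a broken stick in log
space), clipped to [0, 1] and never exceeding availability. An
alternative predictor regresses pesticide load directly on sediment load;
dividing the fitted line by event runoff volume converts it to an EMC
relation.

Partitioning: `f_diss = 1/(1 + K_d·C_TSS)` with TSS as the sole sorbent
phase. Default `K_d`: bifenthrin 10⁵, cyfluthrin and cypermethrin
5×10⁴ L/kg — the usual pyrethroid sediment range, with bifenthrin most
particle-associated.

## Fitting

Transfer coefficients are ordinary least squares of washed fraction on
`g(M_w,TSS)`, restricted by default to particle-bound storms (the
relation only claims validity there); standard errors come from the OLS
covariance.

The degradation rate is fitted from dissolved-regime storms, where the
observed load equals the ledger availability and hence depends on
`k_deg`: nonlinear least squares of log observed load on log modelled
availability. Because the ledger is driven by *observed* (noisy) loads of
earlier storms, storms whose availability is dominated by recent wash-off
subtraction inherit amplified noise; a second weighted pass propagates
that history noise into per-event variances,
`σ_i² ∝ 1 + Σ_j (w_j e^(−kΔt_ij)/avail_i)²`, which automatically
downweights low-information "echo" storms. Unweighted fitting is visibly
biased and overconfident on synthetic campaigns; the weighted estimator
is calibrated (recovery z-scores within ±1.5 across seeds at σ = 0.01).

## Evaluation

RMSE, NSE and KGE are computed exactly as defined, with Pearson
correlation and sample (N−1) standard deviations in the KGE components —
the conventional definition. Constant observations or a zero observed
mean raise explicit errors rather than returning NaN. Pooled scores
concatenate the per-analyte observed/simulated series.

PCA standardizes columns to unit sample variance (the 11 monitoring
variables mix days, mm, m³ and masses, so the correlation matrix is the
only defensible choice); the site variable enters as a 0/1 indicator;
rows with any missing value are dropped (complete-case, no imputation).
All components are returned; `retained_count` is the smallest set
reaching a cumulative-variance target (default 0.70).

## Synthetic campaigns

Storm arrivals: exponential dry gaps (mean 10 days) within an
October–April wet season; dates falling in the dry season jump to the
next season start, producing the long first-of-season antecedent dry
periods. Depth and duration are lognormal (median 8 mm / σ = 0.9; median
6 h / σ = 0.5), depths resampled below the 2 mm sampling trigger.
Hyetographs are constant-intensity blocks. Use reports: fixed monthly
pattern, summer (Jun–Aug) upweighted ×2.5, county totals around 10⁵ g per
analyte per month against a 5×10⁸ m² developed reference area.

Loads carry multiplicative lognormal observation noise; the
particle-bound fraction can carry additive Gaussian noise; optional
masking NaNs one analyte in a randomly chosen subset of events to emulate
incomplete records. True (noise-free) loads feed the generator's own
ledger, so a zero-noise campaign is exactly reproducible by the forward
pipeline — the closed-loop identity the acceptance checks assert.

What the generator does **not** emulate: correlation between storm size
and use intensity, multi-site rainfall correlation beyond shared
parameters, pollutograph dynamics, laboratory censoring (non-detects),
and any covariance between available mass and sediment supply. In
particular, load-on-load regressions are much weaker on these synthetic
campaigns than fraction-on-load regressions, because availability varies
independently of storm size here; passing tests therefore demonstrate
internal consistency and estimator calibration, not field validity.

## Numerical choices and degenerate inputs

Masses in g (pesticide) and mg (TSS); volumes m³ (1 mm over 1 m² =
10⁻³ m³); EMCs ng/L (pesticide) and mg/L (TSS), so `EMC[ng/L] ×
V[m³] = EML[µg]` exactly per table row. Mass-balance tolerance 10⁻⁹
relative. Zero runoff with positive wash-off is an error; zero runoff
with zero wash-off returns zero EMC. Degenerate regression predictors
(zero variance) are rejected; a constant response returns slope 0 and
R² 0. Ledger linearity, window independence and non-negativity are
asserted as property tests.

## Known limitations

- The dissolved regime's export-everything rule is an upper bound, not a
  kinetic model.
- Sediment and hydrology coefficients are uncalibrated defaults; any real
  application must calibrate them against local monitoring.
- County-to-catchment apportionment by developed-area ratio ignores
  spatial clustering of applications.
- The fixed 10 mg threshold makes predictions discontinuous in sediment
  load; `regime_discontinuity` reports the jump size so users can judge
  its impact.

## Problem sizes

Test and acceptance runs use 15–100-event campaigns and 90-day ledgers —
ample for the identities and recovery checks they assert, and the same
order as multi-year monitoring programmes (tens of sampled storms).
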