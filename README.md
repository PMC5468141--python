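# pumaconnect

Movement-based habitat quality and circuit-theory connectivity for
wide-ranging carnivores.

`pumaconnect` re-implements, as a tested and reusable pipeline, a
movement-to-connectivity analysis for large carnivores (pumas are the
motivating species): GPS collar fixes are screened, each individual's
space use during bouts of active movement is estimated with a Brownian
bridge movement model (BBMM), habitat quality for movement is modeled
from the BBMM surfaces with spatial linear mixed models and all-subsets
AIC averaging, quality is converted to landscape conductance, statewide
omnidirectional connectivity is computed with circuit theory, and
connectivity pinch points at risk from expanding development and traffic
are flagged. It is aimed at movement ecologists and connectivity
planners who want the whole chain — from raw fixes to at-risk pinch
points — scripted, seeded and unit-tested.

Because real collar data of this kind are typically withheld, the
package ships a first-class synthetic-data module that generates
landscapes, telemetry, roads and land-use projections with the
statistical structure the analysis assumes, so every stage runs and is
validated at desk scale.

## The model chain

**Telemetry screening.** Fixes with positional dilution of precision
(PDOP) > 10 are dropped; putative den/kill-site fixes — those within
200 m of both temporal neighbors — are removed iteratively; consecutive
fixes more than 24 h apart contribute no movement step.

**Brownian bridge movement model.** For a step of elapsed time *T*
between fixes *a* and *b*, the position at time fraction α is

    z(α) ~ N( (1−α)a + αb ,  σ²(α) I ),
    σ²(α) = T α(1−α) σ²m + ((1−α)² + α²) δ²,

with σ²m the Brownian motion (mobility) variance and δ the per-coordinate
location-error SD (default 26.2 m). σ²m is estimated by maximizing the
leave-one-out likelihood of odd-numbered fixes under the bridges spanned
by their even-numbered neighbors. The occurrence surface averages the
gridded bridge densities with weights T_i/ΣT_i and keeps cells with
probability > 1e-5.

**Habitat quality.** With y = ln BBMM probability at random points in
each individual's buffered surface,

    y = Xβ + b(animal) + ε,   Σ_a = σ²_u J + τ² I + σ²_s exp(−D/ρ),

is fitted by maximum likelihood (variance components REML-adjusted,
estimated once under the global model). All 192 hierarchical subsets of
the seven habitat terms plus a ruggedness quadratic are fitted; Akaike
weights give per-term weights of evidence w₊, model-averaged β̃ and
unconditional SEs; fixed-effect uncertainty uses the cluster-robust
(Huber–White) sandwich estimator. The averaged linear predictor is
mapped and min–max rescaled to conductance in (1e-3, 1], with open water
forced to the minimum.

**Connectivity and risk.** Cells become nodes of a resistor network
(8-neighborhood, mean-conductance edges, √2 diagonal scaling); one-cell
edge strips of the map rectangle act as collapsed terminals; east–west
and north–south solves of the graph Laplacian are summed into an
omnidirectional current map after filling out-of-boundary cells with
normal draws matching the in-boundary conductance distribution. Pinch
points are cells in the 95th percentile of summed current; risk overlays
select pinch cells in the 90th percentile of projected impervious-surface
increase and road mile markers (1-km disc rule) whose traffic exceeds,
or is projected to cross, the 3,000–5,000 vehicles/day deterrence
thresholds.

## Worked example

Run the full synthetic pipeline (48×48 landscape, 6 animals × 150
fixes) and print the report:

```bash
pumaconnect run-all --set n_rows=48 --set n_cols=48 \
    --set n_individuals=6 --set n_fixes=150 --set seed=4 \
    --out-dir demo_run
pumaconnect report --run-dir demo_run
```

which prints (abridged):

```
{
  "delta_aic": 38.25,
  "risk_site_counts": {"development": 1, "traffic_current": 2,
                       "traffic_future": 6}
}
   variable   w_plus       beta       se
young_adult 1.000000  -0.823677 0.284860
       male 1.000000   0.136158 0.309693
 ruggedness 0.999992   0.252862 0.040919
      shrub 0.992092   0.202655 0.050937
  human_mod 0.584914  -0.105940 0.070920
  ...
  intercept      NaN -10.819741 0.279719
```

Reading the output: the global model beats the intercept-only null by
38 AIC units (> 10 means the habitat terms genuinely explain movement
probability). The tracks in this scenario were simulated with positive
selection for ruggedness and shrub cover and avoidance of human
modification; the averaged model recovers both strong positive terms
with w₊ ≈ 1 and the negative human-modification coefficient. The
indicators (age, sex, capture area) are forced into every candidate
model, so their w₊ is exactly 1. `demo_run/` also holds the quality,
conductance and current maps (`*.asc`), the per-animal BBMM summary, the
filter report and the risk-site table.

Library use mirrors the CLI:

```python
from pumaconnect import RunConfig, run_all
res = run_all(RunConfig(seed=4), save_artifacts=False)
print(res.averaged.table())        # w+, averaged beta, unconditional SE
print(res.global_null["delta_aic"])
```

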