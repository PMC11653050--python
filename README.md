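# glycowear

Association analysis between continuous glucose monitor (CGM) data and
multi-rate wrist-wearable physiology plus dietary nutrients.

The package is aimed at biostatisticians working with cohorts like the
PhysioNet *BIG IDEAs Lab Glycemic Variability and Wearable Device Data*
accession: ~16 participants in the high-normal/prediabetic HbA1c band, each
monitored for 8–10 days with a 5-minute interstitial glucose sensor (Dexcom
G6 style) and an Empatica-E4-style wrist device recording triaxial
acceleration (ACC, 32 Hz), heart rate (HR, 1 Hz), skin temperature (TEMP,
4 Hz), electrodermal activity (EDA, 4 Hz), blood volume pulse (BVP, 64 Hz)
and interbeat intervals (IBI, event based), together with a food log of
per-meal nutrient totals.

## What it computes

1. **Alignment.** Every channel is reduced to the 5-minute CGM grid (ACC via
   the Euclidean norm `sqrt(x² + y² + z²)`); each variable gets 3-point
   (10-minute) rolling mean and sample-SD summaries.
2. **Lag correlation profiles.** Spearman's ρ between a glucose summary at
   time *t* and a channel summary at *t + ℓ* for lags
   ℓ = −120, −105, …, +120 min (negative ℓ = physiology measured before
   glucose), pooled across participants, for the statistic pairs
   mean–mean, mean–SD and SD–SD.
3. **Postprandial excursion slopes.** For each meal, the pre-rise trough,
   post-meal peak and post-peak nadir of the glucose curve; rise and fall
   tangent slopes `Δy/Δx` in mg/dL·min⁻¹; channel mean/SD features over
   the meal→peak, peak→nadir and the three 30-minute pre-meal windows; and
   summed meal nutrients (calories, carbohydrate, fiber, sugar, protein,
   fat).
4. **Inference.** Backward-elimination multiple regression of the rise/fall
   slopes on the physiology and nutrient predictors (retention criterion
   *P* < .20, optional forced sex adjustment), and median-split
   combination-pattern one-way ANOVA (codes such as `TEMP:ACC:HR:EDA=1011`,
   1 = above the pooled median) with the all-below-median group as control.
5. **Synthetic cohorts.** A seeded generator produces complete cohorts in
   exactly the input dialects — CGM tables, E4 channel files, food logs,
   participant tables — with configurable ground-truth couplings
   (carbohydrate-driven excursions with fiber damping, lagged channel–glucose
   couplings), so the full pipeline runs and is validated without any data
   download.

## Worked example

```sh
cat > sim.yaml <<'YAML'   # a small cohort; omit --config for the full default
n_participants: 2
days_range: [8, 8]
day_seconds: 9000
seed: 5
YAML
glycowear simulate --config sim.yaml --out demo/sim
glycowear ingest  --sim demo/sim --out demo/cohort
glycowear align   --in demo/cohort --out demo/aligned
glycowear lagcorr --in demo/aligned --out demo/lag
glycowear excursions --in demo/cohort --grids demo/aligned --out demo/design.csv
glycowear regress --design demo/design.csv --response rise --features mean --out demo/reg
glycowear anova   --design demo/design.csv --response rise --vars TEMP_mean,EDA_mean --min-group-n 2 --out demo/anova
```

On a small synthetic cohort this prints, stage by stage (the simulator
config used here is 2 participants × 8 shortened days, seed 5;
`demo/sim/sim_config.yaml` records it in full):

```
wrote synthetic cohort (2 participants) to demo/sim
ingested 2 participants -> demo/cohort
aligned 2 participants -> demo/aligned
wrote 18 profiles -> demo/lag/lag_correlations.csv
47 excursions (48 meals) -> demo/design.csv
rise_slope ~ mean: retained ['ACC_mean', 'ACC_30_mean', 'EDA_60_mean', 'BVP_60_mean', 'IBI_60_mean', 'carbohydrate', 'sugar'] (n=47, R2=0.650) -> demo/reg
F=0.451 (df 3,43), p=0.7181; dropped groups (< n=2): []
```

Reading the regression output (`demo/reg/rise_mean_coefficients.csv`):
carbohydrate survives elimination with a positive coefficient
(0.035 mg/dL·min⁻¹ per g, *t* = 5.11 — more carbohydrate → steeper
postprandial rise), matching the generator's ground-truth kernel; most of
the other survivors are chance retentions at the deliberately permissive
*P* < .20 criterion, which is expected on a 47-row table. The
`lag_correlations.csv` table holds ρ, *P* and *n* per channel, statistic
pair and lag; in this run the EDA SD profile against the glucose mean peaks
at −15 minutes with ρ = −0.55, recovering the configured EDA coupling
(lag −15, strength −0.5).

Every stage is also available as a library function (`glycowear.ingest`,
`.align`, `.lagcorr`, `.excursion`, `.inference`, `.synthetic`); the CLI is
a thin wrapper. `glycowear reproduce --accession DIR --out DIR` runs the
entire analysis on a local data copy laid out like the simulated cohorts
and emits all tables (column maps for other dialects go in a YAML config).

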