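# ricerisk

Probabilistic human-health risk assessment of **inorganic arsenic (iAs) in
rice**. Rice grown in flooded paddies takes up arsenite and arsenate; in
populations where rice is a staple — Brazil's adult per-capita intake is about
167 g of raw rice per day — dietary iAs is a Group 1 carcinogen exposure worth
quantifying. `ricerisk` estimates the age-stratified average daily dose, the
incremental lifetime cancer risk (ILCR) and the hazard quotient (HQ) by Monte
Carlo simulation, fits parametric concentration models to survey data, and
evaluates mitigation scenarios such as imposing a maximum contaminant level
(MCL). It is aimed at exposure-assessment and food-safety researchers.

## Model

For age group *j* with ingestion rate *IR*ⱼ (g/day), exposure duration *ED*ⱼ
(years), exposure frequency *EF*ⱼ (days/year) and body weight *BW*ⱼ (kg), the
average daily dose of a contaminant at concentration *C* (mg/g raw rice) is

    ADDⱼ = (C · IRⱼ · EDⱼ · EFⱼ) / (BWⱼ · AT),   AT = EDⱼ · 365 days

(the duration cancels against the averaging time). Lifetime metrics weight
each group by its share of the lifetime *LT* = 70 y:

    ILCR = Σⱼ ADDⱼ · SF · EDⱼ/LT        SF  = 1.5 (mg/kg-day)⁻¹
    HQ   = Σⱼ (ADDⱼ/RfD) · EDⱼ/LT       RfD = 0.003 mg/kg-day

Concentration uncertainty is propagated by Monte Carlo (default 100,000
iterations): each iteration draws one concentration from a fitted normal,
lognormal or exponential model (maximum likelihood, lowest AIC selected;
normal draws zero-truncated) and applies it to every age group. Because both
metrics are linear in *C*, the mean ILCR equals the closed-form ILCR at the
distribution mean — the engine's built-in oracle — and `ILCR = HQ·SF·RfD`
holds to machine precision on shared draws.

Since real survey microdata (per-age intake and body-weight tables, raw
concentration measurements) are not redistributable, the `synthetic_data`
module generates realistic stand-ins: stratified concentration datasets
(white market rice ~ truncated Normal(100.17, 44.62) ng/g, n=64; brown rice
n=90 split 69 farm / 21 market with cultivar labels) and a 27-bin exposure
table whose ED-weighted mean intake is exactly 156.6 g/day with adult bins at
167 g/day and EF = 6/7 · 365 ≈ 312.86 days/year.

## Worked example

```sh
ricerisk generate-data --out-dir data --seed 1
ricerisk fit --dataset data/concentrations_brown.csv
```

```
family       params                                         logLik          AIC  selected
normal       mean=79.71, sd=52.52                        -484.2041     972.4081
lognormal    mu=4.134, sigma=0.7447                      -473.2578     950.5156  *
exponential  rate=0.01255                                -484.0532     970.1063
```

The synthetic brown-rice survey is best described by a lognormal (μ = 4.13,
σ = 0.74 on the log scale) — the farm/market mixture is right-skewed, so the
lognormal beats the normal by ~22 AIC points. Assessing the white dataset:

```sh
ricerisk --quiet assess --dataset data/concentrations_white.csv \
    --exposure-table data/exposure_table.csv \
    --iterations 100000 --seed 1 --out white_risk
```

```
selected distribution: normal {'mean': 98.92631128311407, 'sd': 35.1727875624302}
lifetime ILCR mean 4.07e-04, p95 6.43e-04
lifetime HQ mean 9.04e-02 (below 1)
```

An excess lifetime cancer risk around 4 × 10⁻⁴ — four in ten thousand, well
above the 10⁻⁶–10⁻⁴ range usually deemed acceptable — while the hazard
quotient below 1 indicates no concern for non-cancer effects. Mitigation
scenarios from a YAML config (`kind`: `mcl_filter`, `substitute_distribution`
or `exclude_ages`):

```sh
ricerisk --quiet scenarios --dataset data/concentrations_white.csv \
    --exposure-table data/exposure_table.csv --config scenarios.yaml \
    --iterations 100000 --seed 1 --out scen
```

```
white MCL 100 ng/g: ILCR 2.86e-04, reduction 29.79%
white MCL 75 ng/g: ILCR 2.08e-04, reduction 48.95%
white MCL 50 ng/g: ILCR 1.43e-04, reduction 64.77%
no white rice <= 6 years: ILCR 3.40e-04, reduction 16.47%
```

Each MCL scenario drops samples above the limit, refits the concentration
model within the baseline's family, and re-simulates with the same seed
(common random numbers); reductions are reported against the baseline mean
ILCR. Every output directory includes a JSON record of seed, iterations,
parameter convention and truncation flag, so reruns are bit-identical.

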