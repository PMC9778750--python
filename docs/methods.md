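# Methods

## Dose and risk model

The package implements the standard chronic dietary exposure chain for a
carcinogenic food contaminant, stratified into age groups so that exposure
factors can vary over a lifetime. For group *j*:

- **ADD** (average daily dose, mg/kg-day) = C · IRⱼ · EDⱼ · EFⱼ / (BWⱼ · AT),
  with the averaging time AT defined as EDⱼ · 365 days. Defining AT over the
  exposure duration (rather than the whole lifetime) makes ADD a *dose rate
  while exposed*; the lifetime weighting EDⱼ/LT is applied separately in the
  risk sums, not inside ADD. A consequence worth knowing: ADD is independent
  of EDⱼ, which cancels.
- **ILCR** = Σⱼ ADDⱼ · SF · EDⱼ/LT with SF = 1.5 (mg/kg-day)⁻¹ (oral iAs).
- **HQ** = Σⱼ (ADDⱼ/RfD) · EDⱼ/LT with RfD = 0.003 mg/kg-day.

These two sums are proportional: ILCR = HQ · SF · RfD for any fixed
concentration and table. The engine computes both from the same draws, so the
identity holds to 1e-12 relative and is asserted in the test suite. ILCR is
interpreted as an excess lifetime cancer probability; HQ > 1 flags potential
non-cancer (cardiovascular, dermal) effects.

Concentrations are carried in ng/g throughout the package; the single 1e-6
conversion to mg/g lives in `exposure_model.add_coefficient` so the unit
change has exactly one auditable location — misplaced powers of ten are the
classic failure mode of this calculation.

## Concentration models

Candidate families are normal, lognormal and exponential, fit by maximum
likelihood with closed-form estimators (normal and log-scale sd use the
n-divisor MLE; descriptive statistics report the n−1 sample sd — both are
surfaced, never mixed). AIC = 2k − 2 log L ranks the fits; ties break by the
fixed order normal > lognormal > exponential. Values ≤ 0 are excluded from
the lognormal fit only, with a logged count. Constant-valued data make the
normal/lognormal likelihood unbounded; such fits report log L = +∞
(AIC = −∞) and the tie-break selects the normal point mass, which keeps the
degenerate pipeline exact end to end. One test cross-checks all three AICs
against R's fitdistrplus as an independent oracle.

**Truncation.** Concentrations are physically nonnegative, but a fitted
normal (e.g. mean 30.55, sd 16.85 after a strict MCL filter) can put a few
percent of its mass below zero. Sampling therefore rejects and redraws
negative normal draws by default (`truncate_at_zero`). Truncation shifts the
mean upward — Normal(100.17, 44.62) truncated at zero has mean ≈ 101.6 — and
the closed-form truncated mean μ + σφ(μ/σ)/Φ(μ/σ) is used wherever the
distribution mean is needed, verified against numerical integration in the
tests. The flag is recorded in all output metadata.

**Lognormal parameter conventions.** Log-scale (μ, σ of log values) is the
default and the statistically correct reading of a lognormal fit. Because
published lognormals quoted as "(mean; sd)" are ambiguous, the sampler also
accepts `param_convention="arithmetic"`, which treats the pair as arithmetic
moments and converts via σ² = ln(1 + sd²/mean²). The two readings differ
drastically when μ and σ are log-scale values of order 4 and 1: the mean
concentration is exp(μ + σ²/2) ≈ 90.5 ng/g under log-scale but 4.1 ng/g under
arithmetic — a ~22× collapse of the implied risk. The acceptance suite
demonstrates both behaviors (brown/white mean-ILCR ratio ≈ 0.90 vs ≈ 0.040)
because this conflation is a documented pitfall in published rice-arsenic
risk figures; the package takes no position on any specific study's intent.

## Monte Carlo engine

Each of the `iterations` (default 100,000) draws a single concentration and
applies it to **all** age groups: an iteration represents one lifetime lived
under one long-run mean concentration, giving full between-group correlation.
This choice affects percentiles but not means; an independent-draw-per-group
mode is deliberately out of scope. Exposure factors are fixed constants per
age bin — intake/body-weight surveys rarely support a defensible variability
distribution, and fixing them keeps the uncertainty budget attributable to
the concentration alone.

Summaries report the mean and empirical percentiles (linear interpolation
between closest order statistics, so p95 values are bit-reproducible given a
seed) plus the Monte Carlo standard error sd/√n. All randomness flows from a
single `numpy` `default_rng(seed)`; identical config ⇒ bit-identical output.

Linearity in concentration yields the engine's oracle: the MC mean ILCR must
match `closed_form_ilcr(distribution_mean(dist), …)` within Monte Carlo
error, asserted for all three families.

## Mitigation scenarios

Three intervention kinds, each evaluated against a baseline run with the same
iterations, seed and convention (the shared seed gives common random numbers,
so reported reductions carry far less noise than two independent runs):

- `mcl_filter`: remove samples above a maximum contaminant level, refit
  **restricted to the baseline's selected family** (small retained samples
  could otherwise flip family and confound the comparison), simulate.
- `substitute_distribution`: simulate a replacement concentration model
  directly (e.g. a cleaner cultivar or subgroup).
- `exclude_ages`: zero the ingestion rate of bins starting below
  `max_excluded_age + 1` years ("no consumption ≤ 6 years" zeroes the infant
  bin through the 6-year bin). The boundary is a documented convention.

Reductions are `100 · (1 − mean ILCR_scenario / mean ILCR_baseline)`. For
concentration-side interventions the table factors cancel in the ratio, so
reductions are exposure-table invariant (tested exactly, thanks to shared
draws); for age exclusion the reduction equals the zeroed bins' share of the
baseline ILCR, a deterministic identity also tested exactly.

## Synthetic study conditions

The generator emulates the structure of a Brazilian rice survey; its defaults
are the study conditions used throughout the tests:

- **White rice**: zero-truncated Normal(100.17, 44.62) ng/g, n = 64, market.
- **Brown rice**: n = 90 = 69 farm + 21 market. The farm stratum is composed
  of cultivar substrata (Irga 424: 80.7 ± 22.35, n = 19; Puitá: 46.6 ± 31.69,
  n = 48; 2 unlabelled at the pooled farm moments 57.36 ± 34.36) and the
  market stratum has moments 154.91 ± 44.8 — all lognormal via moment
  matching, since pooled brown concentrations are lognormal-selected. The
  pooled farm mean (≈56.3) sits slightly below the nominal 57.36 because the
  substrata take priority; both are well inside the 3-SE test bands.
- **Exposure table**: 27 bins — "<1" (0.33–1 y, ED = 8/12, solid food starting
  at 4 months), yearly bins 1–19, 5-year bins to 35, 10-year bins to 65, and
  65–70 — totalling ED ≈ 69.67 y. Bins from age 10 use the adult survey
  intake of 167 g/day; younger bins follow a rising shape (0.4 at "<1" up to
  1.05 at age 9, relative) scaled so the ED-weighted all-age mean is exactly
  156.6 g/day. The binding constraints are the two published aggregate means;
  the child shape is only a plausibility device. Body weight is interpolated
  at bin midpoints through anchors (8 kg infant → 60 kg adult plateau → mild
  decline after 65) that are fixture constants, not population claims.
  EF = 6/7 · 365 ≈ 312.857 days/year everywhere (a staple eaten 6 days/week).
- **As–Cd pairs**: bivariate normal with a target Pearson correlation
  (default r = 0.049, n = 69), pairs with negative components redrawn.
  Cadmium moments (25 ± 12 ng/g) are synthetic fixture choices.

What the generator does **not** emulate: real per-age intake microdata (so
absolute per-age risks are not reproducible and are not claimed), city-level
concentration structure, detection limits/censoring, measurement error, or
within-sample replicate variance. Passing tests demonstrate correctness of
the machinery under these stylized conditions, not the accuracy of any
specific population risk estimate.

## Numerical choices and problem sizes

- Percentile estimator: linear interpolation (numpy default), documented for
  bit-reproducibility.
- Rejection sampling for truncation rather than inverse-CDF truncated
  sampling: keeps the draw stream simple and exact; the acceptance rate is
  ≥ 96.5% for every distribution used here.
- Seeds: every stochastic test and the acceptance script fix seeds; child
  generators are spawned from a single top-level `default_rng`.
- Problem sizes: Monte Carlo runs use 100,000 iterations (the headline
  configuration; ~0.5 s per run), oracle-equivalence and convention checks
  50,000–100,000, replicate studies (AIC selection, correlation power,
  generator calibration) 200 replicates at the survey n of 64–90. The full
  suite runs in well under a minute.

## Known limitations

- Oral route only; no dermal/inhalation, bioavailability or cooking-loss
  adjustment, and no rice-derived products (flour, infant cereal).
- No censored-data likelihoods or goodness-of-fit testing beyond AIC ranking;
  no Bayesian fitting.
- One-dimensional uncertainty analysis: no nested variability × uncertainty
  simulation, no correlation between exposure factors.
- The ILCR aggregates all arsenic-associated cancer sites; site-specific
  risks are not identifiable from a slope-factor model.
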