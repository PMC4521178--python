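# Methods

## Scope and data model

`glycurve` analyses cohorts phenotyped with three instruments: fasting
blood chemistry, a euglycemic-hyperinsulinemic clamp, and a liquid
mixed-meal tolerance test (LMMTT) sampled at 0, 30, 60, 90, 120 and
240 min. Canonical internal units are mmol/l for glucose and mU/l for
insulin; conversion (18.0 mg/dl per mmol/l, 6.0 pmol/l per mU/l)
happens only at the I/O boundary. The glucose factor is deliberately
18.0 rather than the molar-mass 18.016 so that the protocol equivalence
90 mg/dl = 5 mmol/l is exact. A meal series may sit on any strictly
increasing grid starting at 0; operations needing a specific sample
(the 30-min point for the insulinogenic index) raise rather than
interpolate. There is no imputation anywhere: a subject lacking the
inputs for an index gets a null for that index plus a recorded
exclusion reason, and the rest of the cohort proceeds.

## Index definitions and conventions

The panel is standard; the places where a convention had to be chosen
are:

* **IAUC convention.** Incremental AUC defaults to *net* (total
  trapezoidal AUC minus baseline×duration), which can go negative if
  the curve dips below fasting. A *positive_only* variant (trapezoid of
  max(v − v₀, 0) with exact linear-crossing interpolation) is available
  behind a flag; it is never smaller than the net value. Net is the
  default because it is the simpler reading of "incremental AUC by the
  trapezoidal rule" and is what the Matsuda computation downstream
  consumes; both are reported side by side in pipeline output so the
  choice is auditable.
* **Matsuda grouping.** The composite index is computed as
  10⁴/√(G₀·I₀·IAUC_glu·IAUC_ins), the square root over the full
  four-term product — the grouping that keeps the index on the familiar
  ~1–3 scale and dimensionally mirrors the original composite (a
  geometric mean of a fasting term and a dynamic term). The alternative
  reading (root over G₀·I₀ only) is available as
  `grouping="fasting-only"` and flagged in output metadata. The classic
  mean-concentration Matsuda form is a separately named function
  (`matsuda_isi_classic`) because it is a genuinely different statistic
  and the two must not be conflated silently.
* **ISI-clamp scaling.** The raw quotient (M/LBM)/I_ss is ~0.14 for
  physiologic values (~10 mg·kg⁻¹·min⁻¹ at ~70 mU/l); the default ×100
  display scaling puts the index on the conventional ~10–15 scale and
  is recorded in panel metadata. `scale=1` gives the raw quotient. The
  clamp schema takes the absolute infusion rate (mg/min) plus lean mass
  and normalises internally, since bedside logs record absolute pump
  rates.
* **Degenerate denominators.** HOMA-B is undefined at fasting glucose
  ≤ 3.5 mmol/l and raises a domain error naming the singularity. A flat
  0→30-min glucose change makes the insulinogenic index undefined; it
  becomes a null with an exclusion record rather than ±∞, because group
  summaries of this index implicitly assume such exclusions.

## The DI hyperbola and off-curve scores

Appropriate beta-cell compensation is modelled as the strict hyperbola
B = k/S with exponent fixed at −1; no free-exponent power law is
fitted, since the hyperbolic form is the model being assumed, not
estimated. Fitting defaults to the log scale, where least squares on
log B = log k − log S has the closed form k̂ = exp(mean(log(S·B))) (the
geometric mean of the products): multiplicative physiologic noise makes
this the statistically natural scale, the estimator is exactly
equivariant under rescaling of either axis, and the per-subject
residuals r_i = log(S_i·B_i) − log k̂ average to zero by construction.
Linear-scale least squares (closed form k̂ = Σ(B/S)/Σ(1/S²)) is
retained for comparison. The off-curve score of any point is
r = log(S·B) − log k: 0 on the curve, negative below it
(under-compensation). Group placement reports arithmetic group means of
(S, B) and of the scores, ordered worst first.

Two sensitivity axes are supported — ISI-clamp (default, mirroring how
such cohorts are usually plotted) and Matsuda ISI (which defines the
oral DI) — with the choice recorded in output.

A note on reference populations: a pooled fit absorbs part of any
group-level deficit into k̂ (with three equal groups of which one has
deficit δ, the deficit group's pooled-fit mean score is ⅔·log δ).
Recovering a deficit *as specified* therefore requires fitting the
curve on the normally-compensating reference subjects and scoring the
suspect group against that fit; the validation suite and acceptance
script do exactly this. Pooled fits remain correct for *ranking* groups,
since the reference choice shifts all scores equally.

## Group statistics

* **ANCOVA.** Each index is compared across groups by the linear model
  y ~ group + covariate (age by default), with a partial F test of the
  group factor (statsmodels OLS/anova_lm). Adjusted group means are
  evaluated at the grand covariate mean. Pairwise contrasts use the
  model's standard errors with Bonferroni correction over the number of
  pairs. A constant covariate is dropped automatically, which reduces
  the model exactly to one-way ANOVA. Constant outcomes and groups with
  fewer than two subjects are errors.
* **Repeated measures.** The excursion matrix (subject × timepoint,
  complete cells only — subjects with missing cells must be excluded)
  is analysed by the classic split-plot sums-of-squares decomposition,
  which partitions exactly: SS_total = SS_group + SS_subjects(group) +
  SS_time + SS_group×time + SS_error. Group is tested against
  subjects-within-groups, time and interaction against the within
  error. The implementation is hand-authored (the installed statsmodels
  repeated-measures tool handles within-subject factors only) and is
  cross-checked against pingouin's mixed ANOVA in the test suite.
  Sphericity is not assumed: Greenhouse–Geisser ε is computed from the
  pooled within-group covariance of the timepoints and the corrected
  p-values (df scaled by ε) are reported alongside the uncorrected
  ones, with ε clipped to its theoretical range (1/(T−1), 1]. When the
  analysis is run on incremental values the baseline column has zero
  variance and ε sits at its lower bound; the corrected p-value remains
  valid, just maximally conservative. How to age-adjust a split-plot
  design is genuinely under-specified in practice; here the covariate
  enters the between-subject stratum only (ANCOVA on subject means) —
  a time-constant covariate cannot explain within-subject variation —
  and the adjusted group F is always co-reported with the unadjusted
  one rather than replacing it. Per-timepoint pairwise group contrasts
  use the pooled within-group error at that timepoint with Bonferroni
  over pairs only (not pairs × timepoints), matching how per-timepoint
  differences are conventionally reported; p-values are two-sided and
  0.05 is an annotation, never a filter.
* **Bootstrap.** Group DI means get percentile 95% CIs by resampling
  subjects within group (default 1000 draws), seed-reproducible.

## The synthetic-cohort generator

The generator exists so that every pipeline stage can be validated by
parameter recovery; its structure is the weakest model that reproduces
the phenomena the analysis targets.

Per subject i in group g:

1. true sensitivity S_i ~ lognormal, parametrised by the group's
   arithmetic mean and SD (clamp scale);
2. true secretion B_i = δ_g·k_g/S_i·exp(ε_i), ε_i ~ N(0, σ_B²), with
   hyperbola constant k_g and compensation deficit δ_g ∈ (0, 1];
3. fasting insulin FI_i = c_FI/S_i × lognormal(σ_FI) (anti-correlated
   with sensitivity, as hyperinsulinemia compensates resistance), with
   c_FI = 69 mU/l per sensitivity unit; fasting glucose ~ N truncated
   to (3.6, 7.0) mmol/l (normoglycemic inclusion);
4. glucose curve G(t) = FG_i + A_i·h(t) with the fixed kernel
   h(t) = (t/45)²·exp(2(1 − t/45)) — unimodal, peak at 45 min, h(0)=0,
   h(240)≈0.005. A parametric kernel rather than an ODE minimal model
   keeps the ground truth interpretable; the analysis only ever sees
   sampled points, so curve mechanics beyond shape would add nothing a
   test could use. Amplitude A_i ∝ 1/(S_i·B_i) within group (low
   disposition index ⇒ high excursion), normalised so the group-mean
   net incremental glucose AUC equals the group's target;
5. insulin curve I(t) = FI_i + β_i·h(t − 10 min), with β_i solved so
   that total-AUC(insulin) = B_i × total-AUC(glucose) on the sampling
   grid. This choice makes the computed insulin secretion index equal
   the ground-truth B_i exactly in the noiseless limit (the closed-loop
   property the validation relies on) and lands the implied insulin
   IAUCs at realistic magnitudes (~10⁴ mU·min/l) for secretion indices
   of ~10 mU/mmol. Negative β (possible in extreme noise draws) is
   handled by resampling the subject;
6. clamp record M_i = S_i·I_ss,i·LBM_i/100 with steady-state insulin
   I_ss ~ N(70, 8²) mU/l — a plausible steady state for a
   40 mU·m⁻²·min⁻¹ infusion, recorded as a preset constant — so the
   computed ISI-clamp recovers S_i exactly.

All bound enforcement is by resampling, never clipping, to preserve
distribution shape near the bounds; all draws come from a single seeded
generator, so cohorts are byte-reproducible.

### Preset calibration

The three study-like presets encode group sizes 14/21/24 and moment
targets for a lean young Asian male cohort: sensitivity means
14.2/12.9/8.8 (SDs reconstructed as SE×√n from standard errors of
1.2/1.2/0.6 at those n), fasting glucose 4.41/4.12/4.12 mmol/l, ages
29.6/25.2/24.3 y, and net glucose-IAUC targets 157/306/224.6
mmol·min/l. Hyperbola constants come from the sensitivity×secretion
products: the first and third groups are on-curve (δ=1) with
k = 149.1 and 108.2; the middle group's k is the geometric mean of the
two on-curve constants (127.0) with δ = 0.924 so its own product
(117.4) is matched — encoding a group whose beta-cell output falls
short of the reference compensation curve. Lean body mass (52 ± 5 kg)
and the log-noise scales (σ_B = 0.25, σ_A = 0.35, σ_FI = 0.35) are not
recoverable from group summary tables and were set once to values
typical for lean young men and for the observed dispersion of such
indices. The excursion target is per-group rather than a single global
coupling constant: with one global constant, A ∝ 1/(S·B) and the three
S·B products would order the glucose IAUCs oppositely to the design
targets, so the within-group coupling (which carries the
low-DI ⇒ high-excursion structure) is normalised per group.

A `null` preset (three identical groups of 20) supports type-I-error
studies.

### What the generator does and does not emulate

It reproduces: the group-level moment structure of the three-group
design; the hyperbolic secretion–sensitivity coupling with group-level
deficits; sensitivity-linked fasting hyperinsulinemia; DI-linked meal
excursions on the protocol grid; clamp steady states consistent with
true sensitivity. It does not model: incretin effects, C-peptide or
hepatic insulin extraction, gut absorption kinetics, within-day assay
drift, lipid panels, or any correlation between anthropometry and the
metabolic axes (BMI, waist and body fat are drawn independently).
Passing recovery tests therefore demonstrates that the *pipeline* is
correct and well-calibrated under its own assumptions, not that those
assumptions capture every feature of real cohorts — in particular,
real ISI-clamp is measured with clamp-level noise that the exact
inversion in step 6 deliberately omits, so real-data rank correlations
will be lower than the simulated ones.

## Problem sizes used in validation

The validation suite simulates cohorts at the design's sizes (59
subjects) for calibration checks across 100 seeds; type-I calibration
uses 1000 null cohorts of 60; deficit recovery uses two groups of 500;
the estimator oracle checks use n = 200 with σ_log = 0.2. These sizes
put Monte-Carlo error well below the margins being asserted while the
full suite stays fast enough to run routinely.

## Known limitations

* The Matsuda variant implemented as primary uses incremental AUCs, as
  specified for this pipeline's provenance; values are therefore not
  numerically comparable to the classic mean-concentration Matsuda
  index (provided separately).
* The split-plot ANCOVA age adjustment is one defensible convention
  among several (SPSS-style covariate×time terms would differ);
  both adjusted and unadjusted results are always emitted, and neither
  is claimed to replicate any particular historical analysis.
* Bonferroni is the only multiplicity control offered, by design
  parity with the analyses this pipeline mirrors.
* Group summary moments computed from tables of means (e.g. an index
  evaluated at group-mean inputs) do not equal the mean of per-subject
  index values; the presets calibrate the former against the latter
  only up to the documented tolerances.
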