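# Methods

This note documents the models, numerical conventions and design choices
behind `pigletgfr`, and what the simulation-based validation does and does
not demonstrate.

## Study design being emulated

The package targets a cross-sectional renal-maturation study in
conventional male piglets at four ages — 8 days, 4 weeks (28 d), 7 weeks
(49 d) and 6 months (180 d) — in which GFR is measured three ways per
animal: endogenous creatinine clearance with plasma creatinine assayed by
the Jaffe and by the enzymatic method, and plasma clearance of exo-iohexol
after a single IV bolus of 64.7 mg iohexol/kg (0.1 mL/kg of a 300 mg
iodine/mL contrast formulation; the conversion uses iohexol's three iodine
atoms and 821.14 g/mol molar mass). Blood for iohexol is drawn at 0 (pre-
dose), 5, 15, 30, 60, 120, 180, 360, 480, 600 and 1440 min; plasma
creatinine at 10 am, 2 pm and 6 pm; urine in three 1-h collections
(10–11 am, 2–3 pm, 6–7 pm). Animals under 1.50 kg are withdrawn
(`apply_bw_exclusion`); the generator's group statistics describe the
cohort *after* that exclusion, so the pipeline does not re-apply it by
default.

## Synthetic cohort generator

Per age group, bodyweight, kidney weight, plasma creatinine and total
plasma protein are drawn from normal distributions truncated at zero by
rejection, using the group's mean and SD. Truncation avoids impossible
negative draws at small n without materially changing the moments (the
smallest mean/SD ratio in the defaults is ≈ 4.2, so less than ~0.003 % of
mass is rejected).

**Body surface area** is not sampled independently: BSA is derived from
bodyweight through the allometric surface law `BSA = k · BW^(2/3)`, with
`k` calibrated once by least squares of `log BSA − (2/3) log BW` over the
four group-mean (BW, BSA) pairs (`k ≈ 0.1013 m²/kg^(2/3)` for the default
groups). This keeps surface area physically consistent with weight; the
calibrated law reproduces the group-mean BSAs within 5 % across a 56-fold
weight range. Kidney weight, by contrast, does not follow a clean power
law across these ages (the kidney-to-body mass ratio falls sharply after
weaning), so it is sampled from its group distribution directly.

**Latent true GFR** is assigned per subject as
`GFR = 1.879 · BW^1.092 / Pcr^0.600 · exp(ε)`, `ε ~ N(0, σ)` with default
σ = 0.15 on the natural-log scale, chosen so group coefficients of
variation resemble those of measured piglet clearances (SD/mean ≈ 0.2–0.3).
All simulated measurements are constructed to be *exactly* consistent with
this latent value before noise:

* **Urine collections** draw a volume around a basal urine flow of
  1.5 mL/kg/h (lognormal, CV 0.30) and solve the urinary creatinine from
  the clearance equation, so noise-free collections invert exactly.
* **Plasma creatinine**: the enzymatic assay reads the latent value; the
  Jaffe assay reads it depressed by the protein error
  `0.23 · (1 − TP/75)` mg/dL, so the protein correction recovers the
  latent value exactly. Assay noise is multiplicative mean-one lognormal
  with the configured CV (default 5 %).
* **Iohexol profiles** follow a two-compartment biexponential
  `C(t) = A e^(−αt) + B e^(−βt)` with defaults α = 0.05/min, β = 0.004/min
  and 40 % of the AUC in the fast phase — a visually plausible decay over
  the 1440-min window with a terminal half-life of ≈ 2.9 h. A and B are
  solved so that `exo dose / (A/α + B/β)` equals the subject's clearance,
  making the analytic clearance exact by construction. α = β is allowed
  and collapses to a monoexponential (used by exactness tests). These
  disposition parameters are modelling scaffolding, not measured values.
  The exo-isomer fraction of the dose defaults to 0.90 and is configurable;
  no measured isomer ratio is available.

Reproducibility: one master seed; each subject's draws come from an
independent `numpy` stream keyed by (seed, subject index), so cohorts are
byte-identical across runs regardless of generation order.

## Non-compartmental analysis

AUC to the last positive sample uses the standard linear-up/log-down rule:
the logarithmic trapezoid `(c1 − c2)/ln(c1/c2) · Δt` — exact for
monoexponential decay — on strictly declining positive segments, the linear
trapezoid on rising, flat or zero-bounded segments.

**The t = 0 sample is pre-dose and reads zero, but an IV bolus has
C(0⁺) > 0.** Treating the first segment as a linear triangle from zero
loses about half of the first segment's area (≈ 5 % of total AUC under the
default kinetics and schedule). The package therefore back-extrapolates C0
log-linearly through the first two post-dose samples — the standard bolus
convention — and integrates the first segment with the log rule from that
C0, falling back to the linear-from-zero rule when the first two samples
are non-decreasing. With this convention the residual AUC error on the
default biexponential sampled at the 11 scheduled points is ≈ +1.5 %
(from log-down segments where both phases still mix), and the recovered
clearance is within 3 % of the analytic value; on monoexponential profiles
every step is exact to machine precision.

λz is the negated slope of the least-squares fit of ln C on t over the
best tail: candidate tails of 3–6 points (never including the observed
peak; points at or below a configurable LOQ, default disabled, are dropped
first), selected by maximum adjusted R², slope required negative.
`AUC0–∞ = AUC0–last + C_last/λz`; a warning is issued when more than 20 %
of the AUC is extrapolated. Clearance = exo dose (mg → µg) / AUC0–∞.

## eGFR regression

Response and predictors are log-transformed (base 10 by default; the
exponents are base-invariant and only the intercept-to-constant map
depends on the base). Candidates, in fixed tie-breaking order: log Pcr,
log BW, log age, log age × log Pcr, log age × log BW. Selection is
bidirectional stepwise: enter the candidate with the smallest partial-F
p-value while it is below 0.05, then prune any retained term whose
partial-F p-value exceeds 0.10, worst first, to a fixed point; the
intercept is always retained, sweeps are bounded (error on cycling), and
the strict `p_in < p_out` ordering prevents enter/remove oscillation.
Partial-F p-values are computed from residual sums of squares of
`statsmodels` OLS fits, with explicit guards for saturated (zero-residual)
fits where coefficient p-values are undefined: a term whose addition
removes numerically all residual variance gets p = 0, a term adding
nothing to an already-perfect fit gets p = 1. This makes noiseless
identifiability exact.

The fitted log model is back-transformed to `eGFR = a · BW^b / Pcr^c`
with `a = base^intercept` and `c` stored as the positive denominator
exponent (the raw log-Pcr coefficient is −c). If age terms survive
selection they are reported separately and flagged as outside the
two-predictor form; if either main effect is missing no power-law model is
emitted. The equation targets absolute clearance in mL/min (bodyweight is
a predictor, so no additional size indexing is applied). Accuracy is
summarized by adjusted R² on the log scale and by P10/P30, the percentage
of predictions within ±10 %/±30 % of measured GFR (band edges inclusive).
The null benchmark of predicting the grand mean is available in reports
but is not a model.

## Comparisons

Age effects within a technique: one-way ANOVA on log GFR followed by
pairwise two-sample t-tests, Bonferroni multiplier = number of pairs.
Technique effects within an age: within-subject paired t-tests on log GFR
across the three techniques, Bonferroni multiplier 3, subjects missing a
technique dropped with a warning. This preserves the estimable quantities
of a repeated-measures analysis — which pairs differ — without fitting the
full mixed model, which is out of scope. Degenerate inputs are handled
explicitly: all-equal groups flag the table rather than emitting an
undefined F; a constant nonzero paired difference is exact separation
(p = 0), a constant zero difference gives p = 1.

## Validation protocols and problem sizes

Two seed-averaged experiments (also run by `scripts/acceptance.py`)
summarize the pipeline's accuracy; sizes were chosen to estimate
seed-averaged means precisely while keeping a full run in seconds:

* **Power-law recovery** — 20 replicates of 200 subjects (50 per age
  group), true GFR from the reference equation with log-noise SD 0.05,
  full candidate set. Mean fitted coefficients land within ~1 % of
  (1.879, 1.092, 0.600). Spurious age terms are excluded in ≈ 85 % of
  replicates; with three null candidates each tested at p_in = 0.05, the
  expected all-excluded rate of plain stepwise selection is
  ≈ 0.95³ ≈ 0.86, so this is the selection procedure's nominal behaviour,
  not estimation error.
* **NCA closure** — each subject's true clearance is a target indexed
  value times its size metric (e.g. 46.57 mL/min/m² × BSA for the
  neonatal group, n = 14; 100.92 mL/min/m² for the 7-week group, n = 16),
  profiles simulated on the 11-point schedule with 5 % assay CV,
  20 replicates. Recovered group means sit within ~2 % of the configured
  targets, the net of the +1.5 % AUC discretization bias and mean-one
  noise.

## What passing tests do and do not show

The generator reproduces marginal distributions of body metrics, the
protein-error structure of the Jaffe assay, and self-consistent clearance
physiology, and the closure tests show the estimators are unbiased at the
study's sampling design and noise levels. Real data differ in ways the
simulation does not model: tubular secretion of creatinine (which biases
creatinine clearance upward relative to a filtration marker), assay
interferences beyond total protein, within-day creatinine variation,
incomplete urine collections, deviations from biexponential disposition,
and correlation structures between body metrics beyond the BW–BSA law.
Agreement of the three techniques in simulation therefore validates the
computational pipeline, not the physiological equivalence of the methods.

## Known limitations

* The repeated-measures mixed model is deliberately replaced by paired
  contrasts plus one-way ANOVA; variance-component estimates are not
  produced.
* The exo-isomer fraction (default 0.90) is a configurable stand-in; no
  measured value is available.
* The stepwise family-wise entry rate over several null candidates exceeds
  the per-test 5 % level by construction; users wanting stricter exclusion
  should lower `p_in` or pre-screen candidates.
* Creatinine clearance per subject is the mean of the three interval
  clearances at the subject's mean plasma creatinine; this equals the
  pooled-mass estimate only when interval durations are equal (they are,
  in the emulated design).
* The 24-h creatinine load reading `mass × 24/(hours collected)` is the
  only unit-consistent interpretation of the screen and is used as such.
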