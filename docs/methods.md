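# Methods

## Model and assumptions

The quantity of interest is diet-induced thermogenesis (DIT): the energy a
fed animal expends above what it would have expended, at the same level of
physical activity, had it stayed fasted. The method estimates the
counterfactual with a per-animal regression fitted under fasting:

    EE_fast = a + b * f(A) + ε,      f = sqrt by default,

where A is the infrared beam-break count per minute averaged over a 12-min
bin and EE comes from gas exchange via EE = 3.9·VO2 + 1.1·VCO2 (kcal/min,
gases in L/min). This is the Ferrannini energy equation with the urinary-
nitrogen term dropped: protein oxidation contributes a few percent at most
in this setting and the cage system cannot measure it. Inputs may be
declared in mL/min (the default, matching mouse-scale monitor output) and
are converted internally; the unit is never guessed from magnitudes.

Assumptions the user should be aware of:

- **Linearity in f(A).** The sqrt transform is the default because the
  energetic cost per beam break falls with activity; log1p and identity are
  offered, and `select_transform` picks the best R² with the fixed
  tie-break sqrt > log1p > identity. There is no hard rule for when a
  low-activity animal needs log1p; the choice is exposed, not automated.
- **Temporal transportability.** The fasting model is fitted on a
  0000–1100 h window but applied across the whole 22-h fed window
  (1700–1500 h). Circadian variation in resting EE that is not mediated by
  activity is therefore absorbed into the DIT estimate. This mismatch is
  part of the method; the package documents it rather than correcting it.
- **Bin-scale analysis.** Four 3-min samples are averaged per channel and
  EE/RER are computed from the binned gas means. For EE the order of
  operations is irrelevant (the equation is linear); RER is the ratio of
  bin means, not the mean of ratios — the difference is negligible except
  at near-zero VO2 and is stated here once.

## Pipeline numerics

- Bins are non-overlapping groups of `bin_factor` (default 4) samples; a
  trailing partial group is dropped. The design windows give exactly
  55 fasting and 110 fed bins. Gaps in the 3-min grid are a hard error at
  trace construction — imputation would silently bias the DIT integral.
- Photoperiod labels use the half-open convention [lights-on, lights-off),
  default 0700–1900, so boundary bins are assigned deterministically and
  the labels always partition a trace.
- Totals are rectangle-rule sums (rate × bin width). Each binned rate is by
  construction the mean over its interval, so rectangles are the unbiased
  quadrature; a trapezoid rule would double-count the interval means.
- Negative per-bin DIT values are retained in all integrals; clipping at
  zero would bias totals upward under symmetric noise. The count of
  negative bins is reported (`n_negative_bins`) so a pathological run is
  visible.
- TEE decomposes exactly: total EE = AUC of predictions + total DIT, by
  linearity of the rectangle rule. This identity is tested at 1e-12.
- OLS is fitted by `scipy.stats.linregress`; the test suite checks it
  against hand-coded normal equations at 1e-10. Degenerate designs
  (constant transformed activity, n < 3) raise errors rather than
  returning NaNs.
- The homoscedasticity check is a Breusch–Pagan LM test (statsmodels) of
  squared residuals on fitted values. A perfect fit is reported as p = 1
  with a `degenerate` flag. The p-value is advisory only.

## Group statistics

`compare_groups` reproduces the SPSS-style decision procedure common in
this literature: classic mean-centered Levene at α = 0.05 (median-centered
Brown–Forsythe available) gates between Tukey HSD (scipy, Tukey–Kramer for
unequal n) and a hand-implemented Games–Howell (Welch pairwise SEs,
Welch–Satterthwaite df, studentized-range p-values; no scipy/statsmodels
implementation exists, so ours is cross-checked against pingouin in the
test suite). The gate α equals the significance α because the procedure
states no separate gate level. Summaries are mean ± SEM, SEM = sd/√n with
the n−1 sd.

One caveat carried over from the procedure itself: the same animals
measured under successive protocols are compared with independent-groups
post-hocs. The package replicates that choice; a repeated-measures model
would be more efficient but is out of scope.

## The simulator

`ditcalc.simulate` emulates the experimental design — 3-min sampling, 11-h
fasted window from midnight, 22-h fed window from the 1700 h meal, 12-h
light cycle — with known ground truth for every run:

- **Activity**: negative-binomial counts with photoperiod-dependent means
  (defaults 180.6 dark / 63.8 light counts/min for ad libitum; the
  restricted presets use their higher observed dark activity) and shape
  k = 5, giving the visible overdispersion of beam-break data (Poisson
  would be far too tight). A configurable anticipatory multiplier (default
  1.5× in the 90 min before mealtime, fasted condition only) models
  food-anticipatory activity; the default fasted window does not overlap
  it, so it only appears in custom windows.
- **Baseline EE**: a + b·√(A_bin) with a = 0.005 kcal/min,
  b = 0.00025 kcal/min per √count. The law is deliberately defined at the
  12-min bin scale (per-sample baseline uses the √ of the sample's bin-mean
  activity): √ does not commute with averaging, and defining the law on the
  analysis grid makes the noiseless limit exact — a σ = 0 run sits exactly
  on the fitted line and the pipeline recovers the injected DIT to machine
  precision, which is what makes recovery a sharp test. Gaussian noise
  (σ = 0.0009 kcal/min per 3-min sample) was chosen by error propagation so
  that fasting fits land in a realistic R² band (roughly 0.65–0.85);
  negative draws are truncated at zero and counted.
- **DIT kernel**: linear rise (30 min) to a plateau, exponential decay
  (τ = 120 min) after the plateau ends. Plateau end and amplitude are
  protocol presets — ad libitum 600 min at 0.0038 kcal/min, 33%-restricted
  360 min at 0.0040, 66%-restricted 180 min at 0.0033 — chosen so the
  kernel integral is ≈12.5% of each protocol's intake (ad libitum:
  0.0038·(15 + 570 + 120·(1−e⁻⁶)) ≈ 2.68 kcal on 21.6 kcal eaten), i.e.
  the restriction shortens the plateau because the food runs out. Each
  3-min sample carries the kernel's *interval mean* computed from the
  closed-form antiderivative, so rectangle-rule integration reproduces the
  continuous integral exactly rather than to O(Δt²).
- **Gases**: EE and a deterministic RER trajectory (0.75 fasted; fed rising
  to 0.95 over 1 h then relaxing with τ = 6 h) are inverted to VO2/VCO2
  via VO2 = EE/(3.9 + 1.1·RER), keeping all three channels mutually
  consistent by construction.
- **Cohorts**: per-animal seeds derive deterministically from a base seed
  (`numpy.random.SeedSequence.spawn`); optional between-animal variation
  draws a and b with 7% fractional sd — a guess, since no within- or
  between-day variance data exist to calibrate it.

What the simulator does *not* emulate: meal microstructure, substrate-
driven coupling between RER and EE, thermoregulatory responses, analyzer
drift, or missing data. Passing recovery tests therefore demonstrates that
the *estimator* is correct under the stated generative model, not that the
model captures every feature of real cage data.

## Problem sizes

Tests and the acceptance script use the study-scale design throughout:
6 animals per cohort, 220/440 samples per trace, 20 replicate seeds for
noisy-recovery medians, and 2000 Monte-Carlo replicates per null for the
type-I-error calibration of Levene, Tukey HSD and Games–Howell (binomial
±3 SE bands around the nominal 5%, widened to 2.5–8% for Games–Howell,
which is an approximate test at moderate n).

## Known limitations

- Intake must be supplied as measured kcal; the tool never estimates it.
- The DIT kernel shape is a phenomenological stand-in (rise/plateau/decay);
  real postprandial dynamics have no agreed functional form.
- R² plausibility bands and protocol presets are qualitative calibration,
  not a reproduction of any specific animal dataset.
- Hourly values are reported as kcal summed per hour (equal to kcal/h for
  complete hours); a partial trailing hour is flagged, not rescaled.
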