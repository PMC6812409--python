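# ditcalc

Absolute diet-induced thermogenesis (DIT) from mouse indirect-calorimetry
time series.

DIT — the thermic effect of food — is the rise in energy expenditure (EE)
that follows a meal, driven by digestion, absorption and nutrient storage.
In mice it has traditionally been read off as a postprandial bump in body
temperature or VO2, which gives relative comparisons but no absolute
energy value, and is confounded by spontaneous activity: a mouse that eats
also moves. `ditcalc` implements an activity-matched regression method
that yields DIT in kcal, for researchers doing metabolic phenotyping in
metabolic cages (3-min VO2/VCO2/activity sampling, 12-h light cycles).

## Method

For each animal:

1. **Fasting measurement** (11 h, 0000–1100 h). EE is computed per sample
   from gas exchange with the abbreviated Ferrannini equation,

   EE (kcal/min) = 3.9 · VO₂ + 1.1 · VCO₂  (L/min; protein-oxidation term
   set to zero),

   samples are averaged into 12-min bins (55 bins per 11 h), and a simple
   linear regression is fitted:

   EE = a + b · √(activity count)

   The square root straightens the EE–activity scatter; a log1p transform
   is available for low-activity animals, and `select_transform` compares
   candidates by R².
2. **Fed measurement** (22 h, 1700–1500 h, meal at 1700). The same binning
   gives 110 points. For each fed bin, the fasting model predicts the EE
   an unfed animal would spend *at that activity level*; the excess

   DIT(t) = EE_fed(t) − [a + b·√(activity(t))]

   is the diet-induced thermogenesis rate, free of the activity confound.
3. **Integration and summary.** Rectangle-rule areas under the curves give
   total DIT and total EE (TEE) in kcal, hourly time courses, and the two
   headline percentages DIT/intake = 100·DIT/intake and
   DIT/EE = 100·DIT/TEE.
4. **Group comparison.** Per-animal outcomes across feeding protocols are
   compared with a Levene variance-homogeneity gate routing to Tukey HSD
   (homogeneous) or Games–Howell (heterogeneous), reported as mean ± SEM.

A seeded simulator (`ditcalc.simulate`) generates paired fasted/fed traces
with known baseline law and injected DIT kernel, so the whole pipeline can
be verified by recovery rather than eyeballed; presets cover ad libitum
(21.6 kcal/day), 33%-restricted (15 kcal/day) and 66%-restricted
(7.5 kcal/day) feeding.

## Worked example

```python
from ditcalc import *

fasted = read_trace("m01_fasted.csv")   # 220 samples, 0000-1100 h
fed    = read_trace("m01_fed.csv")      # 440 samples, 1700-1500 h
protocol = FeedingProtocol(21.6, "1700", "ad_libitum")  # weighed intake

model = fit_fasting_model(bin_trace(fasted), "sqrt")
series = compute_dit_series(bin_trace(fed), model)
result = summarize(series, protocol)
```

On a simulated ad-libitum animal (`ditcalc simulate --protocol ad_libitum
--n 1 --seed 42 --out demo/`) this prints:

```
EE = 0.00427 + 0.000305 * sqrt(activity)   R2 = 0.816  (n = 55 bins)
total DIT  = 2.70 kcal over 22 h
total EE   = 12.71 kcal (TEE)
DIT/intake = 12.5 %
DIT/EE     = 21.3 %
activity   = 180.0 (dark) / 63.7 (light) counts/min
```

The regression says this animal spends 4.27 cal/min at rest plus
0.31 cal/min per unit √activity; feeding added 2.70 kcal of thermogenesis
over the day — 12.5% of what it ate and 21.3% of everything it burned.

The same workflow is available from the shell:

```sh
ditcalc simulate --protocol ad_libitum --n 6 --seed 1 --out sim/
ditcalc compute --fasted sim/m01_fasted.csv --fed sim/m01_fed.csv \
        --protocol protocol.json --transform sqrt --out m01_report.json
ditcalc compare --reports 'reports/*.json' --metric dit_over_ee
```

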