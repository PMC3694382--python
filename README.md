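# sasang-shi

Constitution-specific health scoring for Sasang constitutional
medicine (SCM): a tested re-implementation of the **Sasang Health
Index (SHI)** pipeline, from raw diagnostic signals to the two-stage
sparse regression model, with a synthetic-cohort generator standing in
for the (non-public) clinical data so every stage runs offline.

## The problem

SCM assigns each person one of four constitutions — Tae-Eum (TE),
So-Eum (SE), So-Yang (SY), and the rare Tae-Yang — with
constitution-specific physiology, symptoms and care. The SHI asks: can
a clinician-style health judgement (a 0–100 visual analogue scale,
VAS, where ≥ 80 is healthy, 40–80 subhealthy and < 40 diseased) be
predicted per constitution from five objective diagnostic components?

* **complexion** — 60 YCrCb mean/SD statistics over 10 facial sectors
  of a chart-corrected photograph;
* **radial pulse** — 20 per-arm features at the Gwan position: beat
  timing (heart rate, pulse pressure, dicrotic-notch time t4 and
  height h4, HR75-normalized timing and beat areas), tonometry depth
  indices (PDI, PVI, PPW_PVI) and Welch-PSD harmonics;
* **voice** — per-vowel F0, jitter/shimmer-family perturbations
  (JITT, RAP, PPQ, SHIM, APQ), formants F1–F3 with bandwidths, and
  sentence pitch statistics (sDT, sF10/sF50/sF90,
  sFHL = (sF90 − sF50)/(sF50 − sF10));
* **skin** — suction viscoelasticity (E, E_hys = E₁ − E₃, V_E) and
  wrinkle-area fractions;
* **questionnaire** — 87 ordinal items scored into 16 factors
  (exploratory factor analysis, principal components + promax,
  Cronbach-alpha screening) plus a self-estimation score.

The model is fitted in two LASSO stages per constitution *i*:

```
SHI_comp,i = α_i0 + Σ_j α_ij · z(x_ij)                     (stage 1)
SHI_sum    = β_0 + Σ_i β_i · z(SHI_comp,i) + β_a·age + β_b·BMI   (stage 2)
```

with a Student's t-test prefilter (P < 0.2, healthy vs unhealthy),
z-scored features, a 10-fold cross-validated penalty, and stage 2 fit
on *out-of-fold* stage-1 scores (stacked generalization) with an OLS
refit on the selected support. The published coefficient tables ship
with the package (`sasang_shi.model.load_published_models()`), so the
scorer reproduces the published models exactly; their age/BMI
coefficients were never published, which the API surfaces explicitly.

Intended users: researchers in traditional-medicine informatics and
biostatistics who want a reproducible reference implementation of the
SHI pipeline, or reusable extractors for any of the five components.

## Worked example

```python
from sasang_shi import (SyntheticConfig, generate_cohort,
                        icc_agreement, load_published_models)
from sasang_shi.evaluate import ratings_matrix, summarize_cohort

cohort = generate_cohort(SyntheticConfig(seed=1))
print(len(cohort))                      # 298 subjects: 100 TE, 72 SE, 126 SY
print(round(icc_agreement(ratings_matrix(cohort)), 4))   # 0.9515
print(summarize_cohort(cohort))

comps, integ = load_published_models()
m = comps[("SE", "pulse")]
print(m.score({"L_PDI": 0.0}))          # 68.9  (published intercept)
print(m.score({"L_PDI": 1.0}))          # 64.07 (one z-unit deeper pulse)
```

The cohort summary printed for seed 1:

```
  TE: n=100, age 58.6±5.2, BMI 26.5±2.6, VAS 59.9±22.2 [healthy: 25 (25%), subhealthy: 46 (46%), diseased: 29 (29%)]
  SE: n=72,  age 56.8±4.7, BMI 21.5±1.8, VAS 65.8±25.5 [healthy: 29 (40%), subhealthy: 25 (35%), diseased: 18 (25%)]
  SY: n=126, age 55.7±4.3, BMI 23.0±1.8, VAS 73.0±20.0 [healthy: 58 (46%), subhealthy: 53 (42%), diseased: 15 (12%)]
```

— the published ordering VAS(TE) < VAS(SE) < VAS(SY) and the
category mix emerge from the calibration, not from per-subject
hard-coding. Fitting the full two-stage model on such a cohort
(`analysis/04_fit_models.py`) prints the cross-validated accuracy per
constitution next to the published adjusted R² (0.51 TE / 0.56 SE /
0.30 SY).

## Analysis scripts

Numbered drivers under `analysis/` run the study end to end on
synthetic data and write their tables under `results/`:

1. `01_simulate_cohort.py` — cohort generation + demographic summary
2. `02_rater_agreement.py` — ICC(2,1) and VAS ANOVA across replicates
3. `03_extract_signals.py` — raw-signal fixtures → extractor round trip
4. `04_fit_models.py` — two-stage fits, model JSONs, fit report
5. `05_score_published.py` — scoring with the bundled published models

## Layout

```
src/sasang_shi/       library: synth, signals, complexion, pulse,
                      voice, skin, questionnaire, model, evaluate
src/sasang_shi/data/  published model coefficients (checksummed JSON)
analysis/             numbered narrative drivers
scripts/acceptance.py headline-number reproduction
docs/methods.md       model, calibrations, numerical choices, limits
tests/                pytest suite (unit, property, acceptance)
```
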