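# anthropoage

Biological age from anthropometry: Gompertz mortality models on
chronological age and body composition, the AnthropoAge / AnthropoAgeAccel
transforms, and the longitudinal-validation machinery needed to evaluate
such a metric on multi-study aging panels.

## The problem

Chronological age (CA) is the dominant mortality risk factor in older
adults, but it hides the heterogeneity of aging. *Biological age* (BA)
metrics re-express an individual's physiological state on the age scale.
AnthropoAge is a second-generation BA proxy built from nothing but measured
height, weight and waist circumference — cheap enough for large
population surveys — via two sex-stratified Gompertz proportional-hazards
models of all-cause mortality:

1. **CA-only:** hazard `h(t) = exp(β₀ + β₁·CA) · exp(γ₀ t)`, *t* in months;
2. **CA + anthropometry:** linear predictor
   `xb = rate + b·CA + b₁·ln BMI + b₂·(ln BMI)² + b₃·WHtR^⅓`,
   with a separate shape `γⱼ` per race/ethnicity group *j*.

Matching the two cumulative distribution functions at a 120-month horizon —
the age at which the CA-only model predicts the same 10-year death
probability `M = 1 − exp(−e^{xb} γⱼ⁻¹ (e^{γⱼ t} − 1))` that the
anthropometry model assigns to the individual — gives the closed form

```
AnthropoAge = [ ln( −ln(1−M) / (γ₀⁻¹ (e^{γ₀ t} − 1)) ) − β₀ ] / β₁ ,   t > 0
```

**AnthropoAgeAccel** is the residual of AnthropoAge regressed on CA within
sex (study intercepts absorbed); values > 0 define *accelerated aging*.

The package covers the full evaluation loop used to validate such a metric
on harmonized longitudinal panels:

- `anthropoage.synth` — synthetic multi-study panel generator with known
  ground truth (latent per-subject acceleration, true Gompertz parameters,
  injectable hazard ratios) so every estimator is testable without any
  restricted data;
- `anthropoage.anthropometrics` — BMI/WHtR, the benchmark body-shape
  indices (BRI, WWI, ABSI), ADL/IADL/comorbidity scores, eligibility
  filters (ages 50–94; height 125–200 cm; weight 30–150 kg; waist 50–160 cm;
  BMI 10–60 kg/m²);
- `anthropoage.gompertz` — the Gompertz PH maximum-likelihood fitter, the
  CDF-matching transform, acceleration residualization, coefficient-file
  round-tripping;
- `anthropoage.surveval` — weighted stratified Cox models, Uno's IPCW
  c-statistic, cumulative/dynamic time-dependent AUC, paired bootstrap AUC
  comparison, Kaplan–Meier, log-rank, Schoenfeld-residual PH diagnostics;
- `anthropoage.dca` — decision curve analysis (net benefit across risk
  thresholds, with IPCW handling of censoring);
- `anthropoage.gee` — GEE aging trends (Gaussian, AR(1), sandwich SEs),
  new-onset outcome models (Poisson/binomial), QIC comparison, weighted
  prevalence curves;
- `anthropoage.pipeline` — the end-to-end study replica, one tidy CSV per
  stage, byte-reproducible under a fixed seed.

## Worked example

```python
import numpy as np
from anthropoage import (SynthConfig, generate_panel, fit_gompertz,
                         anthropoage_batch, anthropoage_accel)

cfg = SynthConfig(n_subjects=2000, studies={"US": (0, 2, 4), "CHN": (0, 2, 4)},
                  seed=42)
panel, truth = generate_panel(cfg)
panel["bmi"] = panel.weight_kg / (panel.height_cm / 100) ** 2
panel["whtr"] = panel.waist_cm / panel.height_cm

base = panel[panel.wave == 0]
ca_fits, anthro_fits = {}, {}
for sex, sub in base.groupby("sex"):
    t_m = sub.time_years.to_numpy() * 12          # Gompertz time is months
    ev = sub.event.to_numpy()
    ca_fits[sex] = fit_gompertz(t_m, ev, sub[["age"]].to_numpy(), sex=sex)
    lb = np.log(sub.bmi.to_numpy())
    X = np.column_stack([sub.age, lb, lb**2, np.cbrt(sub.whtr)])
    anthro_fits[sex] = fit_gompertz(t_m, ev, X, sex=sex,
                                    shape_groups=sub.ethnicity.to_numpy())

panel["anthropoage"] = anthropoage_batch(panel, ca_fits, anthro_fits)
panel = anthropoage_accel(panel, mode="study-intercepts")
```

Output of the accompanying prints:

```
CA-only (women): gamma0=0.00365/mo  beta0=-11.968  beta1=0.0870/yr
subject 0: CA 65.2 y, BMI 38.8, WHtR 0.57
  10-y risk-matched AnthropoAge = 68.1 y, AnthropoAgeAccel = +3.2 y, accelerated = True
share of visits flagged accelerated: 49.8%
```

Reading: the fitted CA-only model says mortality doubles roughly every
`ln 2 / 0.00365 ≈ 190` months of follow-up time and every
`ln 2 / 0.087 ≈ 8` years of age. Subject 0's obesity-range BMI maps their
10-year death risk to that of a 68-year-old with average body composition —
3.2 years older than their calendar age, so the subject is flagged as aging
in an accelerated fashion.

The same computation is scriptable:

```
anthropoage synth --n-subjects 2000 --seed 42 --out panel.csv
anthropoage compute --panel panel.csv --coefs coefs.tsv --out ba.csv
anthropoage run --config config.yaml        # full pipeline
```

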