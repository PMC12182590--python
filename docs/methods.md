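# Methods

## The biological-age model

Two right-censored Gompertz proportional-hazards models of all-cause
mortality are fit per sex by maximum likelihood. The hazard is
`h(t) = exp(xb) · exp(γt)` with follow-up time *t* in **months**; the
log-likelihood of a sample with event indicators `d_i` is

```
Σ_i w_i [ d_i (xb_i + γ_i t_i) − e^{xb_i} (e^{γ_i t_i} − 1)/γ_i ]
```

Model 1 uses chronological age (CA, in **years**) as the only covariate —
the mixed time units (γ per month, β₁ per year of age) are deliberate and
recorded in the serialized coefficient header so a loaded model can never be
applied under the wrong convention. Model 2 adds `ln BMI`, `(ln BMI)²`
(raw powers; the coefficient-file format carries a basis tag so an
orthogonal-polynomial coefficient set with its centering constants is also
loadable) and `WHtR^⅓`, with a separate shape `γ_j` per race/ethnicity
group. Survey-weighted likelihood is available but off by default.

AnthropoAge solves `CDF₁(t, age) = M` where `M = CDF₂(t, xb)` at
`t = 120` months; the closed form is in the README. `M` is required to lie
strictly in (0, 1): out-of-range values raise rather than silently clamp,
with an explicit `clamp_eps` escape hatch that warns and counts.

### Numerical choices in the fitter

The Gompertz MLE is a quasi-Newton (L-BFGS-B) optimization with analytic
gradients. Raw parametrization is badly conditioned — the rate intercept is
nearly collinear with `β₁·CA`, and γ lives three orders of magnitude below
the βs — so internally the covariates are centered at their weighted means
and the shapes optimized on the log scale; estimates and the
observed-information covariance (finite differences of the analytic
gradient) are mapped back to the natural parametrization by the delta
method. Several shape starts (0.003, 0.01, 0.001, 0.03 per month) guard
against premature termination; a shape that still ends at the box boundary
is reported as non-identified rather than clipped. Convergence tolerance is
`ftol = 1e-9` on the scaled objective.

Calibration was verified by simulation: at n = 20 000 with ~30%
administrative censoring the three Wald CIs achieve ~95% marginal and ~91%
joint coverage on exact event times. Month-rounded death dates (see below)
introduce a small upward coarsening bias in γ̂ (about +0.5 SE at that
sample size), which is a property of the data coarsening, not the fitter.

## Acceleration residualization

AnthropoAgeAccel is the per-row residual of AnthropoAge on CA, fit
separately by sex. The default mode is OLS with fixed study intercepts:
with a handful of studies it is numerically indistinguishable from a study
random intercept, and it is exactly testable (residuals sum to zero and are
orthogonal to CA within sex). A mixed mode uses a random intercept per
participant (repeated measures; study as fixed effect) or per study
(baseline-only data). Residuals smaller than 1e-9 years are snapped to
zero so the `accelerated = accel > 0` flag is stable on exact-identity
inputs. Quartiles are unweighted per-sex sample quartiles with linear
interpolation; weighting of the quartile cut-points is not specified in
this literature, and unweighted cut-points keep them reproducible from the
residuals alone.

## Discrimination metrics

Uno's c and the cumulative-case/dynamic-control time-dependent AUC are
computed as explicit inverse-probability-of-censoring-weighted pair sums.
The censoring survival Ĝ is a Kaplan–Meier on the pooled sample (not
stratified); event *i* contributes weight `Ĝ(t_i−)⁻²` (c-statistic) or
`Ĝ(t_i−)⁻¹` against controls weighted `Ĝ(τ)⁻¹` (tAUC). Predictor ties
count ½; an evaluation time with no cases or no controls is returned as
missing, never fabricated. Optional weight truncation at `Ĝ ≥ g_floor` is
off by default with no silent behavior. With no censoring and τ at the
maximum follow-up, the c-statistic reduces exactly to Harrell's C — this
identity, and exact agreement with O(n²) brute-force pair sums, are tested.
The truncation time τ defaults to the per-analysis maximum follow-up and is
configurable per study horizon.

Model AUCs are compared by a paired nonparametric bootstrap over subjects
(default B = 1000 in analyses; smaller in the test pipeline) with a normal
two-sided p-value; degenerate resamples are dropped and counted, and more
than 10% dropped is an error.

Cox models, Kaplan–Meier, the log-rank test and the Schoenfeld-residual
proportional-hazards test are delegated to lifelines (Efron ties by
default, Breslow available for cross-checks; "standardized survey weights"
are weights divided by their in-sample mean). The global PH statistic sums
the per-covariate score chi-squares (df = number of covariates), an
independence approximation that is documented rather than hidden.

## Decision curves

Net benefit at threshold `p_t` is `TP/n − (FP/n)·p_t/(1−p_t)` with
"treated" meaning predicted risk ≥ p_t; weighted variants replace counts by
weight sums. Survival outcomes are converted to horizon-binary status by
IPCW: deaths before the horizon weighted `1/Ĝ(t−)`, survivors past it
`1/Ĝ(τ)`, subjects censored earlier dropped (weight 0); a naive
complete-follower conversion is provided for comparison. The default
threshold grid is 0.01–0.50 in steps of 0.01, the relevant range for
10-year mortality decisions. Cox linear predictors are mapped to absolute
risks by weighted logistic recalibration, which preserves ranks.

## GEE models

Population aging trends regress AnthropoAge on follow-up years with a
Gaussian variance function; a slope above 1 means faster-than-expected
aging, read off the robust-CI position against 1. New-onset models exclude
subjects already reporting the outcome at baseline, model post-baseline
reports only (onset is assigned to the reporting wave — interview-based
panels cannot localize onset more finely), and fit the three standard
contrasts: acceleration per year, its interaction with time, and the binary
accelerated flag; Poisson variance for ADL/IADL deficit counts (rate
ratios), binomial for binary outcomes (odds ratios).

All GEEs use robust sandwich covariance and an AR(1) working correlation
whose distance metric is the integer wave index, estimated by the lag-1
moment (grid) method — the continuous-distance bracket search in
statsmodels fails when within-subject correlation approaches 1, which is
the typical regime for a biological-age series. Calendar-time AR(1) is
possible by passing follow-up years as the time index with independence
fallback. Weights act as mean-1-normalized frequency weights in the
estimating equations; statsmodels does not propagate them into the AR(1) α
moment itself. QIC follows Pan (2001); for Gaussian families both models in
a comparison are evaluated at the larger model's scale (with a 1e-12
floor so exact fits stay finite), and only ΔQIC signs and orderings are
interpreted, never levels.

## The synthetic cohort generator

The generator emulates the structure of harmonized multinational aging
panels: five studies with wave schedules spanning 3–7 visits over 4–12
years, baseline ages 50–94 drawn right-skewed (median ≈ 61), 55% women, a
four-group race/ethnicity mix (45/30/17/8%), and anthropometry generated on
transformed scales — `ln BMI ~ N(3.27–3.30, 0.16–0.19)` and
`WHtR ~ N(0.575–0.585, 0.06–0.075)` per sex with mild age slopes — then
back-transformed and clipped to the plausibility ranges (clip bounds just
inside the eligibility filter). These levels reproduce the pooled medians
and IQRs reported for such panels (BMI ≈ 26.6 [23.3–30.6],
WHtR ≈ 0.58 [0.53–0.64]); per-study variances are not published, so the
dispersions are a qualitative choice fixed once.

A latent per-subject acceleration deviate `z ~ N(0, 2.5 years)` loads on
the anthropometry deviations and on outcome accrual, so ground truth for
acceleration recovery exists by construction. Mortality follows the
configured Gompertz hazard with `γ* = 0.0045`/month, `β₁* = 0.085`/year and
a rate intercept of −12, giving ~20% twelve-year mortality at the median
age; anthropometry enters through deviations of `ln BMI` (quadratic,
U-shaped) and `WHtR^⅓` from their age/sex expectations. Death times are
drawn in continuous time by CDF inversion from a stored per-subject
uniform, then reported rounded to the month (mimicking approximate dates of
death); follow-up is computed from those dates, and regenerating with a
modified hazard ratio (`inject_acceleration`) reuses the stored uniforms,
so a ratio of 1 reproduces the panel bitwise. Self-reported outcomes accrue
monotonically (a diagnosis, once reported, persists) with baseline
prevalences between 4% and 35% and per-wave incidences at 15% of baseline
prevalence, each tilted by age and by the latent deviate (log-OR 0.12 per
latent year). Survey weights are lognormal, normalized to mean 1 per study.
One RNG stream is spawned per study from the master seed, so adding a study
never perturbs the others.

What the generator does **not** emulate: item nonresponse beyond optional
completely-at-random blanking, rotating anthropometry subsamples,
informative censoring, cross-study measurement heterogeneity, or secular
trends in body composition. Passing tests therefore demonstrate estimator
correctness under a known data-generating process, not robustness to the
messiness of real survey data.

## Pipeline

Stages run strictly in order (validation → eligibility → Gompertz fits →
biological age → discrimination/DCA → Cox/KM → trends → new-onset), each
writing a tidy CSV; the manifest records the config hash, seed and row
counts, and a rerun under the same configuration is byte-identical. Pooled
analyses carry the study label as an intercept/stratification covariate.
Categorical adjustment covariates (education 3 levels, smoking 4, alcohol
4) are dummy-encoded against their first level. The test suite and the
acceptance script run the replica at 300–1200 subjects per study — large
enough for stable coefficients while keeping a full run in about a minute —
whereas the generator scales to the ~10⁴-per-study regime used in the
calibration simulations.

## Known limitations

- The Gompertz fitter assumes exact event times; interval-coarsened (e.g.
  month-rounded) times bias γ̂ slightly upward and are not modeled.
- The global PH test is an independence approximation across covariates.
- The mixed residualization mode approximates the two-random-intercept
  model with one random intercept plus fixed effects; with few studies the
  difference is negligible but it is not the literal crossed design.
- Decision-curve uncertainty (confidence bands) and competing risks are out
  of scope.
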