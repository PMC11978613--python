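# Methods

This note records the statistical model, the synthetic-data generator, the
numerical choices, and the design decisions that were genuinely open.

## 1. Model

### Longitudinal submodels

Each marker *k* is modeled on a transformed scale — square roots for dense
and nondense areas (both are right-skewed on the raw cm² scale), identity
for BMI — as

y<sub>ikj</sub> = x<sub>ik</sub>(t<sub>ij</sub>)′β<sub>k</sub> + b<sub>ik</sub> + ε<sub>ikj</sub>,

with age at mammogram as the time axis. The fixed effects are an intercept,
a natural cubic spline in age with 5 degrees of freedom, and baseline
covariates: BMI (centered at 25 kg/m²), HRT status
(never/previous/current/missing) and family history (no/yes/missing).
Missingness in the categorical covariates is an explicit level, never
dropped, mirroring how baseline tables report "missing data" rows. Random
effects are intercepts only; random slopes are deliberately out of scope
(between-subject slope heterogeneity is small relative to intercept
heterogeneity at screening cadence, and intercept-only effects keep the
marginal likelihood low-dimensional). The random intercepts across markers
share a K×K covariance Σ_b; residuals are correlated within a visit
(Σ_ε) and independent across visits. Within-visit-only residual
correlation is the natural choice when the error is dominated by the
image-processing measurement on a single mammogram.

### Survival submodel and association

The hazard on the age scale is log-linear in a natural-spline baseline
(explicit intercept + 5 spline columns), baseline covariates w (BMI, HRT,
FH; BMI is removed when the BMI trajectory itself is modeled), and the
current model-implied marker means ("expected value" association):

λ<sub>i</sub>(t) = exp( s₀(t)′ω + w<sub>i</sub>′γ + Σ<sub>k</sub> α<sub>k</sub> μ<sub>ik</sub>(t) ).

α_k is per unit of the transformed marker (√cm²; kg/m² for BMI); exported
hazard-ratio tables state this scale in their metadata. Only linear
(current-value) association structures are implemented.

### Left truncation

Women must be cancer-free at their first screen, so subjects enter risk sets
at their entry age. The default likelihood conditions on the random effects:
the survival factor is λ(T)^δ · exp(−Λ(entry→T)), with no re-weighting of
the random-effect prior by survival from the left boundary to entry. This is
standard delayed-entry practice and is exactly the mechanism of the
generator, which draws b unconditionally and simulates events from entry —
so recovery experiments are internally consistent. A fully marginal
correction (dividing by ∫ S(boundary→entry | b) φ(b) db) is available as
`truncation="marginal"` for sensitivity checks; it uses finite-difference
gradients because the analytic gradient covers only the conditional variant.

## 2. Likelihood and numerics

The per-subject marginal likelihood integrates the K random intercepts out
of (Gaussian visit densities) × (survival factor) × (random-effect prior).
Two code paths compute it:

* `subject_loglik` — the readable reference: per-subject adaptive
  Gauss–Hermite quadrature in K dimensions (default 7 nodes/dimension),
  centered and scaled at the posterior mode/curvature of b, found by Newton
  iterations on the log-concave integrand.
* `CohortLikelihood` — the fitting path, vectorized across subjects. The
  Gaussian part of the integrand is collapsed analytically (complete the
  square in b), after which the survival factor depends on b only through
  u = α′b; the K-dimensional integral therefore reduces **exactly** to a
  1-D integral over u ~ N(α′m_i, α′Q_i⁻¹α), evaluated by 1-D adaptive
  Gauss–Hermite (same node count). Both paths agree with each other to
  ~1e−12 and with brute-force dense-grid integration to well below 1e−6
  (tested).

Cumulative hazards use Gauss–Legendre quadrature: 30 nodes in the reference
`cumulative_hazard` operation, 15–21 nodes inside the fitter (the integrand
is a smooth exponential of a spline over ≤ ~8 years of follow-up; the
node-halving error is far below 1e−3 on cohort log-likelihoods, tested).

Fitting maximizes the total log-likelihood with L-BFGS-B using an
**analytic gradient** of the collapsed likelihood (verified against central
finite differences to ~1e−5 relative error). Covariance matrices are
parameterized by log-Cholesky factors, so every iterate is positive
definite. Starting values are staged: (1) per-marker OLS plus
moment-matched variance components, refined by fitting the longitudinal
model alone; (2) the spline-hazard survival submodel at α = 0; (3) all
parameters released. Convergence requires the optimizer's own success flag
(relative log-likelihood change below ~1e−11, projected gradient below
1e−3); anything else is flagged `converged=False`, never silently returned.
Standard errors come from the observed information: central differences of
the analytic gradient at the optimum (relative step 1e−4), inverted with a
pseudo-inverse fallback. Visits with a missing BMI measurement contribute
the marginal density of the observed markers (missingness patterns are
grouped and handled exactly); BMI is never imputed.

Degenerate inputs: subjects with zero follow-up contribute only their visit
densities; Σ_b → 0 collapses to the fixed-effects likelihood (tested);
α = 0 decouples the submodels.

## 3. Classic comparison models

Models 1–3 use the same age scale and delayed entry. Fitting is delegated
to lifelines (Cox PH with entry ages; counting-process Cox for time-updated
covariates; Efron ties throughout — simulated ages are continuous so ties
are rare, and Efron is the safer default). An independent Efron
partial-likelihood implementation in this package is the oracle the
library fits are tested against (the lifelines optimum must maximize it).
Continuous-exposure models enter √areas linearly, matching the joint
model's scale. Tertiles are cut at the 1/3 and 2/3 linear-interpolation
quantiles of the *entire* analysis sample's baseline raw areas and reused
unchanged in subgroups; the 2-df joint Wald test for the NDA tertile terms
is reported. Zero-variance covariate columns (e.g. an unused dummy level in
a small subgroup) are dropped before fitting and recorded.

The nested case–control design samples, for each case, m = 2 controls
without replacement from the risk set at the case's event age, matched on
entry age within ±2.5 years; both settings are configurable because the
exact published matching scheme for this design is not available. The
conditional logistic likelihood is maximized per matched set via
statsmodels' `ConditionalLogit`; with all-at-risk controls and no matching
it reproduces the Cox estimate (tested).

Median follow-up uses the reverse Kaplan–Meier estimator (censoring as the
event) on the follow-up-duration scale, with the median CI read off the
log−log Greenwood confidence band.

## 4. The synthetic-data generator

The generator emulates a population-based mammography screening cohort:

* **Entry ages and menopausal status.** Status (pre 40.1%, peri 3.8%,
  post 56.1%) doubles as the entry-age mixture component: truncated normals
  centered at 45 (pre), 52 (peri) and 62 (post) years, all within the 40–74
  screening window. This reproduces both the status frequencies and the
  overall median entry age of ~54. A latent menopause age is drawn
  consistently with status (ahead of entry for premenopausal women).
* **Visit cadence.** Log-normal inter-visit gaps with the log-median pinned
  to 1.97 years and the log-sd fitted to the published IQR ratio
  (2.11/1.61); at most 8 visits, none after age 74 or the administrative
  horizon. A two-parameter distribution cannot match median and both
  quartiles of a left-skewed interval distribution simultaneously; the
  median is matched exactly and the realized IQR is (≈1.70, ≈2.22) instead
  of (1.61, 2.11). Dropout beyond the event/censoring process is not
  modeled (config extension point).
* **Covariates.** HRT frequencies conditional on menopausal status, family
  history and parity marginal frequencies, and a log-normal baseline BMI
  (median 24.46, IQR-matched spread, clipped to 15–60) follow the published
  baseline table. "Missing" is generated as a category with its printed
  frequency.
* **Markers.** The three marker processes are simulated from exactly the
  mixed model the fitters estimate, with fixed age curves (√NDA rising and
  decelerating from ~9.6 to ~12.4 √cm², √DA falling from ~6.3 to ~4.3 √cm²,
  BMI drifting +0.03 kg/m²/year around the baseline value) projected onto
  the same spline basis used in fitting, so truths lie exactly in the
  fitted span. Variance components (σ_b = 1.80/1.45 √cm², σ_ε = 0.55 √cm²,
  intercept correlation −0.63, error correlation −0.43) and the +0.52
  √cm² per kg/m² BMI effect on √NDA were calibrated once, analytically plus
  one design-time Monte-Carlo check, so that the **raw-scale** correlations
  reproduce the published −0.506 (NDA–DA) and 0.696 (NDA–BMI). Raw areas
  are stored as squares of the √-scale draws, floored at zero (rare).
  The subject-table BMI is a questionnaire-style baseline value distinct
  from the visit-level BMI measurements, which avoids response/covariate
  circularity in the trivariate model.
* **Events.** Event ages invert Λ(entry→T) = −log U by bisection on
  [entry, entry + horizon] (60 iterations; the root is bracketed because
  administrative censoring applies beyond the horizon), with the cumulative
  hazard evaluated by 30-node Gauss–Legendre quadrature. The default
  baseline log-hazard is linear in age (slope 0.035/yr, level at age 55 set
  so the event fraction is a cohort-realistic ~2.5–3% over the default
  7.9-year administrative window). `survival_mode` selects whether the true
  hazard is the bivariate model (baseline BMI in γ) or the trivariate model
  (BMI trajectory through α); the recorded truth object always matches the
  selected mode exactly.

**What passing tests show, and what they do not.** The generator is the
fitted model plus published summary statistics; recovery tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions (including correct coverage and the closed-form exponential
limit), not robustness to real-data features such as informative dropout,
digital/analog device changes, within-woman BMI measurement regimes, or
image-side selection — all of which are upstream of this package.

## 5. Scaled-down experiment sizes

Recovery experiments use cohorts of 800–1500 women with the baseline hazard
raised to ~10% cumulative incidence (`recovery_config`), chosen so each
replicate carries 100–200 events — enough information for stable
association estimates at desk scale while the full-size cohort (62k women,
~2.5% incidence) carries the same information per event. Replicate counts
(8–10) put the Monte-Carlo error of mean estimates near 0.01 on the log-HR
scale. The 20 000-subject default cohort used for the correlation and
visit-gap summaries matches those quantities' published precision to two
decimals.

## 6. Known limitations

* Intercept-only random effects; no current-slope or cumulative
  association structures; no competing risks (death is censoring), cure
  fractions, dynamic prediction, or Bayesian inference.
* The marginal (unconditional) left-truncation correction has no analytic
  gradient path and is slower to fit.
* The nested case–control matching defaults are placeholders for an
  unavailable published scheme and are clearly configurable.
* Tertile cut points in subgroup analyses reuse the full-sample cuts;
  subgroup-specific cuts would need a one-line configuration change.
* The generator produces one marker series per woman; mammographic view
  (MLO/CC) and image-side selection are metadata-level concepts here.
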