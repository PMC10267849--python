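# Methods

## Pharmacokinetic exposure construction

Each drug is described by a linear mammillary model with central volume
`V1` (L), rate constants `k10, k12, k21, k13, k31` (1/min) and an effect
compartment coupled by `ke0`:

```
dA1/dt = -(k10 + k12 + k13) A1 + k21 A2 + k31 A3      (amounts, µg)
dA2/dt =  k12 A1 - k21 A2
dA3/dt =  k13 A1 - k31 A3
dCe/dt =  ke0 (A1/V1 - Ce)                            (ng/mL)
```

IV boluses are instantaneous jumps of `A1`. Between boluses the
four-state linear system is propagated *exactly*: the generator matrix is
eigendecomposed once per parameter set and each inter-bolus segment is
evaluated in closed form on the sampling grid; if the spectrum is
degenerate (e.g. `ke0 = k10`, which makes the matrix defective) the code
falls back to per-offset matrix exponentials. Consequences: superposition
and dose linearity hold to ~1e-13, concentrations are nonnegative, and
refining the grid only changes the trapezoidal window mean, not the
trajectory. Default grid `dt = 0.1` min (configurable; statistical
analyses in the tests use 0.5–2 min, where the quadrature error of the
window mean is far below the Monte-Carlo noise of any estimate).

The exposure is the time-average of `Ce` over the patient's
intraoperative window, computed by trapezoidal quadrature with
interpolated endpoints. Patients with no bolus of a drug before window
end have exposure exactly 0 — this is the point mass that drives the
two-part propensity model. Shipped default PK parameters
(`data/pk_defaults.yaml`) are literature-style adult values for IV
fentanyl (fast effect-site equilibration, `ke0 ≈ 0.15`/min) and
hydromorphone (slow, `ke0 ≈ 0.03`/min); the code treats them as opaque
configuration and every test uses synthetic parameters. MME conversion
factors are likewise config-only (defaults: fentanyl 0.1, hydromorphone
0.004 MME/µg).

Infusions and covariate-adjusted (allometric) PK parameterizations are out
of scope; per-drug parameter overrides are a config hook
(`GeneratorConfig.pk_overrides`, `--pk`).

## Synthetic cohort

`cohort_synth.default_config()` encodes the study conditions the package
is demonstrated under:

* covariates of all four kinds — age ~ N(55.4, 17.1²) truncated to
  [18, 95], BMI ~ N(27.9, 6²), female (p = 0.535), opioid-naive
  (p = 0.807), ordinal ASA I–IV (11.4/58.8/28.4/1.4%), categorical
  surgical service (six levels at the reported frequencies);
* per drug, a semicontinuous dose model: `P(no dose) = expit(γ0'x)` and
  positive total dose LogNormal(γ+'x, τ), split into 1–5 equal boluses
  whose times are Beta(1,3)-front-loaded (fentanyl) or uniform
  (hydromorphone) over the window; windows are log-normal around 90 min.
  Zero-part intercepts were solved numerically (once, at n = 200 000) so
  the marginal zero fractions hit 7.3% / 36.4%, and dose scales were set
  so exposure medians land near 0.5 ng/mL with cross-drug Pearson
  r ≈ −0.04;
* exposures are produced by running the generated dosing records through
  the PK module itself, so the generator cannot drift from the exposure
  code (round-trip agreement is asserted at 1e-6);
* outcomes with known coefficients on the *realized* exposures:
  proportional-odds 0–10 pain (11 categories, latent-logistic), hurdle
  MME (logit zero part + log-normal positive part), exponential
  time-to-event with administrative censoring (constant baseline hazard,
  so the Cox expected-time machinery has a known truth), and Bernoulli
  binary outcomes. The default set carries one outcome per family; the
  config accepts any number.

What the generator does *not* emulate: EHR messiness (unit errors,
duplicated records), informative missingness (only an optional MCAR-style
complete-case path), the joint covariate distribution of a real surgical
population (marginals only), infusion dosing, and outcome dependence on
the full concentration *trajectory* rather than its window mean. Passing
tests therefore certify the statistical machinery under a correctly
specified data-generating process, not robustness to real-EHR pathology.

`strong_confounding_config()` is a second preset used for balance
diagnostics, with two binary confounders whose zero-part coefficients
(±2.0) push each confounder's unweighted exposure correlation above 0.3.
The confounding deliberately lives in the zero part with bounded cell
probabilities: that keeps the stabilized weights light-tailed, so
99.5th-percentile trimming removes rows from a homogeneous high-weight
block. We found (and verified with oracle true-density weights) that when
strong confounding sits in the positive log-dose part instead, the largest
weights are exactly the balance-carrying observations and percentile
*discarding* re-introduces up to two-thirds of the unweighted correlation
— a practical caveat for weight-trimming pipelines generally.

## Propensity model and weights

Per drug: logistic regression of `1{E = 0}` on the confounder design
(categoricals one-hot, reference dropped) and OLS of `log E` on the same
design over the positive subset, with residual SD from the residual mean
square; marginal analogues are intercept-only. The stabilized weight uses
the density of `log E` in both numerator and denominator (the `1/E`
Jacobian cancels), multiplies across the two drugs (justified by their
near-independence; a joint-density variant would be a config extension),
and rows with combined weight strictly above the empirical 99.5th
percentile are flagged and excluded from all weighted computations —
"discarded", not capped. Exact ties at the boundary survive (strict `>`),
which also makes the all-weights-equal edge case trim nothing.

Balance diagnostics: weighted Pearson (weighted moments) for continuous
and binary covariates — binary via point-biserial, categorical expanded
level by level including the reference — and a pair-weighted Kendall
tau-b (`w_i w_j` pair weights, tie-corrected) for ordinal covariates,
computed blockwise in O(n²). Unit weights reduce both to their classical
estimates (asserted to 1e-12 against scipy).

## Outcome models

Designs standardize exposures and continuous covariates to weighted mean
0 / SD 1 on the untrimmed sample (unweighted moments are a switch);
transformation metadata is stored and replayed verbatim on counterfactual
copies. Families:

* **Proportional odds** (own implementation): `P(Y ≤ k | x) =
  expit(α_k − x'β)`, thresholds parametrized as a first cutpoint plus
  positive log-increments, weighted NLL minimized by BFGS with analytic
  gradients (`gtol 1e-8`); observed-information SEs from a
  finite-difference Hessian of the gradient. Unobserved interior
  categories are merged (with a warning) so small cohorts stay
  well-posed. statsmodels' `OrderedModel` (unweighted) is the independent
  cross-check at 1e-6. Written in-package because statsmodels has no
  observation-weighted ordinal model.
* **Hurdle**: weighted GLM logistic on `1{Y > 0}` plus weighted least
  squares of `log Y` on the positives; `σ²` is the weighted mean squared
  residual. Components are reported separately; predictions combine them
  as `P(Y>0|x)·exp(μ(x) + σ²/2)`.
* **Cox**: lifelines `CoxPHFitter` (Efron ties, `precision 1e-12`) on the
  weighted partial likelihood, plus the constant-baseline-hazard profile
  estimate `h0 = Σ w d / Σ w t e^{x'β}` stored for expected-time
  prediction only — the fit itself stays semiparametric. A weighted
  Breslow Newton solver is available as `ties="breslow"`; note that
  splitting observations into half-weight duplicates is exactly
  fit-invariant under Breslow but only approximately under Efron (the
  duplicates form ties).
* **Logistic**: weighted GLM (binomial, `var_weights`); apparent
  separation (|coef| > 30) is rejected naming the offending column.

Effect estimates are `exp(β)` per 1 SD of exposure: odds ratios, two per
exposure for hurdle models (binomial and log-normal components), hazard
ratios for Cox (ratio > 1 ⇒ higher event rate ⇒ *shorter* expected time).
Adjustment covariates are fitted but not surfaced by default — they are
not confounding-controlled and should not be interpreted. Model CIs come
from the bootstrap below; Wald SEs are diagnostics only.

## Counterfactuals

Interventions are mechanistic: one extra bolus (default at window start,
where fentanyl dosing concentrates; window-mid and custom times are
config) inserted into each record and re-simulated, so the counterfactual
exposure respects the PK nonlinearity of time-averaging (and its
linearity in dose). Expected outcomes per family — ordinal `Σ k P(Y=k)`
treating the 0–10 categories as numeric, hurdle `p·exp(μ+σ²/2)`, logistic
probability (reported per 1000), Cox `1/(h0 e^{x'β})` — are averaged over
the **unweighted, untrimmed** population under observed and counterfactual
exposure; the mean difference and its percent of the predicted baseline
are reported. Counterfactual exposures beyond 1.5× the observed maximum
flag (not reject) extrapolation. Percentile bootstrap (default B = 200)
resamples patients with replacement and re-runs propensity fitting,
trimming, standardization, model fitting, and prediction per replicate;
failed replicates are counted and >10% failures abort. BCa was not used —
a plain percentile interval matches the pipeline's scale of precision and
re-runs cheaply.

## Numerical and testing choices

Problem sizes were chosen so the full suite demonstrates each property at
sensible Monte-Carlo precision: single-replicate coefficient recovery at
n = 20 000, bias over 20 replicates at n = 10 000, bootstrap coverage over
100 replicates of n = 2 000 with B = 100, generator-vs-PK round trips at
n = 2 000, and balance at n = 5 000; PK statistical runs use coarse grids
(0.5–2 min) since the propagation is exact and only the quadrature of the
window mean depends on the grid. Determinism: every stage derives its
generator from `numpy.random.SeedSequence([master_seed, stage])`, and
pipeline reruns with one seed are byte-identical.

Known limitations: the GPS density is parametric (two-part log-normal) and
inherits that family's misspecification risk; the hurdle positive part is
least squares on `log Y` rather than a log-link GLM (a deliberate,
documented choice); proportional odds and proportional hazards are
assumed, not tested; and percentile-trimmed weighting can re-introduce
confounding when weights are heavy-tailed (see above) — balance tables
should always be read after trimming, as produced here.
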