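# opioidcf

Causal-style analysis of intraoperative opioid dosing and postoperative
outcomes. The package reimplements, as a tested and reusable pipeline, the
inference chain that links raw intraoperative IV bolus records to
counterfactual predictions of postoperative pain, opioid use, length of
stay, and binary complications:

1. **Exposure construction (`opioidcf.pkpd`).** Each patient's fentanyl and
   hydromorphone boluses are pushed through linear two/three-compartment
   pharmacokinetic models with an effect compartment
   (`dCe/dt = ke0 (Cp − Ce)`); the exposure is the mean effect-site
   concentration `E = (1/T) ∫ Ce(t) dt` over the intraoperative window,
   in ng/mL. The linear system is propagated exactly between boluses, so
   superposition and dose linearity hold to machine precision. Total doses
   are also converted to morphine milligram equivalents (MME).
2. **Generalized propensity weighting (`opioidcf.weighting`).** Both
   exposures are semicontinuous (a point mass at zero plus a positive
   bulk), so the conditional exposure density given confounders is modeled
   as a two-part density: logistic `P(E = 0 | x)` plus log-normal
   `log E | E > 0, x`. Stabilized weights `w = f(E) / f(E | x)` are the
   product over the two (near-independent) drugs; raw weights strictly
   above the empirical 99.5th percentile are discarded. Balance tables
   report each covariate's correlation with each exposure before and after
   weighting (Pearson for continuous/binary, weighted Kendall tau-b for
   ordinal).
3. **Weighted outcome models (`opioidcf.outcome_models`).** Four families,
   all maximizing weight-multiplied likelihoods on standardized designs:
   proportional-odds ordinal regression for 0–10 pain scores, hurdle
   (binomial + log-normal) models for MME outcomes, Cox proportional
   hazards (Efron ties) for times-to-event, and logistic regression for
   binary outcomes. Effect estimates are `exp(β)` per 1 SD of exposure.
4. **g-computation counterfactuals (`opioidcf.counterfactual`).** A
   hypothetical additional bolus (e.g. fentanyl 100 µg) is inserted into
   every dosing record, the PK simulation is re-run, and the fitted models
   predict each patient's expected outcome under observed vs
   counterfactual exposure; the unweighted population mean difference is
   the reported quantity, with percentile bootstrap CIs that re-run the
   entire pipeline (weights, trimming, fits) on every resample. Expected
   event times use a constant-baseline-hazard profile estimate
   `h0 = Σ w d / Σ w t exp(x'β)`, i.e. `E[T | x] = 1 / (h0 exp(x'β))`.

Because the EHR cohort behind such a study cannot be redistributed, the
package ships a first-class synthetic-cohort generator
(`opioidcf.cohort_synth`) with known ground truth, calibrated to the
reported cohort structure: 7.3% zero-fentanyl and 36.4% zero-hydromorphone
patients, bimodal exposures with medians near 0.5 ng/mL, cross-drug
Pearson correlation ≈ −0.03, front-loaded fentanyl vs uniformly spread
hydromorphone bolus timing, and real confounding between covariates and
exposures. All statistical guarantees are demonstrated against this
generator's truth.

## Worked example

```python
from opioidcf import cohort_synth as cs, weighting as wt, counterfactual as cf

syn = cs.generate_cohort(cs.default_config(2000), seed=7)
model = wt.fit_propensity(syn.cohort, syn.config.confounders())
weights = wt.compute_weights(model, syn.cohort)
print(weights["raw_weight"].mean(), int(weights["trimmed"].sum()))
# 1.161  10   <- stabilized weights average ~1; 10/2000 above the 99.5th pct

iv = cf.Intervention("fentanyl", 100.0)
pairs = cf.apply_intervention(syn.dosing, iv, syn.config.pk_params())
res = cf.bootstrap_ci(
    syn.cohort, pairs, "pain_pacu_max", "ordinal", syn.config.roles(),
    syn.config.confounders(), [c.name for c in syn.config.covariates],
    iv, B=100, seed=7,
)
print(f"{res.mean_change:+.3f} ({res.ci_low:+.3f} to {res.ci_high:+.3f})")
# -0.680 (-0.848 to -0.496)
```

Read: an additional 100 µg of intraoperative fentanyl raises every
patient's window-mean effect-site concentration (by ≈0.5 ng/mL on average
here) and the fitted proportional-odds model predicts a **0.68-point mean
reduction** in the 0–10 PACU maximum pain score, with a 95% bootstrap CI
of (−0.85, −0.50). The generator's true fentanyl→pain coefficient is
negative, so the sign and rough magnitude are as expected; the same call
with a hurdle/Cox/logistic outcome returns MME, expected-time, and
per-1000 risk changes.

The same chain is available as numbered scripts (`analysis/01_simulate.py`
… `analysis/05_counterfactual.py`, writing tables under `results/`) and as
a CLI:

```bash
opioidcf run-all --out-dir out/ --n 2000 --seed 7 --b 200
opioidcf simulate|exposure|weigh|fit|counterfactual --help
```

`run-all` writes `balance.csv` (covariate balance before/after weighting),
`forest.csv` (odds/hazard ratios per 1 SD of exposure), `table2.csv`
(counterfactual mean changes with CIs) and a `manifest.json` with row,
trim, and drop counts; reruns with the same seed are byte-identical.

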