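"""g-computation counterfactuals with percentile bootstrap CIs.

The causal contrast of interest is the population-mean expected change in
each outcome if every patient had additionally received one intraoperative
bolus (e.g. fentanyl 100 ug or hydromorphone 500 ug). The counterfactual
exposure is constructed mechanistically: the extra bolus is inserted into
the patient's dosing record at a configurable policy time (window start by
default, where fentanyl boluses concentrate), the effect-site trace is
re-simulated, and the window mean recomputed. Fitted outcome models then
predict each patient's expected outcome under the observed and
counterfactual exposures with all other covariates held fixed, and the
differences are averaged over the *unweighted, untrimmed* study population.

Confidence intervals come from a patient-level nonparametric bootstrap
that re-runs the entire estimation pipeline (propensity fit, weight
trimming, standardization, outcome fit, prediction) on every resample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import outcome_models as om
from . import pkpd
from . import weighting as wt

__all__ = [
    "Intervention",
    "CounterfactualResult",
    "apply_intervention",
    "predict_mean_change",
    "bootstrap_ci",
    "shift_exposure",
]


@dataclass(frozen=True)
class Intervention:
    """An incremental intraoperative bolus.

    ``time_policy``: 'window-start', 'window-mid', or a float (minutes).
    """

    drug: str
    dose: float  # ug
    time_policy: object = "window-start"

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("intervention dose must be > 0")

    def insertion_time(self, record: pkpd.DosingRecord) -> float:
        if self.time_policy == "window-start":
            t = record.window_start
        elif self.time_policy == "window-mid":
            t = 0.5 * (record.window_start + record.window_end)
        else:
            t = float(self.time_policy)
        if not record.window_start <= t <= record.window_end:
            raise ValueError(
                f"insertion time {t} outside window "
                f"[{record.window_start}, {record.window_end}]"
            )
        return t


@dataclass(frozen=True)
class CounterfactualResult:
    outcome: str
    family: str
    intervention: Intervention
    mean_change: float  # outcome units (probability for binary)
    percent_change: float  # 100 * mean_change / baseline mean
    baseline_mean: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    pct_ci_low: float = np.nan
    pct_ci_high: float = np.nan
    n_bootstrap: int = 0
    n_failed: int = 0
    flags: tuple[str, ...] = field(default=())

    def per_1000(self) -> tuple[float, float, float]:
        """Binary-outcome presentation: change in events per 1000 patients."""
        return (
            1000 * self.mean_change,
            1000 * self.ci_low,
            1000 * self.ci_high,
        )


def apply_intervention(
    dosing: dict[str, pkpd.DosingRecord],
    intervention: Intervention,
    pk_params: dict[str, pkpd.PKModelParameters],
    dt: float = 0.5,
    observed: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Observed and counterfactual window-mean exposure per patient.

    Only the intervened drug is (re)simulated; PK linearity guarantees the
    counterfactual exposure is the observed one plus the window mean of the
    single inserted bolus, and that it scales linearly in the dose.
    ``observed`` optionally supplies already-computed window means per
    patient (e.g. the cohort's exposure column) to skip re-simulating the
    observed records.
    """
    drug = intervention.drug
    params = pk_params[drug]
    rows = []
    for pid, rec in dosing.items():
        if observed is not None:
            obs = float(observed[pid])
        else:
            sub = rec.for_drug(drug)
            if sub.events:
                trace = pkpd.simulate_effect_site(sub, params, dt=dt)
                obs = pkpd.mean_window_concentration(
                    trace, rec.window_start, rec.window_end
                )
            else:
                obs = 0.0
        t_ins = intervention.insertion_time(rec)
        extra = pkpd.DosingRecord(
            pid, (pkpd.BolusEvent(t_ins, intervention.dose, drug),),
            rec.window_start, rec.window_end,
        )
        tr2 = pkpd.simulate_effect_site(extra, params, dt=dt)
        delta = pkpd.mean_window_concentration(tr2, rec.window_start, rec.window_end)
        rows.append(
            {"patient_id": pid, "observed": obs, "counterfactual": obs + delta}
        )
    return pd.DataFrame(rows)


def shift_exposure(
    cohort: pd.DataFrame, exposure_col: str, exposure_pairs: pd.DataFrame
) -> pd.DataFrame:
    """Counterfactual copy of the cohort with one exposure column replaced."""
    pairs = exposure_pairs.set_index("patient_id").loc[cohort["patient_id"]]
    out = cohort.copy()
    out[exposure_col] = pairs["counterfactual"].to_numpy()
    return out


def predict_mean_change(
    model: om.FittedOutcomeModel,
    cohort: pd.DataFrame,
    exposure_pairs: pd.DataFrame,
    intervention: Intervention,
    exposure_col: str | None = None,
    extrapolation_factor: float = 1.5,
) -> CounterfactualResult:
    """Mean expected outcome change over the full (unweighted, untrimmed)
    population under the intervention, with all other covariates fixed.

    Counterfactual exposures beyond ``extrapolation_factor`` times the
    observed maximum are flagged (not rejected): predictions there lean on
    the model beyond the support of the data.
    """
    if exposure_col is None:
        exposure_col = f"mean_Ce_{intervention.drug}"
    X_obs = om.replay_design(cohort, model.info)
    cf = shift_exposure(cohort, exposure_col, exposure_pairs)
    X_cf = om.replay_design(cf, model.info)

    flags: list[str] = []
    obs_max = float(cohort[exposure_col].max())
    cf_max = float(cf[exposure_col].max())
    if obs_max > 0 and cf_max > extrapolation_factor * obs_max:
        msg = (
            f"counterfactual {exposure_col} max {cf_max:.3g} exceeds "
            f"{extrapolation_factor} x observed max {obs_max:.3g}"
        )
        warnings.warn(msg, stacklevel=2)
        flags.append("extrapolation")

    pred_obs = om.predict_expectation(model, X_obs)
    pred_cf = om.predict_expectation(model, X_cf)
    baseline = float(np.mean(pred_obs))
    change = float(np.mean(pred_cf - pred_obs))
    pct = 100.0 * change / baseline if baseline != 0 else np.nan
    return CounterfactualResult(
        outcome=model.outcome,
        family=model.family,
        intervention=intervention,
        mean_change=change,
        percent_change=pct,
        baseline_mean=baseline,
        flags=tuple(flags),
    )


def _fit_family(design, cohort, outcome, family, event_col, wvec):
    # accept the generator's family labels as synonyms
    family = {"binary": "logistic", "tte": "cox"}.get(family, family)
    y = cohort[outcome].to_numpy()
    if family == "ordinal":
        return om.fit_ordinal(design, y, wvec)
    if family == "hurdle":
        return om.fit_hurdle(design, y, wvec)
    if family == "logistic":
        return om.fit_logistic(design, y, wvec)
    if family == "cox":
        return om.fit_cox(design, y, cohort[event_col].to_numpy(), wvec)
    raise ValueError(f"unknown family {family!r}")


def run_outcome_analysis(
    cohort: pd.DataFrame,
    outcome: str,
    family: str,
    roles: dict,
    confounders,
    adjustment_vars,
    exposure_cols=wt.DEFAULT_EXPOSURES,
    event_col: str | None = None,
    trim_percentile: float = 99.5,
    weighted_scaling: bool = True,
):
    """One full estimation pass: propensity -> weights -> design -> fit.

    Returns (model, weights frame). This is the unit the bootstrap re-runs.
    """
    pm = wt.fit_propensity(cohort, confounders, exposure_cols)
    w = wt.compute_weights(pm, cohort, trim_percentile)
    keep = ~w["trimmed"].to_numpy()
    sub = cohort.loc[keep].reset_index(drop=True)
    wsub = w.loc[keep].reset_index(drop=True)
    design = om.build_design(
        sub, wsub, adjustment_vars, roles, exposure_cols, weighted_scaling
    )
    model = _fit_family(
        design, sub, outcome, family, event_col, wsub["weight"].to_numpy()
    )
    model = om.FittedOutcomeModel(
        family=model.family, outcome=outcome, info=model.info, coefs=model.coefs,
        thresholds=model.thresholds, category_values=model.category_values,
        sigma=model.sigma, h0=model.h0, converged=model.converged,
        diagnostics=model.diagnostics,
    )
    return model, w


def bootstrap_ci(
    cohort: pd.DataFrame,
    exposure_pairs: pd.DataFrame,
    outcome: str,
    family: str,
    roles: dict,
    confounders,
    adjustment_vars,
    intervention: Intervention,
    B: int = 200,
    seed: int = 0,
    event_col: str | None = None,
    trim_percentile: float = 99.5,
    exposure_cols=wt.DEFAULT_EXPOSURES,
    max_failure_fraction: float = 0.1,
) -> CounterfactualResult:
    """Point estimate plus percentile bootstrap CI for the mean change.

    Every replicate resamples patients with replacement and re-runs the
    entire pipeline (propensity fit, trimming, standardization, outcome
    fit, g-computation). Replicates whose model fit fails are dropped and
    counted; more than ``max_failure_fraction`` failures aborts.
    ``B == 0`` skips resampling and returns the point estimate with
    degenerate CIs equal to it.
    """
    model, _ = run_outcome_analysis(
        cohort, outcome, family, roles, confounders, adjustment_vars,
        exposure_cols, event_col, trim_percentile,
    )
    point = predict_mean_change(model, cohort, exposure_pairs, intervention)
    if B == 0:
        return CounterfactualResult(
            **{**point.__dict__, "ci_low": point.mean_change,
               "ci_high": point.mean_change, "pct_ci_low": point.percent_change,
               "pct_ci_high": point.percent_change, "n_bootstrap": 0}
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 91]))
    n = len(cohort)
    changes, pcts = [], []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = cohort.iloc[idx].reset_index(drop=True)
        # resampled patients keep their own exposure pair; realign by position
        pairs = exposure_pairs.set_index("patient_id").loc[
            cohort["patient_id"]].iloc[idx].reset_index()
        # duplicate patients must stay distinct rows for design alignment
        new_ids = [f"B{i:07d}" for i in range(n)]
        boot = boot.assign(patient_id=new_ids)
        pairs = pairs.assign(patient_id=new_ids)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # flags already on the point estimate
                bmodel, _ = run_outcome_analysis(
                    boot, outcome, family, roles, confounders, adjustment_vars,
                    exposure_cols, event_col, trim_percentile,
                )
                res = predict_mean_change(bmodel, boot, pairs, intervention)
        except (ValueError, RuntimeError, FloatingPointError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        changes.append(res.mean_change)
        pcts.append(res.percent_change)
    if n_failed > max_failure_fraction * B:
        raise RuntimeError(
            f"bootstrap unstable: {n_failed}/{B} replicates failed"
        )
    lo, hi = np.percentile(changes, [2.5, 97.5])
    plo, phi = np.percentile(pcts, [2.5, 97.5])
    return CounterfactualResult(
        outcome=outcome, family=family, intervention=intervention,
        mean_change=point.mean_change, percent_change=point.percent_change,
        baseline_mean=point.baseline_mean,
        ci_low=float(lo), ci_high=float(hi),
        pct_ci_low=float(plo), pct_ci_high=float(phi),
        n_bootstrap=B - n_failed, n_failed=n_failed, flags=point.flags,
    )
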