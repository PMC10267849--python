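"""End-to-end orchestration: simulate -> exposures -> weigh -> fit ->
counterfactual, emitting the three headline tables.

Artifacts written to the output directory:

* ``cohort.csv`` / ``dosing.csv`` / ``windows.csv`` — the (synthetic) study data;
* ``weights.csv`` — stabilized weights with the trimming flag;
* ``balance.csv`` — covariate-exposure correlations, unweighted and weighted;
* ``forest.csv`` — exponentiated exposure coefficients per outcome/component;
* ``table2.csv`` — counterfactual mean expected changes with bootstrap CIs;
* ``manifest.json`` — row counts, dropped/trimmed counts, seed, versions.

Stages communicate only through these documented file formats / frames; a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cohort_synth as cs
from . import counterfactual as cf
from . import outcome_models as om
from . import pkpd
from . import weighting as wt


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    seed: int = 0
    n_patients: int = 2000
    B: int = 200
    trim_percentile: float = 99.5
    dt: float = 0.5
    interventions: tuple[cf.Intervention, ...] = (
        cf.Intervention("fentanyl", 100.0),
        cf.Intervention("hydromorphone", 500.0),
    )
    row_filter: str | None = None  # pandas query over the cohort, e.g. "bmi > 30"
    generator: cs.GeneratorConfig | None = None  # None -> default study conditions

    def __post_init__(self) -> None:
        if not 50 < self.trim_percentile < 100:
            raise ValueError("trim_percentile must be in (50, 100)")


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts stay on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_dosing(dosing: dict[str, pkpd.DosingRecord], out: Path) -> None:
    rows = [
        {"patient_id": pid, "drug": e.drug, "time_min": e.time, "dose_ug": e.dose}
        for pid, rec in dosing.items()
        for e in rec.events
    ]
    pd.DataFrame(rows, columns=["patient_id", "drug", "time_min", "dose_ug"]).to_csv(
        out / "dosing.csv", index=False
    )
    pd.DataFrame(
        [
            {"patient_id": pid, "window_start_min": r.window_start,
             "window_end_min": r.window_end}
            for pid, r in dosing.items()
        ]
    ).to_csv(out / "windows.csv", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "B": config.B,
        "trim_percentile": config.trim_percentile,
        "versions": {"opioidcf": __version__},
    }

    stage = "simulate"
    try:
        gen = config.generator or cs.default_config(config.n_patients, pk_dt=config.dt)
        syn = cs.generate_cohort(gen, config.seed)
        cohort, dosing = syn.cohort, syn.dosing
        cohort.to_csv(out / "cohort.csv", index=False)
        _write_dosing(dosing, out)
        roles = gen.roles()
        confounders = gen.confounders()
        adjustment = [c.name for c in gen.covariates]
        outcome_specs = [
            (o.name, o.family, f"{o.name}_event" if o.family == "tte" else None)
            for o in gen.outcomes
        ]
        manifest["n_simulated"] = len(cohort)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    stage = "complete_cases"
    try:
        cohort, n_dropped = wt.complete_cases(cohort)
        manifest["n_dropped_incomplete"] = n_dropped
        if config.row_filter:
            cohort = cohort.query(config.row_filter).reset_index(drop=True)
            dosing = {p: dosing[p] for p in cohort["patient_id"]}
        manifest["n_analyzed"] = len(cohort)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "weigh"
    try:
        pm = wt.fit_propensity(cohort, confounders)
        weights = wt.compute_weights(pm, cohort, config.trim_percentile)
        weights.to_csv(out / "weights.csv", index=False)
        balance = wt.balance_diagnostics(cohort, weights, roles)
        balance.to_csv(out / "balance.csv", index=False)
        manifest["n_trimmed"] = int(weights["trimmed"].sum())
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "fit"
    try:
        keep = ~weights["trimmed"].to_numpy()
        sub = cohort.loc[keep].reset_index(drop=True)
        wsub = weights.loc[keep].reset_index(drop=True)
        design = om.build_design(sub, wsub, adjustment, roles)
        wvec = wsub["weight"].to_numpy()
        models = {}
        forest_rows = []
        for name, family, event_col in outcome_specs:
            fam = "tte" if family == "tte" else family
            model = cf._fit_family(
                design, sub, name, "cox" if fam == "tte" else fam, event_col, wvec
            )
            model = om.FittedOutcomeModel(
                family=model.family, outcome=name, info=model.info,
                coefs=model.coefs, thresholds=model.thresholds,
                category_values=model.category_values, sigma=model.sigma,
                h0=model.h0, converged=model.converged, diagnostics=model.diagnostics,
            )
            models[name] = (model, event_col)
            for est in om.effect_estimates(model):
                forest_rows.append(
                    {"outcome": name, "exposure": est.exposure,
                     "component": est.component, "kind": est.kind,
                     "ratio": est.ratio}
                )
        pd.DataFrame(forest_rows).to_csv(out / "forest.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "counterfactual"
    try:
        pk_params = gen.pk_params()
        rows = []
        for iv in config.interventions:
            obs = dict(zip(cohort["patient_id"], cohort[f"mean_Ce_{iv.drug}"]))
            pairs = cf.apply_intervention(
                dosing, iv, pk_params, dt=config.dt, observed=obs
            )
            for name, family, event_col in outcome_specs:
                res = cf.bootstrap_ci(
                    cohort, pairs, name,
                    "cox" if family == "tte" else family,
                    roles, confounders, adjustment, iv,
                    B=config.B, seed=config.seed, event_col=event_col,
                    trim_percentile=config.trim_percentile,
                )
                scale = 1000.0 if family == "binary" else 1.0
                rows.append(
                    {"outcome": name, "family": family, "drug": iv.drug,
                     "dose_ug": iv.dose,
                     "units": "per 1000" if family == "binary" else "outcome units",
                     "change": scale * res.mean_change,
                     "ci_low": scale * res.ci_low, "ci_high": scale * res.ci_high,
                     "percent_change": res.percent_change,
                     "pct_ci_low": res.pct_ci_low, "pct_ci_high": res.pct_ci_high,
                     "n_bootstrap": res.n_bootstrap, "n_failed": res.n_failed}
                )
        pd.DataFrame(rows).to_csv(out / "table2.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    manifest["outcomes"] = [name for name, _, _ in outcome_specs]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
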