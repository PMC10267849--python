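"""Weighted outcome models and the forest table of effect estimates.

Fits the four weighted families (proportional-odds pain score, two-part
MME, Cox length of stay, logistic uncontrolled pain) on the reweighted
cohort and writes exponentiated exposure coefficients — odds/hazard ratios
per 1 SD of effect-site exposure — to results/forest.csv.
"""

from pathlib import Path

import pandas as pd

from opioidcf import cohort_synth as cs
from opioidcf import counterfactual as cf
from opioidcf import outcome_models as om

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = pd.read_csv(ROOT / "sim" / "cohort.csv")
    weights = pd.read_csv(ROOT / "weights.csv")
    config = cs.default_config(len(cohort))
    keep = ~weights["trimmed"].to_numpy()
    sub = cohort.loc[keep].reset_index(drop=True)
    wsub = weights.loc[keep].reset_index(drop=True)
    adjustment = [c.name for c in config.covariates]
    design = om.build_design(sub, wsub, adjustment, config.roles())
    wvec = wsub["weight"].to_numpy()

    rows = []
    for spec in config.outcomes:
        event_col = f"{spec.name}_event" if spec.family == "tte" else None
        model = cf._fit_family(design, sub, spec.name, spec.family, event_col, wvec)
        model = om.FittedOutcomeModel(**{**model.__dict__, "outcome": spec.name})
        for est in om.effect_estimates(model):
            rows.append({"outcome": spec.name, "exposure": est.exposure,
                         "component": est.component, "kind": est.kind,
                         "ratio": est.ratio})
    forest = pd.DataFrame(rows)
    forest.to_csv(ROOT / "forest.csv", index=False)
    print("effect estimates (ratio per 1 SD of exposure):")
    print(forest.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
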