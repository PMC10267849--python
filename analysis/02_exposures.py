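"""Rebuild effect-site exposures from the raw dosing records.

Re-runs the compartmental PK simulation on results/sim/dosing.csv and
verifies that the window-mean effect-site concentrations match the ones the
generator emitted (they must: the generator routes its own exposures
through the same PK code). Writes results/exposures.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from opioidcf import pkpd

ROOT = Path(__file__).resolve().parents[1] / "results"
DT = 0.5


def main() -> None:
    records = pkpd.read_dosing_csv(ROOT / "sim" / "dosing.csv",
                                   ROOT / "sim" / "windows.csv")
    params = pkpd.load_pk_params()
    summary = pkpd.summarize_exposures(records, params, dt=DT)
    summary.to_csv(ROOT / "exposures.csv", index=False)
    cohort = pd.read_csv(ROOT / "sim" / "cohort.csv").set_index("patient_id")
    redo = summary.set_index("patient_id").loc[cohort.index]
    for drug in ("fentanyl", "hydromorphone"):
        err = np.max(np.abs(redo[f"mean_Ce_{drug}"] - cohort[f"mean_Ce_{drug}"]))
        print(f"{drug}: max round-trip discrepancy {err:.2e} ng/mL")
    print(f"wrote {len(summary)} exposure summaries to results/exposures.csv")


if __name__ == "__main__":
    main()
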