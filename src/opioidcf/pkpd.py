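"""Compartmental pharmacokinetics with an effect compartment.

Converts per-patient intravenous bolus records into plasma (Cp) and
effect-site (Ce) concentration traces, window-mean exposure summaries, and
total morphine-milligram-equivalent (MME) doses.

The model is the standard linear mammillary system (two or three
compartments) plus a first-order effect compartment:

    dA1/dt = -(k10 + k12 + k13) A1 + k21 A2 + k31 A3 + boluses
    dA2/dt =  k12 A1 - k21 A2
    dA3/dt =  k13 A1 - k31 A3
    dCe/dt =  ke0 (A1/V1 - Ce)

with Cp = A1/V1.  Doses are in ug and V1 in litres, so concentrations come
out in ug/L = ng/mL.  Boluses are instantaneous jumps of the central
amount A1; between boluses the system is propagated *exactly* (eigenvalue
or matrix-exponential propagation), so the only discretization error in
downstream window means is quadrature error on the sampling grid.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import yaml

__all__ = [
    "PKModelParameters",
    "BolusEvent",
    "DosingRecord",
    "ConcentrationTrace",
    "ExposureSummary",
    "MMEConversionTable",
    "simulate_effect_site",
    "mean_window_concentration",
    "total_mme",
    "summarize_exposures",
    "load_pk_params",
    "load_mme_table",
    "read_dosing_csv",
    "default_pk_config_path",
]


@dataclass(frozen=True)
class PKModelParameters:
    """Rate constants (1/min) and central volume (L) for one drug.

    ``n_compartments`` is 2 or 3; a two-compartment drug must have
    ``k13 == k31 == 0``.  ``ke0`` couples plasma to the effect site.
    """

    drug: str
    V1: float
    k10: float
    k12: float
    k21: float
    k13: float
    k31: float
    ke0: float
    n_compartments: int = 3

    def __post_init__(self) -> None:
        if self.V1 <= 0:
            raise ValueError(f"V1 must be > 0, got {self.V1}")
        if self.ke0 <= 0:
            raise ValueError(f"ke0 must be > 0, got {self.ke0}")
        for name in ("k10", "k12", "k21", "k13", "k31"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_compartments not in (2, 3):
            raise ValueError("n_compartments must be 2 or 3")
        if self.n_compartments == 2 and (self.k13 != 0 or self.k31 != 0):
            raise ValueError("two-compartment model requires k13 = k31 = 0")

    def system_matrix(self) -> np.ndarray:
        """4x4 generator of the state [A1, A2, A3, Ce]."""
        return np.array(
            [
                [-(self.k10 + self.k12 + self.k13), self.k21, self.k31, 0.0],
                [self.k12, -self.k21, 0.0, 0.0],
                [self.k13, 0.0, -self.k31, 0.0],
                [self.ke0 / self.V1, 0.0, 0.0, -self.ke0],
            ]
        )


@dataclass(frozen=True)
class BolusEvent:
    time: float  # minutes from record origin
    dose: float  # ug
    drug: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"bolus time must be >= 0, got {self.time}")
        if self.dose < 0:
            raise ValueError(f"bolus dose must be >= 0, got {self.dose}")


@dataclass(frozen=True)
class DosingRecord:
    patient_id: str
    events: tuple[BolusEvent, ...]
    window_start: float
    window_end: float

    def __post_init__(self) -> None:
        if not self.window_start < self.window_end:
            raise ValueError("window_start must be < window_end")
        times = [e.time for e in self.events]
        if times != sorted(times):
            object.__setattr__(self, "events", tuple(sorted(self.events, key=lambda e: e.time)))

    def for_drug(self, drug: str) -> "DosingRecord":
        """Sub-record containing only this drug's boluses."""
        return DosingRecord(
            self.patient_id,
            tuple(e for e in self.events if e.drug == drug),
            self.window_start,
            self.window_end,
        )


@dataclass(frozen=True)
class ConcentrationTrace:
    times: np.ndarray
    Ce: np.ndarray
    Cp: np.ndarray
    drug: str


@dataclass(frozen=True)
class ExposureSummary:
    patient_id: str
    mean_Ce_fentanyl: float
    mean_Ce_hydromorphone: float


@dataclass(frozen=True)
class MMEConversionTable:
    """ug-administered -> morphine milligram equivalents, per drug."""

    factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"MME factor for {drug!r} must be > 0")


class _Propagator:
    """Exact propagation of x' = A x over arbitrary time offsets.

    Uses the eigendecomposition when A is safely diagonalizable (the generic
    case for a mammillary system); falls back to per-offset matrix
    exponentials for degenerate spectra (e.g. ke0 colliding with k10).
    """

    def __init__(self, A: np.ndarray) -> None:
        self.A = A
        lam, V = np.linalg.eig(A)
        scale = max(1.0, float(np.max(np.abs(lam))))
        diffs = np.abs(lam[:, None] - lam[None, :])
        np.fill_diagonal(diffs, np.inf)
        sep = float(diffs.min())
        self._diagonalizable = bool(sep > 1e-9 * scale) and np.isfinite(
            np.linalg.cond(V)
        ) and np.linalg.cond(V) < 1e10
        if self._diagonalizable:
            self._lam = lam
            self._V = V
            self._Vinv = np.linalg.inv(V)

    def propagate(self, x0: np.ndarray, offsets: np.ndarray) -> np.ndarray:
        """States at ``offsets`` minutes after a state ``x0``; shape (m, 4)."""
        if len(offsets) == 0:
            return np.empty((0, x0.size))
        if self._diagonalizable:
            c = self._Vinv @ x0.astype(complex)
            out = (np.exp(np.outer(offsets, self._lam)) * c) @ self._V.T
            return out.real
        return np.stack([scipy.linalg.expm(self.A * t) @ x0 for t in offsets])


def simulate_effect_site(
    record: DosingRecord, params: PKModelParameters, dt: float = 0.1
) -> ConcentrationTrace:
    """Simulate Cp and Ce on a uniform grid covering [0, window_end].

    Boluses are instantaneous increments of the central-compartment amount;
    between boluses the linear system is propagated exactly, so refining
    ``dt`` only refines the sampling of an already-exact trajectory.
    Concentrations are right-continuous at bolus times.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    for e in record.events:
        if e.drug != params.drug:
            raise ValueError(
                f"event drug {e.drug!r} does not match model drug {params.drug!r}"
            )
    n_steps = int(np.ceil(record.window_end / dt - 1e-9))
    times = np.arange(n_steps + 1) * dt

    dosed = [e for e in record.events if e.time <= times[-1]]
    if not dosed:
        zero = np.zeros_like(times)
        return ConcentrationTrace(times, zero, zero.copy(), params.drug)

    prop = _Propagator(params.system_matrix())
    # Aggregate simultaneous boluses, then propagate segment by segment.
    bolus_times: list[float] = []
    bolus_doses: list[float] = []
    for e in dosed:
        if bolus_times and e.time == bolus_times[-1]:
            bolus_doses[-1] += e.dose
        else:
            bolus_times.append(e.time)
            bolus_doses.append(e.dose)

    states = np.zeros((len(times), 4))
    x = np.zeros(4)
    seg_starts = list(bolus_times)
    seg_ends = bolus_times[1:] + [np.inf]
    for t0, t1, dose in zip(seg_starts, seg_ends, bolus_doses):
        x = x + np.array([dose, 0.0, 0.0, 0.0])
        # Grid points sampled from this segment: t0 <= t < t1 (right-continuous).
        mask = (times >= t0 - 1e-12) & (times < t1 - 1e-12)
        if mask.any():
            states[mask] = prop.propagate(x, times[mask] - t0)
        if np.isfinite(t1):
            x = prop.propagate(x, np.array([t1 - t0]))[0]

    Cp = np.maximum(states[:, 0] / params.V1, 0.0)
    Ce = np.maximum(states[:, 3], 0.0)
    return ConcentrationTrace(times, Ce, Cp, params.drug)


def mean_window_concentration(
    trace: ConcentrationTrace, window_start: float, window_end: float
) -> float:
    """Time-average of Ce over [window_start, window_end] (trapezoidal)."""
    if not window_start < window_end:
        raise ValueError("window_start must be < window_end")
    t = trace.times
    if window_start < t[0] - 1e-9 or window_end > t[-1] + 1e-9:
        raise ValueError(
            f"window [{window_start}, {window_end}] outside trace support "
            f"[{t[0]}, {t[-1]}]"
        )
    window_end = min(window_end, t[-1])
    window_start = max(window_start, t[0])
    inside = (t > window_start) & (t < window_end)
    tt = np.concatenate(([window_start], t[inside], [window_end]))
    cc = np.concatenate(
        (
            [np.interp(window_start, t, trace.Ce)],
            trace.Ce[inside],
            [np.interp(window_end, t, trace.Ce)],
        )
    )
    return float(np.trapezoid(cc, tt) / (window_end - window_start))


def total_mme(record: DosingRecord, table: MMEConversionTable) -> float:
    """Sum of dose x MME factor over boluses inside the record's window."""
    out = 0.0
    for e in record.events:
        if record.window_start <= e.time <= record.window_end:
            if e.drug not in table.factors:
                raise KeyError(f"no MME conversion factor for drug {e.drug!r}")
            out += e.dose * table.factors[e.drug]
    return out


def summarize_exposures(
    records: dict[str, DosingRecord],
    pk_params: dict[str, PKModelParameters],
    dt: float = 0.1,
    drugs: tuple[str, str] = ("fentanyl", "hydromorphone"),
) -> pd.DataFrame:
    """Window-mean effect-site concentration per patient and drug.

    A patient with no boluses of a drug before window_end gets exposure 0.
    The averaging window is the record's [window_start, window_end].
    """
    rows = []
    for pid, rec in records.items():
        row: dict[str, object] = {"patient_id": pid}
        for drug in drugs:
            sub = rec.for_drug(drug)
            if not any(e.time <= rec.window_end for e in sub.events):
                row[f"mean_Ce_{drug}"] = 0.0
                continue
            trace = simulate_effect_site(sub, pk_params[drug], dt=dt)
            row[f"mean_Ce_{drug}"] = mean_window_concentration(
                trace, rec.window_start, rec.window_end
            )
        rows.append(row)
    return pd.DataFrame(rows)


def default_pk_config_path():
    return importlib.resources.files("opioidcf.data") / "pk_defaults.yaml"


def load_pk_params(path=None) -> dict[str, PKModelParameters]:
    """Load per-drug PK parameter sets from a YAML config."""
    path = default_pk_config_path() if path is None else path
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        drug: PKModelParameters(drug=drug, **vals)
        for drug, vals in raw["pk_parameters"].items()
    }


def load_mme_table(path=None) -> MMEConversionTable:
    path = default_pk_config_path() if path is None else path
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return MMEConversionTable(factors={k: float(v) for k, v in raw["mme_per_ug"].items()})


def read_dosing_csv(dosing_path, windows_path) -> dict[str, DosingRecord]:
    """Assemble DosingRecords from a bolus table and a window table.

    ``dosing_path``: columns patient_id, drug, time_min, dose_ug.
    ``windows_path``: columns patient_id, window_start_min, window_end_min.
    Patients present only in the window table get empty records.
    """
    dosing = pd.read_csv(dosing_path)
    windows = pd.read_csv(windows_path)
    by_patient = dict(tuple(dosing.groupby("patient_id", sort=False))) if len(dosing) else {}
    records = {}
    for row in windows.itertuples(index=False):
        pid = str(row.patient_id)
        sub = by_patient.get(row.patient_id)
        events: tuple[BolusEvent, ...] = ()
        if sub is not None:
            events = tuple(
                BolusEvent(time=float(r.time_min), dose=float(r.dose_ug), drug=str(r.drug))
                for r in sub.itertuples(index=False)
            )
        records[pid] = DosingRecord(
            pid, events, float(row.window_start_min), float(row.window_end_min)
        )
    return records
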