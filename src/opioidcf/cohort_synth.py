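"""Synthetic perioperative cohorts with known ground truth.

Emulates the statistical structure of a large surgical EHR cohort:

* covariates of all four kinds (continuous age/BMI, binary sex/opioid
  naivety, ordinal ASA physical status, categorical surgical service);
* two semicontinuous intraoperative opioid exposures built through the
  PK module — each drug has a point mass at zero dose (logit model on
  confounders) and a log-normal positive total dose split into boluses,
  front-loaded in time for the fentanyl-like drug and homogeneous for the
  hydromorphone-like drug, yielding bimodal window-mean effect-site
  concentrations with a spike at 0 and near-independent drugs;
* outcomes from the ordinal (proportional odds), hurdle
  (logistic zero part + log-normal positive part), time-to-event
  (exponential, i.e. constant baseline hazard Cox) and binary (logistic)
  families, generated from the realized exposures and covariates with
  known coefficients.

Every exposure in the emitted cohort table is the PK module's own
window-mean recomputation from the emitted dosing record, so the
generator and the exposure-construction code cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from . import pkpd

__all__ = [
    "CovariateSpec",
    "ExposureModelSpec",
    "OutcomeSpec",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_covariates",
    "generate_dosing",
    "generate_outcomes",
    "generate_cohort",
    "default_config",
    "linear_score",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: its kind, confounder/adjustment role and distribution.

    ``params`` by kind —
    continuous: mean, sd, low, high (truncated normal);
    binary: p;
    ordinal: levels (ints), probs;
    categorical: levels (strings), probs.
    """

    name: str
    kind: str  # continuous | binary | ordinal | categorical
    role: str  # confounder | adjustment
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "ordinal", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.role not in ("confounder", "adjustment"):
            raise ValueError(f"unknown covariate role {self.role!r}")

    def population_mean(self) -> float:
        """Mean used to center this covariate in generator linear scores."""
        if self.kind == "continuous":
            return float(self.params["mean"])
        if self.kind == "binary":
            return float(self.params["p"])
        if self.kind == "ordinal":
            levels = np.asarray(self.params["levels"], dtype=float)
            probs = np.asarray(self.params["probs"], dtype=float)
            return float(levels @ (probs / probs.sum()))
        return 0.0  # categorical enters through per-level offsets


@dataclass(frozen=True)
class ExposureModelSpec:
    """Semicontinuous exposure model for one drug.

    P(no dose) = expit(zero_intercept + score(zero_coefs));
    total positive dose (ug) ~ LogNormal(pos_intercept + score(pos_coefs), tau);
    the total is split into 1..max_boluses equal boluses with times drawn
    from the window by ``timing`` ('front' = Beta(1,3) of the span,
    'uniform' = Uniform).
    """

    drug: str
    zero_intercept: float
    zero_coefs: dict = field(default_factory=dict)
    pos_intercept: float = 5.0  # log ug
    pos_coefs: dict = field(default_factory=dict)
    tau: float = 0.5
    timing: str = "uniform"
    min_boluses: int = 1
    max_boluses: int = 5

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.timing not in ("front", "uniform"):
            raise ValueError(f"unknown timing profile {self.timing!r}")
        if not 1 <= self.min_boluses <= self.max_boluses:
            raise ValueError("need 1 <= min_boluses <= max_boluses")


@dataclass(frozen=True)
class OutcomeSpec:
    """Ground-truth outcome model.

    family 'ordinal': latent logistic score eta cut at strictly increasing
      ``thresholds`` into integer categories (0..len(thresholds));
    family 'hurdle': zero with prob expit(zero part), else LogNormal(eta, sigma);
    family 'tte': exponential event time with rate h0*exp(eta), administrative
      censoring at ``censor_horizon``; emits columns name, name_event;
    family 'binary': Bernoulli(expit(eta)).

    ``beta_exposure`` maps drug -> coefficient per ng/mL of window-mean
    effect-site concentration; ``beta_cov`` maps covariate -> coefficient on
    the centered/standardized generator scale (see ``linear_score``).
    """

    name: str
    family: str
    intercept: float = 0.0
    beta_exposure: dict = field(default_factory=dict)
    beta_cov: dict = field(default_factory=dict)
    thresholds: tuple = ()
    zero_intercept: float = 0.0
    zero_beta_exposure: dict = field(default_factory=dict)
    zero_beta_cov: dict = field(default_factory=dict)
    sigma: float = 1.0
    h0: float = 0.01
    censor_horizon: float = np.inf

    def __post_init__(self) -> None:
        if self.family not in ("ordinal", "hurdle", "tte", "binary"):
            raise ValueError(f"unknown outcome family {self.family!r}")
        if self.family == "ordinal":
            th = np.asarray(self.thresholds, dtype=float)
            if th.size < 1 or np.any(np.diff(th) <= 0):
                raise ValueError("ordinal thresholds must be strictly increasing")
        if self.sigma <= 0 or self.h0 <= 0:
            raise ValueError("sigma and h0 must be > 0")


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int
    covariates: tuple[CovariateSpec, ...]
    exposures: tuple[ExposureModelSpec, ...]
    outcomes: tuple[OutcomeSpec, ...]
    window_log_median: float = np.log(90.0)  # minutes
    window_log_sd: float = 0.35
    window_min: float = 30.0
    window_max: float = 300.0
    pk_dt: float = 0.5  # minutes; generator sampling grid
    pk_config_path: str | None = None  # None -> packaged defaults
    pk_overrides: dict = field(default_factory=dict)  # drug -> PKModelParameters

    def covariate(self, name: str) -> CovariateSpec:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def roles(self) -> dict[str, dict[str, str]]:
        return {c.name: {"kind": c.kind, "role": c.role} for c in self.covariates}

    def confounders(self) -> list[str]:
        return [c.name for c in self.covariates if c.role == "confounder"]

    def pk_params(self) -> dict[str, pkpd.PKModelParameters]:
        params = pkpd.load_pk_params(self.pk_config_path)
        params.update(self.pk_overrides)
        return params


@dataclass(frozen=True)
class SyntheticCohort:
    cohort: pd.DataFrame  # patient_id + covariates + exposures + outcomes
    dosing: dict[str, pkpd.DosingRecord]
    config: GeneratorConfig


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def linear_score(covariates: pd.DataFrame, coefs: dict, config: GeneratorConfig) -> np.ndarray:
    """Linear predictor contribution of covariates, on the generator scale.

    Continuous covariates are standardized by their spec mean/sd, binary and
    ordinal covariates are centered at their spec mean, and categorical
    coefficients are per-level offsets (``{name: {level: offset}}``).
    Centering keeps intercepts interpretable as approximate marginal logits.
    """
    out = np.zeros(len(covariates))
    for name, coef in coefs.items():
        spec = config.covariate(name)
        col = covariates[name]
        if spec.kind == "categorical":
            if not isinstance(coef, dict):
                raise ValueError(f"categorical covariate {name!r} needs per-level offsets")
            out += col.map(coef).fillna(0.0).to_numpy(dtype=float)
        elif spec.kind == "continuous":
            sd = float(spec.params["sd"])
            out += coef * (col.to_numpy(dtype=float) - spec.params["mean"]) / sd
        else:
            out += coef * (col.to_numpy(dtype=float) - spec.population_mean())
    return out


def generate_covariates(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Draw the covariate table; reproducible given (config, seed)."""
    rng = _rng(seed, 0)
    n = config.n_patients
    data: dict[str, object] = {"patient_id": [f"P{i:06d}" for i in range(n)]}
    for spec in config.covariates:
        p = spec.params
        if spec.kind == "continuous":
            a = (p["low"] - p["mean"]) / p["sd"]
            b = (p["high"] - p["mean"]) / p["sd"]
            data[spec.name] = truncnorm.rvs(
                a, b, loc=p["mean"], scale=p["sd"], size=n, random_state=rng
            )
        elif spec.kind == "binary":
            data[spec.name] = (rng.random(n) < p["p"]).astype(int)
        elif spec.kind in ("ordinal", "categorical"):
            probs = np.asarray(p["probs"], dtype=float)
            data[spec.name] = rng.choice(p["levels"], size=n, p=probs / probs.sum())
        else:  # pragma: no cover - guarded by CovariateSpec
            raise ValueError(spec.kind)
    return pd.DataFrame(data)


def generate_dosing(
    covariates: pd.DataFrame, config: GeneratorConfig, seed: int
) -> dict[str, pkpd.DosingRecord]:
    """Draw per-patient windows and bolus schedules for every drug."""
    rng = _rng(seed, 1)
    n = len(covariates)
    spans = np.exp(rng.normal(config.window_log_median, config.window_log_sd, n))
    spans = np.clip(spans, config.window_min, config.window_max)

    per_drug = {}
    for em in config.exposures:
        p_zero = expit(em.zero_intercept + linear_score(covariates, em.zero_coefs, config))
        is_zero = rng.random(n) < p_zero
        totals = np.exp(
            em.pos_intercept
            + linear_score(covariates, em.pos_coefs, config)
            + em.tau * rng.normal(size=n)
        )
        totals[is_zero] = 0.0
        counts = rng.integers(em.min_boluses, em.max_boluses + 1, size=n)
        per_drug[em.drug] = (is_zero, totals, counts, em.timing)

    records: dict[str, pkpd.DosingRecord] = {}
    for i, pid in enumerate(covariates["patient_id"]):
        span = float(spans[i])
        events: list[pkpd.BolusEvent] = []
        for em in config.exposures:
            is_zero, totals, counts, timing = per_drug[em.drug]
            if is_zero[i]:
                continue
            k = int(counts[i])
            if timing == "front":
                times = span * rng.beta(1.0, 3.0, size=k)
            else:
                times = span * rng.random(k)
            for t in np.sort(times):
                events.append(pkpd.BolusEvent(float(t), float(totals[i] / k), em.drug))
        records[str(pid)] = pkpd.DosingRecord(
            str(pid), tuple(sorted(events, key=lambda e: e.time)), 0.0, span
        )
    return records


def generate_outcomes(
    covariates: pd.DataFrame,
    exposures: pd.DataFrame,
    config: GeneratorConfig,
    seed: int,
) -> pd.DataFrame:
    """Draw all configured outcomes given realized exposures and covariates."""
    rng = _rng(seed, 2)
    n = len(covariates)
    expo = exposures.set_index("patient_id").loc[covariates["patient_id"]]
    out = pd.DataFrame({"patient_id": covariates["patient_id"].to_numpy()})

    def eta(intercept, beta_exposure, beta_cov):
        s = intercept + linear_score(covariates, beta_cov, config)
        for drug, b in beta_exposure.items():
            s = s + b * expo[f"mean_Ce_{drug}"].to_numpy()
        return s

    for spec in config.outcomes:
        e = eta(spec.intercept, spec.beta_exposure, spec.beta_cov)
        if spec.family == "ordinal":
            th = np.asarray(spec.thresholds, dtype=float)
            u = rng.logistic(size=n)
            # latent = eta + logistic noise; category = #thresholds below latent
            out[spec.name] = np.searchsorted(th, e + u, side="right").astype(int)
        elif spec.family == "binary":
            out[spec.name] = (rng.random(n) < expit(e)).astype(int)
        elif spec.family == "hurdle":
            p0 = expit(
                spec.zero_intercept
                + eta(0.0, spec.zero_beta_exposure, spec.zero_beta_cov)
            )
            zero = rng.random(n) < p0
            y = np.exp(rng.normal(e, spec.sigma))
            y[zero] = 0.0
            out[spec.name] = y
        elif spec.family == "tte":
            t = rng.exponential(1.0, size=n) / (spec.h0 * np.exp(e))
            event = (t <= spec.censor_horizon).astype(int)
            out[spec.name] = np.minimum(t, spec.censor_horizon)
            out[f"{spec.name}_event"] = event
    return out


def generate_cohort(config: GeneratorConfig, seed: int) -> SyntheticCohort:
    """Full generation pass: covariates -> dosing -> PK exposures -> outcomes."""
    covariates = generate_covariates(config, seed)
    dosing = generate_dosing(covariates, config, seed)
    drugs = tuple(em.drug for em in config.exposures)
    exposures = pkpd.summarize_exposures(
        dosing, config.pk_params(), dt=config.pk_dt, drugs=drugs
    )
    outcomes = generate_outcomes(covariates, exposures, config, seed)
    cohort = covariates.merge(exposures, on="patient_id").merge(outcomes, on="patient_id")
    return SyntheticCohort(cohort=cohort, dosing=dosing, config=config)


def default_config(n_patients: int = 2000, **overrides) -> GeneratorConfig:
    """Study-condition defaults.

    Calibrated to the reported cohort structure: zero-exposure fractions of
    7.3% (fentanyl) and 36.4% (hydromorphone), near-independent exposures,
    front-loaded fentanyl vs homogeneous hydromorphone bolus timing, age
    55.4 (SD 17.1), 53.5% female, ASA distribution concentrated at II-III,
    and pain/opioid-use/length-of-stay/binary outcomes whose exposure
    coefficients are negative for the fentanyl-like drug on pain and
    opioid-use scales.
    """
    covariates = (
        CovariateSpec("age", "continuous", "confounder",
                      {"mean": 55.44, "sd": 17.08, "low": 18.0, "high": 95.0}),
        CovariateSpec("bmi", "continuous", "confounder",
                      {"mean": 27.9, "sd": 6.0, "low": 15.0, "high": 60.0}),
        CovariateSpec("female", "binary", "confounder", {"p": 0.535}),
        CovariateSpec("asa", "ordinal", "confounder",
                      {"levels": [1, 2, 3, 4], "probs": [0.1135, 0.588, 0.2842, 0.0144]}),
        CovariateSpec("opioid_naive", "binary", "adjustment", {"p": 0.807}),
        CovariateSpec(
            "service", "categorical", "adjustment",
            {"levels": ["orthopedic", "general", "urology", "gynecology", "plastic", "other"],
             "probs": [0.2291, 0.1721, 0.1403, 0.1009, 0.0803, 0.2773]},
        ),
    )
    exposures = (
        # Intercepts calibrated (once, numerically) so the marginal zero
        # fractions hit the 7.3% / 36.4% study conditions given the coefs.
        ExposureModelSpec(
            drug="fentanyl",
            zero_intercept=-2.614,
            zero_coefs={"age": 0.30, "asa": 0.40, "bmi": -0.20, "female": -0.10},
            pos_intercept=float(np.log(110.0)),
            pos_coefs={"age": -0.15, "bmi": 0.20, "asa": -0.10},
            tau=0.5,
            timing="front",
        ),
        ExposureModelSpec(
            drug="hydromorphone",
            zero_intercept=-0.615,
            zero_coefs={"age": 0.40, "asa": 0.50, "female": -0.20, "bmi": 0.30},
            pos_intercept=float(np.log(330.0)),
            pos_coefs={"age": 0.20, "bmi": -0.10, "female": 0.10},
            tau=0.55,
            timing="uniform",
        ),
    )
    outcomes = (
        OutcomeSpec(
            name="pain_pacu_max", family="ordinal",
            beta_exposure={"fentanyl": -0.8, "hydromorphone": -0.4},
            beta_cov={"age": -0.2, "asa": 0.3, "female": 0.1, "bmi": 0.1},
            thresholds=(-1.5, -1.1, -0.7, -0.3, 0.1, 0.5, 1.0, 1.5, 2.1, 2.8),
        ),
        OutcomeSpec(
            name="mme_pacu", family="hurdle",
            intercept=float(np.log(2.5)),
            beta_exposure={"fentanyl": -0.4, "hydromorphone": -0.3},
            beta_cov={"age": -0.15, "asa": 0.1},
            zero_intercept=-0.6,
            zero_beta_exposure={"fentanyl": 0.6, "hydromorphone": 0.3},
            zero_beta_cov={"age": 0.2},
            sigma=0.7,
        ),
        OutcomeSpec(
            name="los_pacu_min", family="tte",
            beta_exposure={"fentanyl": 0.3, "hydromorphone": -0.2},
            beta_cov={"age": -0.2, "asa": -0.15},
            h0=0.01, censor_horizon=600.0,
        ),
        OutcomeSpec(
            name="uncontrolled_pain_24h", family="binary",
            intercept=-2.4,
            beta_exposure={"fentanyl": -0.5, "hydromorphone": 0.2},
            beta_cov={"age": -0.1, "asa": 0.2},
        ),
    )
    base = dict(
        n_patients=n_patients,
        covariates=covariates,
        exposures=exposures,
        outcomes=outcomes,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def strong_confounding_config(n_patients: int = 5000) -> GeneratorConfig:
    """Preset with deliberately strong confounding for weighting diagnostics.

    Two binary confounders drive the zero-dose probability of the
    fentanyl-like drug hard enough that each confounder's unweighted
    correlation with that exposure exceeds 0.3. The confounding is placed
    in the zero part with bounded cell probabilities on purpose: that keeps
    the stabilized weights light-tailed, so the 99.5th-percentile trim
    removes a few rows from a homogeneous high-weight block instead of
    destroying the balancing mass. (With heavy positive-part confounding
    the largest weights are exactly the balance-critical observations and
    percentile trimming re-introduces the confounding it is meant to
    remove — a property worth remembering when reading balance tables.)
    """
    covariates = (
        CovariateSpec("sick", "binary", "confounder", {"p": 0.5}),
        CovariateSpec("major_surg", "binary", "confounder", {"p": 0.5}),
    )
    exposures = (
        ExposureModelSpec(
            drug="fentanyl", zero_intercept=0.0,
            zero_coefs={"sick": -2.0, "major_surg": -2.0},
            pos_intercept=float(np.log(110.0)), tau=0.25, timing="front",
            min_boluses=5, max_boluses=5,
        ),
        ExposureModelSpec(
            drug="hydromorphone", zero_intercept=-0.5,
            pos_intercept=float(np.log(300.0)), tau=0.25, timing="uniform",
            min_boluses=5, max_boluses=5,
        ),
    )
    return GeneratorConfig(
        n_patients=n_patients, covariates=covariates, exposures=exposures,
        outcomes=(), pk_dt=2.0, window_log_sd=0.05,
    )


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)
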