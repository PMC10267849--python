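"""Weighted outcome-model families on the reweighted cohort.

Four families mirror the postoperative outcome types:

* proportional-odds ordinal logistic regression for 0-10 pain scores,
  maximizing the weight-multiplied likelihood (own implementation with
  analytic gradients; statsmodels' OrderedModel has no observation
  weights and serves as the unweighted cross-check);
* hurdle (two-part) models for opioid-dose outcomes: weighted logistic
  regression on 1{Y > 0} plus weighted least squares of log Y on the
  positive part with a log-normal residual scale;
* weighted Cox proportional hazards (lifelines, Efron ties) for
  time-to-event outcomes, additionally storing a constant-baseline-hazard
  profile estimate h0 = sum(w d) / sum(w t exp(x'b)) used only for
  expected-event-time prediction;
* weighted logistic regression for binary outcomes.

Continuous design columns (exposures included) are standardized to mean 0,
SD 1 on the untrimmed weighted sample, so exponentiated exposure
coefficients are odds/hazard ratios per 1 SD of exposure; the
transformation metadata is stored so counterfactual copies of the data can
be pushed through the identical scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "DesignInfo",
    "DesignMatrix",
    "FittedOutcomeModel",
    "EffectEstimate",
    "build_design",
    "replay_design",
    "fit_ordinal",
    "fit_hurdle",
    "fit_cox",
    "fit_logistic",
    "effect_estimates",
    "predict_expectation",
]


@dataclass(frozen=True)
class DesignInfo:
    """Replayable transformation metadata for a design matrix."""

    exposure_cols: tuple[str, ...]
    columns: tuple[str, ...]  # final design columns, "const" first
    scaling: dict[str, tuple[float, float]]  # col -> (mean, sd)
    onehot: dict[str, tuple[str, ...]]  # covariate -> levels, [0] = reference


@dataclass(frozen=True)
class DesignMatrix:
    X: pd.DataFrame  # aligned to the rows it was built from
    info: DesignInfo


@dataclass(frozen=True)
class FittedOutcomeModel:
    family: str  # ordinal | hurdle | cox | logistic
    outcome: str
    info: DesignInfo
    coefs: dict[str, np.ndarray] = field(default_factory=dict)
    thresholds: np.ndarray | None = None  # ordinal cutpoints, increasing
    category_values: np.ndarray | None = None  # ordinal category labels
    sigma: float | None = None  # hurdle log-normal scale
    h0: float | None = None  # Cox constant-baseline-hazard estimate
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def coef_series(self, component: str = "mean") -> pd.Series:
        cols = self.info.columns
        b = self.coefs[component]
        if len(b) < len(cols):  # Cox: no intercept
            cols = tuple(c for c in cols if c != "const")
        return pd.Series(b, index=list(cols))


@dataclass(frozen=True)
class EffectEstimate:
    outcome: str
    exposure: str
    component: str  # "", "binomial", "log-normal"
    kind: str  # "odds ratio" | "hazard ratio"
    ratio: float  # exp(beta) per 1 SD of exposure
    ci_low: float = np.nan
    ci_high: float = np.nan


def _weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    m = float(np.average(x, weights=w))
    v = float(np.average((x - m) ** 2, weights=w))
    return m, float(np.sqrt(v))


def build_design(
    cohort: pd.DataFrame,
    weights: pd.DataFrame | None,
    adjustment_vars,
    roles: dict,
    exposure_cols=("mean_Ce_fentanyl", "mean_Ce_hydromorphone"),
    weighted_scaling: bool = True,
) -> DesignMatrix:
    """Standardized, one-hot-encoded design on the untrimmed rows.

    ``cohort`` must already be restricted to untrimmed patients (pass the
    weight frame so that the weighted moments used for scaling are the fit
    weights; ``weighted_scaling=False`` switches to unweighted moments).
    Exposures and continuous covariates are scaled to mean 0 / SD 1;
    binary and ordinal covariates pass through; categoricals are one-hot
    with the first (sorted) level dropped as reference.
    """
    if weights is not None:
        w = weights.set_index("patient_id").loc[cohort["patient_id"]]
        if w["trimmed"].any():
            raise ValueError("build_design expects untrimmed rows only")
        wvec = w["weight"].to_numpy() if weighted_scaling else np.ones(len(cohort))
    else:
        wvec = np.ones(len(cohort))

    scaling: dict[str, tuple[float, float]] = {}
    onehot: dict[str, tuple[str, ...]] = {}
    parts: list[pd.DataFrame] = []

    for name in list(exposure_cols) + list(adjustment_vars):
        if name in exposure_cols:
            kind = "continuous"
        else:
            meta = roles[name]
            kind = meta["kind"] if isinstance(meta, dict) else meta
        col = cohort[name]
        if kind == "continuous":
            x = col.to_numpy(dtype=float)
            m, s = _weighted_mean_sd(x, wvec)
            if s == 0:
                raise ValueError(f"zero-variance column {name!r} cannot be standardized")
            scaling[name] = (m, s)
            parts.append(pd.DataFrame({name: (x - m) / s}))
        elif kind == "categorical":
            levels = tuple(sorted(col.astype(str).unique()))
            onehot[name] = levels
            d = pd.DataFrame(
                {f"{name}={lv}": (col.astype(str) == lv).astype(float) for lv in levels[1:]}
            )
            parts.append(d)
        else:  # binary / ordinal pass through as numeric
            x = col.to_numpy(dtype=float)
            if np.ptp(x) == 0:
                raise ValueError(f"zero-variance column {name!r}")
            parts.append(pd.DataFrame({name: x}))

    X = pd.concat(parts, axis=1)
    X.insert(0, "const", 1.0)
    X.index = cohort.index
    info = DesignInfo(
        exposure_cols=tuple(exposure_cols),
        columns=tuple(X.columns),
        scaling=scaling,
        onehot=onehot,
    )
    return DesignMatrix(X=X, info=info)


def replay_design(cohort: pd.DataFrame, info: DesignInfo) -> pd.DataFrame:
    """Apply stored transformation metadata to (possibly counterfactual or
    trimmed) rows; bit-identical on the original data."""
    cols: dict[str, np.ndarray] = {"const": np.ones(len(cohort))}
    for name in info.columns:
        if name == "const":
            continue
        if "=" in name and name.split("=", 1)[0] in info.onehot:
            cov, lv = name.split("=", 1)
            cols[name] = (cohort[cov].astype(str) == lv).to_numpy(dtype=float)
        elif name in info.scaling:
            m, s = info.scaling[name]
            cols[name] = (cohort[name].to_numpy(dtype=float) - m) / s
        else:
            cols[name] = cohort[name].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=cohort.index)
    return X[list(info.columns)]


# ---------------------------------------------------------------------------
# logistic


def _check_separation(X: pd.DataFrame, params: np.ndarray, limit: float = 30.0) -> None:
    if np.any(np.abs(params) > limit) or not np.all(np.isfinite(params)):
        j = int(np.nanargmax(np.abs(params)))
        raise ValueError(
            f"apparent separation / non-identified logistic fit: column "
            f"{X.columns[j]!r} coefficient {params[j]:.3g}"
        )


def _weighted_logit(X: pd.DataFrame, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(
            y.astype(float), X.to_numpy(dtype=float),
            family=sm.families.Binomial(), var_weights=w,
        ).fit()
    params = np.asarray(fit.params, dtype=float)
    _check_separation(X, params)
    return params


def fit_logistic(
    design: DesignMatrix, outcome: np.ndarray, weights: np.ndarray
) -> FittedOutcomeModel:
    """Weighted maximum-likelihood logistic regression."""
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("logistic outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("binary outcome needs both classes present")
    params = _weighted_logit(design.X, y, np.asarray(weights, dtype=float))
    return FittedOutcomeModel(
        family="logistic", outcome="", info=design.info, coefs={"mean": params}
    )


# ---------------------------------------------------------------------------
# ordinal (proportional odds)


def _ordinal_nll_grad(theta, X, ycode, w, K):
    """Weighted negative log-likelihood and gradient of the proportional-odds
    model P(Y <= k | x) = expit(alpha_k - x'b), alpha parametrized as
    alpha_1 and positive log-increments for monotonicity."""
    p = X.shape[1]
    beta = theta[:p]
    alpha = np.concatenate(([theta[p]], theta[p] + np.cumsum(np.exp(theta[p + 1:]))))
    eta = X @ beta
    # cumulative logits at the two bracketing thresholds of each observation
    hi = np.where(ycode < K - 1, alpha[np.minimum(ycode, K - 2)] - eta, np.inf)
    lo = np.where(ycode > 0, alpha[np.maximum(ycode - 1, 0)] - eta, -np.inf)
    F_hi = expit(hi)
    F_lo = expit(lo)
    prob = np.maximum(F_hi - F_lo, 1e-300)
    nll = -np.sum(w * np.log(prob))

    f_hi = np.where(np.isfinite(hi), F_hi * (1 - F_hi), 0.0)
    f_lo = np.where(np.isfinite(lo), F_lo * (1 - F_lo), 0.0)
    # d nll / d eta and d nll / d alpha_k
    common = w / prob
    g_beta = X.T @ (common * (f_hi - f_lo))
    g_alpha = np.zeros(K - 1)
    np.add.at(g_alpha, np.minimum(ycode, K - 2), -common * f_hi * (ycode < K - 1))
    np.add.at(g_alpha, np.maximum(ycode - 1, 0), common * f_lo * (ycode > 0))
    # chain rule into (alpha_1, log-increments)
    g_a1 = g_alpha.sum()
    incr = np.exp(theta[p + 1:])
    g_incr = incr * np.array([g_alpha[j + 1:].sum() for j in range(K - 2)])
    return nll, np.concatenate((g_beta, [g_a1], g_incr))


def fit_ordinal(
    design: DesignMatrix, outcome: np.ndarray, weights: np.ndarray
) -> FittedOutcomeModel:
    """Weighted proportional-odds ordinal regression.

    Categories are the observed outcome values; unobserved interior
    categories are merged into their neighbours (with a warning), keeping
    the likelihood well-defined on small cohorts.
    """
    y = np.asarray(outcome)
    w = np.asarray(weights, dtype=float)
    values = np.unique(y)
    if len(values) < 2:
        raise ValueError("ordinal outcome needs >= 2 observed categories")
    full_range = np.arange(y.min(), y.max() + 1)
    if len(values) < len(full_range):
        warnings.warn(
            f"merging {len(full_range) - len(values)} empty ordinal categories",
            stacklevel=2,
        )
    ycode = np.searchsorted(values, y)
    K = len(values)
    Xc = design.X.drop(columns="const")  # intercept absorbed by thresholds
    Xa = Xc.to_numpy(dtype=float)

    # start: null thresholds from weighted cumulative fractions
    cum = np.cumsum(np.bincount(ycode, weights=w))[:-1] / w.sum()
    cum = np.clip(cum, 1e-4, 1 - 1e-4)
    alpha0 = np.log(cum / (1 - cum))
    incr0 = np.log(np.maximum(np.diff(alpha0), 1e-3))
    theta0 = np.concatenate((np.zeros(Xa.shape[1]), [alpha0[0]], incr0))

    res = minimize(
        _ordinal_nll_grad, theta0, args=(Xa, ycode, w, K),
        jac=True, method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    gnorm = float(np.max(np.abs(res.jac)))
    if gnorm > 1e-3 * max(1.0, w.sum() / len(w)):
        raise RuntimeError(
            f"ordinal fit did not converge: max |gradient| = {gnorm:.3g}"
        )
    p = Xa.shape[1]
    beta = res.x[:p]
    alpha = np.concatenate(([res.x[p]], res.x[p] + np.cumsum(np.exp(res.x[p + 1:]))))
    params = np.concatenate(([0.0], beta))  # align with design columns (const -> 0)
    # observed-information SEs for beta via finite differences of the gradient
    eps = 1e-5
    H = np.empty((len(res.x), len(res.x)))
    for j in range(len(res.x)):
        step = np.zeros(len(res.x))
        step[j] = eps
        gp = _ordinal_nll_grad(res.x + step, Xa, ycode, w, K)[1]
        gm = _ordinal_nll_grad(res.x - step, Xa, ycode, w, K)[1]
        H[:, j] = (gp - gm) / (2 * eps)
    try:
        beta_se = np.sqrt(np.diag(np.linalg.inv((H + H.T) / 2))[:p])
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate designs
        beta_se = np.full(p, np.nan)
    return FittedOutcomeModel(
        family="ordinal", outcome="", info=design.info,
        coefs={"mean": params}, thresholds=alpha,
        category_values=values.astype(float), converged=res.success or gnorm <= 1e-3,
        diagnostics={
            "grad_norm": gnorm,
            "nll": float(res.fun),
            "beta_se": pd.Series(beta_se, index=list(Xc.columns)),
        },
    )


# ---------------------------------------------------------------------------
# hurdle


def fit_hurdle(
    design: DesignMatrix, outcome: np.ndarray, weights: np.ndarray
) -> FittedOutcomeModel:
    """Two-part model: weighted logistic on 1{Y > 0} ('binomial' component)
    and weighted least squares of log Y on the positive part ('log-normal'
    component) with scale sigma from the weighted residual variance."""
    y = np.asarray(outcome, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.min() < 0:
        raise ValueError("hurdle outcome must be nonnegative")
    pos = y > 0
    if pos.all() or not pos.any():
        raise ValueError("degenerate hurdle: outcome needs both zeros and positives")
    zero_params = _weighted_logit(design.X, pos.astype(float), w)
    Xp = design.X.to_numpy(dtype=float)[pos]
    wls = sm.WLS(np.log(y[pos]), Xp, weights=w[pos]).fit()
    resid = np.log(y[pos]) - Xp @ wls.params
    sigma = float(np.sqrt(np.average(resid**2, weights=w[pos])))
    return FittedOutcomeModel(
        family="hurdle", outcome="", info=design.info,
        coefs={"binomial": zero_params, "log-normal": np.asarray(wls.params, dtype=float)},
        sigma=sigma,
    )


# ---------------------------------------------------------------------------
# Cox


def _breslow_newton(X, t, d, w, max_iter=50, tol=1e-10):
    """Weighted Cox partial likelihood with Breslow tie handling.

    Risk sums are cumulative over descending time, with tied times sharing
    the full risk set; Newton steps on the analytic gradient/Hessian.
    """
    order = np.argsort(-t, kind="stable")
    Xs, ts, ds, ws = X[order], t[order], d[order], w[order]
    # block boundaries so that tied times share risk sums
    _, inv = np.unique(-ts, return_inverse=True)
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(max_iter):
        r = ws * np.exp(Xs @ beta)
        S0 = np.cumsum(r)
        S1 = np.cumsum(r[:, None] * Xs, axis=0)
        S2 = np.cumsum(r[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
        # index of last row in each tie block
        last = np.searchsorted(inv, inv, side="right") - 1
        S0b, S1b, S2b = S0[last], S1[last], S2[last]
        ev = ds > 0
        wd = ws[ev]
        grad = (wd[:, None] * (Xs[ev] - S1b[ev] / S0b[ev, None])).sum(axis=0)
        xbar = S1b[ev] / S0b[ev, None]
        hess = -(
            wd[:, None, None]
            * (S2b[ev] / S0b[ev, None, None] - xbar[:, :, None] * xbar[:, None, :])
        ).sum(axis=0)
        step = np.linalg.solve(hess, -grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def fit_cox(
    design: DesignMatrix,
    time: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray,
    ties: str = "efron",
) -> FittedOutcomeModel:
    """Weighted Cox partial likelihood plus the constant-baseline-hazard
    profile estimate used for expected-time prediction:
    h0 = sum(w * d) / sum(w * t * exp(x'b)).

    Ties are handled by Efron's method (lifelines) by default. Breslow
    (statsmodels PHReg) is available as an option; note that splitting an
    observation into duplicates with shared-out weights is exactly
    fit-invariant under Breslow but only approximately under Efron, because
    the duplicates form a tie that Efron's correction treats differently.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(t <= 0):
        raise ValueError("event times must be > 0")
    if d.sum() == 0:
        raise ValueError("Cox fit needs at least one event")
    df = design.X.drop(columns="const").copy()
    covs = list(df.columns)
    if ties == "efron":
        df["_T"], df["_E"], df["_w"] = t, d, w
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df, duration_col="_T", event_col="_E", weights_col="_w",
                robust=False, fit_options={"precision": 1e-12},
            )
        beta = cph.params_.loc[covs].to_numpy(dtype=float)
    elif ties == "breslow":
        beta = _breslow_newton(df.to_numpy(dtype=float), t, d, w)
    else:
        raise ValueError(f"unknown tie method {ties!r}")
    risk = np.exp(design.X.drop(columns="const").to_numpy(dtype=float) @ beta)
    h0 = float((w * d).sum() / (w * t * risk).sum())
    return FittedOutcomeModel(
        family="cox", outcome="", info=design.info, coefs={"mean": beta}, h0=h0
    )


# ---------------------------------------------------------------------------
# effect estimates & prediction


def effect_estimates(model: FittedOutcomeModel) -> list[EffectEstimate]:
    """Exponentiated exposure coefficients (per 1 SD of exposure).

    Hurdle models yield two estimates per exposure (binomial and log-normal
    components); Cox models are labeled hazard ratios, where a ratio above 1
    means a higher event rate and hence a *shorter* expected event time.
    Confidence intervals are attached by the counterfactual bootstrap.
    """
    if not model.converged:
        raise ValueError("effect estimates require a converged model")
    out = []
    components = (
        [("binomial", "odds ratio"), ("log-normal", "odds ratio")]
        if model.family == "hurdle"
        else [("mean", "hazard ratio" if model.family == "cox" else "odds ratio")]
    )
    for comp, kind in components:
        s = model.coef_series(comp)
        for expo in model.info.exposure_cols:
            out.append(
                EffectEstimate(
                    outcome=model.outcome,
                    exposure=expo,
                    component=comp if model.family == "hurdle" else "",
                    kind=kind,
                    ratio=float(np.exp(s[expo])),
                )
            )
    return out


def predict_expectation(model: FittedOutcomeModel, X: pd.DataFrame) -> np.ndarray:
    """Per-row expected outcome under the fitted model.

    ordinal: sum_k value_k P(Y = value_k); hurdle: P(Y>0) exp(mu + sigma^2/2);
    logistic: event probability; cox: expected event time 1/(h0 exp(x'b))
    under the constant-baseline-hazard assumption.
    """
    arr = X.to_numpy(dtype=float)
    if model.family == "logistic":
        return expit(arr @ model.coefs["mean"])
    if model.family == "ordinal":
        eta = arr @ model.coefs["mean"]  # const coefficient is 0
        cum = expit(model.thresholds[None, :] - eta[:, None])
        probs = np.diff(np.concatenate(
            (np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))), axis=1), axis=1)
        return probs @ model.category_values
    if model.family == "hurdle":
        p_pos = expit(arr @ model.coefs["binomial"])
        mu = arr @ model.coefs["log-normal"]
        return p_pos * np.exp(mu + model.sigma**2 / 2)
    if model.family == "cox":
        nc = [c for c in X.columns if c != "const"]
        eta = X[nc].to_numpy(dtype=float) @ model.coefs["mean"]
        return 1.0 / (model.h0 * np.exp(eta))
    raise ValueError(f"unknown family {model.family!r}")


def ordinal_category_probs(model: FittedOutcomeModel, X: pd.DataFrame) -> np.ndarray:
    """Predicted category probability matrix (rows sum to 1)."""
    arr = X.to_numpy(dtype=float)
    eta = arr @ model.coefs["mean"]
    cum = expit(model.thresholds[None, :] - eta[:, None])
    return np.diff(np.concatenate(
        (np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))), axis=1), axis=1)
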