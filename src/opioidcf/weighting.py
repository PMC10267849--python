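"""Generalized propensity scores and stabilized weights for two
semicontinuous exposures, with balance diagnostics.

Each exposure (window-mean effect-site concentration per drug) has a point
mass at zero and a continuous positive part, so its conditional density
given confounders is modeled as a two-part (zero-inflated log-normal)
density: a logistic regression for P(exposure = 0 | confounders) and an
ordinary least-squares model for log(exposure) on the positive part with a
normal residual. The stabilized weight is the ratio of the marginal
(intercept-only) likelihood of the observed exposure to its conditional
likelihood; with two near-independent exposures the combined weight is the
product of the per-drug weights. Raw weights strictly above the empirical
99.5th percentile (configurable) are flagged trimmed and excluded from all
weighted computations downstream.

Balance is reported as the correlation of each covariate with each exposure
before and after weighting — Pearson for continuous and binary covariates
(categorical covariates level by level as 0/1 indicators), Kendall tau-b
for ordinal covariates, both in weighted forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "TwoPartModel",
    "PropensityModel",
    "fit_propensity",
    "compute_weights",
    "balance_diagnostics",
    "weighted_pearson",
    "weighted_kendall_tau",
    "confounder_design",
    "complete_cases",
]

DEFAULT_EXPOSURES = ("mean_Ce_fentanyl", "mean_Ce_hydromorphone")


@dataclass(frozen=True)
class TwoPartModel:
    """Two-part exposure density for one drug.

    Conditional part: ``zero_coefs`` (logit of P(E = 0) on the confounder
    design incl. intercept) and ``pos_coefs``/``pos_sd`` (normal model of
    log E on the positive subset). Marginal part: intercept-only analogues.
    """

    exposure: str
    columns: tuple[str, ...]
    zero_coefs: np.ndarray
    pos_coefs: np.ndarray
    pos_sd: float
    marginal_p_zero: float
    marginal_pos_mean: float
    marginal_pos_sd: float

    def log_density(self, X: np.ndarray, e: np.ndarray) -> np.ndarray:
        """log f(e | x) under the conditional two-part density.

        For positive exposures the density of log E is used; the 1/e
        Jacobian is omitted identically in the marginal and conditional
        likelihoods, so it cancels from every stabilized weight.
        """
        p0 = expit(X @ self.zero_coefs)
        out = np.empty(len(e))
        zero = e == 0
        with np.errstate(divide="ignore"):  # -inf is caught by the caller
            out[zero] = np.log(p0[zero])
        mu = X[~zero] @ self.pos_coefs
        out[~zero] = np.log1p(-p0[~zero]) + norm.logpdf(
            np.log(e[~zero]), mu, self.pos_sd
        )
        return out

    def log_marginal_density(self, e: np.ndarray) -> np.ndarray:
        out = np.empty(len(e))
        zero = e == 0
        out[zero] = np.log(self.marginal_p_zero)
        out[~zero] = np.log1p(-self.marginal_p_zero) + norm.logpdf(
            np.log(e[~zero]), self.marginal_pos_mean, self.marginal_pos_sd
        )
        return out


@dataclass(frozen=True)
class PropensityModel:
    confounders: tuple[str, ...]
    columns: tuple[str, ...]  # design columns incl. "const"
    models: dict[str, TwoPartModel]  # keyed by exposure column


def complete_cases(cohort: pd.DataFrame, columns=None) -> tuple[pd.DataFrame, int]:
    """Drop rows with missing analysis fields; return (kept, n_dropped)."""
    sub = cohort if columns is None else cohort[list(columns)]
    keep = ~sub.isna().any(axis=1)
    return cohort.loc[keep].reset_index(drop=True), int((~keep).sum())


def confounder_design(
    cohort: pd.DataFrame, confounders, add_const: bool = True
) -> pd.DataFrame:
    """Numeric design for the confounders: categoricals one-hot (reference
    level dropped), everything else passed through as numeric."""
    parts = []
    for name in confounders:
        col = cohort[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            parts.append(d)
        else:
            parts.append(col.astype(float).to_frame(name))
    X = pd.concat(parts, axis=1)
    if add_const:
        X.insert(0, "const", 1.0)
    _check_full_rank(X)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        for j, name in enumerate(X.columns):
            keep = [k for k in range(arr.shape[1]) if k != j]
            if np.linalg.matrix_rank(arr[:, keep]) == rank:
                bad.append(name)
        raise ValueError(f"singular confounder design; collinear columns: {bad}")


def _fit_two_part(X: pd.DataFrame, e: np.ndarray, exposure: str) -> TwoPartModel:
    zero = e == 0
    if zero.all() or (~zero).all():
        raise ValueError(
            f"two-part model undefined for {exposure!r}: needs both zero and "
            f"positive exposures (got {int(zero.sum())} zeros of {len(e)})"
        )
    arr = X.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        zero_fit = sm.GLM(zero.astype(float), arr, family=sm.families.Binomial()).fit()
    pos = ~zero
    loge = np.log(e[pos])
    ols = sm.OLS(loge, arr[pos]).fit()
    pos_sd = float(np.sqrt(ols.mse_resid))
    return TwoPartModel(
        exposure=exposure,
        columns=tuple(X.columns),
        zero_coefs=np.asarray(zero_fit.params, dtype=float),
        pos_coefs=np.asarray(ols.params, dtype=float),
        pos_sd=pos_sd,
        marginal_p_zero=float(zero.mean()),
        marginal_pos_mean=float(loge.mean()),
        marginal_pos_sd=float(loge.std(ddof=1)),
    )


def fit_propensity(
    cohort: pd.DataFrame,
    confounders,
    exposure_cols=DEFAULT_EXPOSURES,
) -> PropensityModel:
    """Fit the two-part generalized propensity model for each exposure."""
    confounders = tuple(confounders)
    if len(confounders) < 2:
        raise ValueError("need at least 2 confounders")
    for c in exposure_cols:
        if c not in cohort.columns:
            raise ValueError(f"exposure column {c!r} missing from cohort")
    X = confounder_design(cohort, confounders)
    models = {
        c: _fit_two_part(X, cohort[c].to_numpy(dtype=float), c) for c in exposure_cols
    }
    return PropensityModel(confounders, tuple(X.columns), models)


def compute_weights(
    model: PropensityModel,
    cohort: pd.DataFrame,
    trim_percentile: float = 99.5,
) -> pd.DataFrame:
    """Stabilized weights with strict-above-percentile trimming.

    Returns a frame with patient_id, raw_weight, weight, trimmed. The
    combined raw weight is the product over exposures of
    marginal/conditional likelihood ratios; rows with raw weight strictly
    above the empirical ``trim_percentile`` of raw weights are flagged
    trimmed and must be excluded from all weighted fits (they keep their
    weight value for transparency).
    """
    if not 50 < trim_percentile < 100:
        raise ValueError("trim_percentile must be in (50, 100)")
    X = confounder_design(cohort, model.confounders)
    if tuple(X.columns) != model.columns:
        raise ValueError("cohort design columns do not match fitted model")
    arr = X.to_numpy(dtype=float)
    logw = np.zeros(len(cohort))
    for exposure, tp in model.models.items():
        e = cohort[exposure].to_numpy(dtype=float)
        log_cond = tp.log_density(arr, e)
        if not np.all(np.isfinite(log_cond)):
            bad = cohort["patient_id"].to_numpy()[~np.isfinite(log_cond)]
            raise FloatingPointError(
                f"conditional exposure density underflow for patients {bad[:5]}"
            )
        logw += tp.log_marginal_density(e) - log_cond
    raw = np.exp(logw)
    threshold = float(np.percentile(raw, trim_percentile))
    trimmed = raw > threshold
    return pd.DataFrame(
        {
            "patient_id": cohort["patient_id"].to_numpy(),
            "raw_weight": raw,
            "weight": raw,
            "trimmed": trimmed,
        }
    )


def weighted_pearson(x, y, w) -> float:
    """Pearson correlation with observation weights (unit weights reduce it
    to the ordinary Pearson estimate)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx == 0 or vy == 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


def weighted_kendall_tau(x, y, w, block: int = 512) -> float:
    """Weighted Kendall tau-b with pair weights w_i * w_j.

    tau_b = sum_{i<j} w_i w_j sgn(x_i - x_j) sgn(y_i - y_j)
            / sqrt((S - T_x)(S - T_y)),
    with S the total pair weight and T the tied-pair weight in each
    variable. Equal weights recover the classical tau-b.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n = len(x)
    num = S = Tx = Ty = 0.0
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        xi = x[i0:i1, None]
        yi = y[i0:i1, None]
        wi = w[i0:i1, None]
        # pairs (i, j) with j > i, block-row i
        dx = np.sign(x[None, :] - xi)
        dy = np.sign(y[None, :] - yi)
        ww = wi * w[None, :]
        mask = np.arange(n)[None, :] > np.arange(i0, i1)[:, None]
        ww = ww * mask
        num += float((ww * dx * dy).sum())
        S += float(ww.sum())
        Tx += float((ww * (dx == 0)).sum())
        Ty += float((ww * (dy == 0)).sum())
    denom = np.sqrt((S - Tx) * (S - Ty))
    if denom == 0:
        return np.nan
    return float(num / denom)


def balance_diagnostics(
    cohort: pd.DataFrame,
    weights: pd.DataFrame,
    roles: dict,
    exposure_cols=DEFAULT_EXPOSURES,
) -> pd.DataFrame:
    """Covariate-exposure correlations before and after weighting.

    ``roles`` maps covariate name -> {"kind": ..., "role": ...}. Continuous
    and binary covariates use (weighted) Pearson; ordinal covariates use
    (weighted) Kendall tau-b; categorical covariates are expanded level by
    level into 0/1 indicators (all levels reported) and use Pearson.
    Unweighted columns use the full cohort; weighted columns use untrimmed
    rows and their stabilized weights. Zero-variance covariates are
    reported as correlation 0 with ``degenerate=True``.
    """
    w = weights.set_index("patient_id").loc[cohort["patient_id"]]
    keep = ~w["trimmed"].to_numpy()
    wk = w["weight"].to_numpy()[keep]

    items: list[tuple[str, str, np.ndarray]] = []  # (label, kind, values)
    for name, meta in roles.items():
        kind = meta["kind"] if isinstance(meta, dict) else meta
        if kind == "categorical":
            for level in sorted(cohort[name].astype(str).unique()):
                items.append(
                    (f"{name}={level}", "binary",
                     (cohort[name].astype(str) == level).to_numpy(dtype=float))
                )
        else:
            items.append((name, kind, cohort[name].to_numpy(dtype=float)))

    rows = []
    for label, kind, x in items:
        degenerate = np.ptp(x) == 0
        row: dict[str, object] = {"covariate": label, "kind": kind, "degenerate": degenerate}
        for expo in exposure_cols:
            e = cohort[expo].to_numpy(dtype=float)
            if degenerate:
                row[f"unweighted_{expo}"] = 0.0
                row[f"weighted_{expo}"] = 0.0
                continue
            if kind == "ordinal":
                row[f"unweighted_{expo}"] = weighted_kendall_tau(x, e, np.ones(len(x)))
                row[f"weighted_{expo}"] = weighted_kendall_tau(x[keep], e[keep], wk)
            else:
                row[f"unweighted_{expo}"] = weighted_pearson(x, e, np.ones(len(x)))
                row[f"weighted_{expo}"] = weighted_pearson(x[keep], e[keep], wk)
        rows.append(row)
    return pd.DataFrame(rows)
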