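"""Design construction and the four weighted outcome-model families."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.miscmodels.ordinal_model import OrderedModel

from opioidcf import outcome_models as om
from opioidcf import weighting as wt


def _design_from_frame(df, exposure_cols=()):
    """Wrap a plain numeric frame (no transformation) as a DesignMatrix."""
    X = df.copy()
    X.insert(0, "const", 1.0)
    info = om.DesignInfo(tuple(exposure_cols), tuple(X.columns), {}, {})
    return om.DesignMatrix(X=X, info=info)


@pytest.fixture(scope="module")
def fitted_inputs(large_cohort):
    """Weights, untrimmed cohort and design for the 20k recovery cohort."""
    syn = large_cohort
    m = wt.fit_propensity(syn.cohort, syn.config.confounders())
    w = wt.compute_weights(m, syn.cohort)
    keep = ~w["trimmed"].to_numpy()
    sub = syn.cohort.loc[keep].reset_index(drop=True)
    wsub = w.loc[keep].reset_index(drop=True)
    adj = [c.name for c in syn.config.covariates]
    design = om.build_design(sub, wsub, adj, syn.config.roles())
    return syn, sub, wsub, design


class TestBuildDesign:
    def test_standardized_column_unchanged(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=2000)
        z = (z - z.mean()) / z.std()
        df = pd.DataFrame({"patient_id": np.arange(2000).astype(str),
                           "mean_Ce_fentanyl": z})
        dm = om.build_design(df, None, [], {}, exposure_cols=("mean_Ce_fentanyl",),
                             weighted_scaling=False)
        m, s = dm.info.scaling["mean_Ce_fentanyl"]
        assert m == pytest.approx(0.0, abs=1e-12) and s == pytest.approx(1.0)
        np.testing.assert_allclose(dm.X["mean_Ce_fentanyl"], z, atol=1e-12)

    def test_three_level_categorical_gives_two_indicators(self):
        df = pd.DataFrame({"patient_id": list("abcdef"),
                           "svc": ["x", "y", "z", "x", "y", "z"]})
        dm = om.build_design(df, None, ["svc"], {"svc": {"kind": "categorical"}},
                             exposure_cols=())
        ind = [c for c in dm.X.columns if c.startswith("svc=")]
        assert len(ind) == 2  # reference level dropped
        assert dm.info.onehot["svc"] == ("x", "y", "z")

    def test_replay_is_bit_identical(self, fitted_inputs):
        _, sub, _, design = fitted_inputs
        replayed = om.replay_design(sub, design.info)
        assert (replayed.to_numpy() == design.X.to_numpy()).all()

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"patient_id": ["a", "b"], "flat": [2.0, 2.0]})
        with pytest.raises(ValueError, match="flat"):
            om.build_design(df, None, ["flat"], {"flat": {"kind": "continuous"}},
                            exposure_cols=())


class TestLogistic:
    def test_intercept_only_equals_logit_of_weighted_rate(self):
        rng = np.random.default_rng(1)
        y = rng.binomial(1, 0.3, 500).astype(float)
        w = rng.uniform(0.2, 3.0, 500)
        dm = _design_from_frame(pd.DataFrame(index=range(500)))
        model = om.fit_logistic(dm, y, w)
        rate = np.average(y, weights=w)
        assert model.coefs["mean"][0] == pytest.approx(logit(rate), abs=1e-8)

    def test_two_by_two_table_log_odds_ratio(self):
        # x=0: 10 events / 40 non-events; x=1: 30 / 20
        x = np.r_[np.zeros(50), np.ones(50)]
        y = np.r_[np.ones(10), np.zeros(40), np.ones(30), np.zeros(20)]
        dm = _design_from_frame(pd.DataFrame({"x": x}))
        model = om.fit_logistic(dm, y, np.ones(100))
        lor = np.log((30 / 20) / (10 / 40))
        assert model.coef_series()["x"] == pytest.approx(lor, abs=1e-7)

    def test_unit_weights_match_reference_logit(self, logistic_fixture_200):
        df = logistic_fixture_200
        dm = _design_from_frame(df[["x1", "x2"]])
        model = om.fit_logistic(dm, df["y"].to_numpy(), np.ones(len(df)))
        ref = sm.Logit(df["y"], sm.add_constant(df[["x1", "x2"]])).fit(disp=0)
        np.testing.assert_allclose(model.coefs["mean"], ref.params.to_numpy(),
                                   atol=1e-6)

    def test_generator_truth_recovery(self, fitted_inputs):
        syn, sub, wsub, design = fitted_inputs
        spec = next(o for o in syn.config.outcomes if o.family == "binary")
        model = om.fit_logistic(design, sub[spec.name].to_numpy(),
                                wsub["weight"].to_numpy())
        ref = sm.GLM(sub[spec.name].to_numpy(), design.X.to_numpy(),
                     family=sm.families.Binomial(),
                     var_weights=wsub["weight"].to_numpy()).fit()
        for drug, beta in spec.beta_exposure.items():
            col = f"mean_Ce_{drug}"
            j = list(design.X.columns).index(col)
            sd = design.info.scaling[col][1]
            assert abs(model.coef_series()[col] - beta * sd) < 3 * ref.bse[j]

    def test_separation_rejected_with_column(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        dm = _design_from_frame(pd.DataFrame({"sep_col": x}))
        with pytest.raises(ValueError, match="sep_col"):
            om.fit_logistic(dm, x.copy(), np.ones(40))


class TestOrdinal:
    def _sim(self, n=400, seed=5, K=4):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"x1": rng.normal(size=n),
                          "x2": rng.binomial(1, 0.5, n).astype(float)})
        eta = 0.8 * X.x1 - 0.5 * X.x2
        th = np.linspace(-1.0, 1.0, K - 1)
        y = np.searchsorted(th, eta + rng.logistic(size=n), side="right")
        return X, y

    def test_matches_statsmodels_unweighted(self):
        X, y = self._sim(n=200)
        dm = _design_from_frame(X)
        mine = om.fit_ordinal(dm, y, np.ones(len(y)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = OrderedModel(y, X, distr="logit").fit(
                method="bfgs", disp=0, gtol=1e-10)
        np.testing.assert_allclose(
            mine.coef_series()[["x1", "x2"]].to_numpy(),
            ref.params.iloc[:2].to_numpy(), atol=1e-6,
        )
        th_ref = np.concatenate(
            ([ref.params.iloc[2]],
             ref.params.iloc[2] + np.cumsum(np.exp(ref.params.iloc[3:])))
        )
        np.testing.assert_allclose(mine.thresholds, th_ref, atol=1e-6)

    def test_two_categories_collapse_to_logistic(self):
        X, y = self._sim(n=300, K=2)
        dm = _design_from_frame(X)
        w = np.random.default_rng(0).uniform(0.5, 2.0, len(y))
        mine = om.fit_ordinal(dm, y, w)
        logi = om.fit_logistic(dm, (y > 0).astype(float), w)
        np.testing.assert_allclose(
            mine.coef_series()[["x1", "x2"]].to_numpy(),
            logi.coef_series()[["x1", "x2"]].to_numpy(), atol=1e-6,
        )
        # P(Y=1) = expit(eta - alpha_1) so alpha_1 = -intercept
        assert mine.thresholds[0] == pytest.approx(-logi.coefs["mean"][0], abs=1e-6)

    def test_generator_truth_recovery(self, fitted_inputs):
        syn, sub, wsub, design = fitted_inputs
        spec = next(o for o in syn.config.outcomes if o.family == "ordinal")
        model = om.fit_ordinal(design, sub[spec.name].to_numpy(),
                               wsub["weight"].to_numpy())
        se = model.diagnostics["beta_se"]
        for drug, beta in spec.beta_exposure.items():
            col = f"mean_Ce_{drug}"
            sd = design.info.scaling[col][1]
            assert abs(model.coef_series()[col] - beta * sd) < 3 * se[col]

    def test_empty_interior_category_merged_with_warning(self):
        X, y = self._sim(n=300, K=4)
        y = np.where(y == 2, 3, y) * 2  # values {0, 2, 6}: gaps in 0..6
        dm = _design_from_frame(X)
        with pytest.warns(UserWarning, match="merging"):
            model = om.fit_ordinal(dm, y, np.ones(len(y)))
        assert list(model.category_values) == [0.0, 2.0, 6.0]
        assert len(model.thresholds) == 2

    def test_all_zero_design_column_keeps_reduced_fit(self):
        X, y = self._sim(n=300)
        Xz = X.assign(dead=0.0)
        full = om.fit_ordinal(_design_from_frame(Xz), y, np.ones(len(y)))
        red = om.fit_ordinal(_design_from_frame(X), y, np.ones(len(y)))
        assert full.coef_series()["dead"] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(
            full.coef_series()[["x1", "x2"]], red.coef_series()[["x1", "x2"]],
            atol=1e-6,
        )

    def test_predicted_probabilities_sum_to_one_and_shift(self):
        X, y = self._sim(n=300, K=5)
        dm = _design_from_frame(X)
        model = om.fit_ordinal(dm, y, np.ones(len(y)))
        probs = om.ordinal_category_probs(model, dm.X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)
        # increasing a positive-coefficient covariate raises expected score
        hi = dm.X.copy()
        hi["x1"] = hi["x1"] + 1.0
        assert np.all(
            om.predict_expectation(model, hi) > om.predict_expectation(model, dm.X)
        )


class TestHurdle:
    def test_null_design_closed_forms(self):
        rng = np.random.default_rng(6)
        n = 800
        y = np.exp(rng.normal(0.7, 0.5, n))
        y[rng.random(n) < 0.35] = 0.0
        w = rng.uniform(0.5, 2.0, n)
        dm = _design_from_frame(pd.DataFrame(index=range(n)))
        model = om.fit_hurdle(dm, y, w)
        p_pos = np.average(y > 0, weights=w)
        assert model.coefs["binomial"][0] == pytest.approx(logit(p_pos), abs=1e-8)
        mu = np.average(np.log(y[y > 0]), weights=w[y > 0])
        assert model.coefs["log-normal"][0] == pytest.approx(mu, abs=1e-10)

    def test_predicted_mean_matches_weighted_sample_mean(self):
        """Intercept-only hurdle: p * exp(mu + s^2/2) vs the weighted mean of Y
        (log-normal mean identity, Monte-Carlo tolerance)."""
        rng = np.random.default_rng(7)
        n = 20000
        y = np.exp(rng.normal(0.5, 0.6, n))
        y[rng.random(n) < 0.4] = 0.0
        dm = _design_from_frame(pd.DataFrame(index=range(n)))
        model = om.fit_hurdle(dm, y, np.ones(n))
        pred = om.predict_expectation(model, dm.X)[0]
        se = y.std(ddof=1) / np.sqrt(n)
        assert abs(pred - y.mean()) < 3 * se

    def test_generator_truth_recovery(self, fitted_inputs):
        syn, sub, wsub, design = fitted_inputs
        spec = next(o for o in syn.config.outcomes if o.family == "hurdle")
        y = sub[spec.name].to_numpy()
        model = om.fit_hurdle(design, y, wsub["weight"].to_numpy())
        pos = y > 0
        ref_bin = sm.GLM(pos.astype(float), design.X.to_numpy(),
                         family=sm.families.Binomial(),
                         var_weights=wsub["weight"].to_numpy()).fit()
        ref_pos = sm.WLS(np.log(y[pos]), design.X.to_numpy()[pos],
                         weights=wsub["weight"].to_numpy()[pos]).fit()
        for drug in spec.beta_exposure:
            col = f"mean_Ce_{drug}"
            j = list(design.X.columns).index(col)
            sd = design.info.scaling[col][1]
            # binomial component models P(Y>0): negated zero-part truth
            truth_bin = -spec.zero_beta_exposure[drug] * sd
            assert abs(model.coef_series("binomial")[col] - truth_bin) < 3 * ref_bin.bse[j]
            truth_pos = spec.beta_exposure[drug] * sd
            assert abs(model.coef_series("log-normal")[col] - truth_pos) < 3 * ref_pos.bse[j]
        assert model.sigma == pytest.approx(spec.sigma, rel=0.05)

    def test_degenerate_hurdle_rejected(self):
        dm = _design_from_frame(pd.DataFrame(index=range(10)))
        with pytest.raises(ValueError, match="degenerate"):
            om.fit_hurdle(dm, np.ones(10), np.ones(10))


class TestCox:
    def test_null_exponential_h0_recovery(self):
        rng = np.random.default_rng(8)
        n = 10000
        lam = 0.02
        t = rng.exponential(1 / lam, n)
        dm = _design_from_frame(pd.DataFrame({"x": rng.normal(size=n)}))
        model = om.fit_cox(dm, t, np.ones(n), np.ones(n))
        # exponential-rate MLE SE: lam / sqrt(n)
        assert abs(model.h0 - lam) < 3 * lam / np.sqrt(n)

    def test_small_table_matches_grid_search_partial_likelihood(self):
        t = np.array([2.0, 5.0, 1.0, 8.0, 3.0, 9.0, 4.0, 7.0])
        d = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0])

        def neg_pl(beta):  # distinct event times: Efron == Breslow
            out = 0.0
            for i in np.where(d == 1)[0]:
                risk = t >= t[i]
                out -= beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return out

        grid = np.linspace(-3, 3, 120001)
        best = grid[np.argmin([neg_pl(b) for b in grid])]
        dm = _design_from_frame(pd.DataFrame({"x": x}))
        model = om.fit_cox(dm, t, d, np.ones(8))
        assert model.coef_series()["x"] == pytest.approx(best, abs=1e-3)

    def test_duplicated_rows_with_half_weights_identical(self):
        """Splitting each observation into two half-weight copies leaves the
        fit unchanged — exactly under Breslow ties; Efron treats the
        duplicate pairs as ties, so it is only near-invariant."""
        rng = np.random.default_rng(9)
        n = 150
        X = pd.DataFrame({"x": rng.normal(size=n)})
        t = rng.exponential(50, n) * np.exp(-0.4 * X["x"])
        d = (rng.random(n) < 0.8).astype(float)
        X2 = pd.concat([X, X], ignore_index=True)
        m1 = om.fit_cox(_design_from_frame(X), t.to_numpy(), d, np.ones(n),
                        ties="breslow")
        m2 = om.fit_cox(_design_from_frame(X2), np.r_[t, t], np.r_[d, d],
                        np.full(2 * n, 0.5), ties="breslow")
        assert m2.coef_series()["x"] == pytest.approx(m1.coef_series()["x"], abs=1e-8)
        assert m2.h0 == pytest.approx(m1.h0, rel=1e-9)
        e1 = om.fit_cox(_design_from_frame(X), t.to_numpy(), d, np.ones(n))
        e2 = om.fit_cox(_design_from_frame(X2), np.r_[t, t], np.r_[d, d],
                        np.full(2 * n, 0.5))
        assert e2.coef_series()["x"] == pytest.approx(e1.coef_series()["x"], abs=5e-3)

    def test_breslow_matches_statsmodels_phreg_unweighted(self):
        rng = np.random.default_rng(11)
        n = 200
        X = pd.DataFrame({"x1": rng.normal(size=n),
                          "x2": rng.binomial(1, 0.5, n).astype(float)})
        t = rng.exponential(30, n) * np.exp(0.6 * X["x1"])
        d = (rng.random(n) < 0.9).astype(float)
        mine = om.fit_cox(_design_from_frame(X), t.to_numpy(), d, np.ones(n),
                          ties="breslow")
        ref = PHReg(t.to_numpy(), X.to_numpy(), status=d, ties="breslow").fit()
        np.testing.assert_allclose(mine.coefs["mean"], ref.params, atol=1e-6)

    def test_unit_weights_match_statsmodels_phreg(self):
        rng = np.random.default_rng(10)
        n = 200
        X = pd.DataFrame({"x1": rng.normal(size=n),
                          "x2": rng.binomial(1, 0.5, n).astype(float)})
        t = rng.exponential(30, n) * np.exp(-0.5 * X["x1"] + 0.3 * X["x2"])
        d = (rng.random(n) < 0.85).astype(float)
        mine = om.fit_cox(_design_from_frame(X), t.to_numpy(), d, np.ones(n))
        ref = PHReg(t.to_numpy(), X.to_numpy(), status=d, ties="efron").fit()
        np.testing.assert_allclose(
            mine.coefs["mean"], ref.params, atol=1e-6
        )

    def test_all_censored_rejected(self):
        dm = _design_from_frame(pd.DataFrame({"x": [0.1, 0.5, 1.0]}))
        with pytest.raises(ValueError, match="event"):
            om.fit_cox(dm, np.array([1.0, 2.0, 3.0]), np.zeros(3), np.ones(3))


class TestEffectEstimates:
    def _manual_logistic(self, betas, cols, exposure_cols):
        info = om.DesignInfo(tuple(exposure_cols), tuple(cols), {}, {})
        return om.FittedOutcomeModel(family="logistic", outcome="y", info=info,
                                     coefs={"mean": np.asarray(betas)})

    def test_zero_and_log2_coefficients(self):
        m = self._manual_logistic([0.1, 0.0, np.log(2)],
                                  ("const", "mean_Ce_fentanyl", "mean_Ce_hydromorphone"),
                                  ("mean_Ce_fentanyl", "mean_Ce_hydromorphone"))
        est = {e.exposure: e.ratio for e in om.effect_estimates(m)}
        assert est["mean_Ce_fentanyl"] == pytest.approx(1.0)
        assert est["mean_Ce_hydromorphone"] == pytest.approx(2.0)

    def test_hurdle_yields_two_estimates_per_exposure(self, fitted_inputs):
        syn, sub, wsub, design = fitted_inputs
        spec = next(o for o in syn.config.outcomes if o.family == "hurdle")
        model = om.fit_hurdle(design, sub[spec.name].to_numpy(),
                              wsub["weight"].to_numpy())
        ests = om.effect_estimates(model)
        for expo in design.info.exposure_cols:
            comps = sorted(e.component for e in ests if e.exposure == expo)
            assert comps == ["binomial", "log-normal"]

    def test_cox_labeled_hazard_ratio(self):
        info = om.DesignInfo(("mean_Ce_fentanyl",), ("const", "mean_Ce_fentanyl"), {}, {})
        m = om.FittedOutcomeModel(family="cox", outcome="t", info=info,
                                  coefs={"mean": np.array([0.5])}, h0=0.01)
        (est,) = om.effect_estimates(m)
        assert est.kind == "hazard ratio" and est.ratio == pytest.approx(np.exp(0.5))
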