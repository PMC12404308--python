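import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from siirii import (
    OutcomeSpec,
    SurveyDataset,
    estimate_sii_rii,
    fit_inequality_model,
    inequality_estimates,
    inequality_table,
    simulate_survey,
    trend_rule,
    weighted_prevalence,
)
from .conftest import make_config


def category_dataset(counts, positives, weights=None):
    """One-stratum dataset, each row its own PSU, ordered SES column."""
    rows = []
    i = 0
    for cat, (n, k) in enumerate(zip(counts, positives), start=1):
        for j in range(n):
            rows.append(
                {
                    "stratum": 1,
                    "psu": i,
                    "weight": 1.0 if weights is None else weights[cat - 1],
                    "year": "2013",
                    "ses": cat,
                    "y": 1 if j < k else 0,
                }
            )
            i += 1
    return SurveyDataset(pd.DataFrame(rows))


class TestFitClosedForms:
    def test_two_category_saturated_ratio(self):
        # exp(beta * (s2 - s1)) must equal the ratio of the two
        # categories' weighted prevalences (saturated two-cell model)
        data = category_dataset([40, 60], [8, 24])
        fit = fit_inequality_model(data, "y", "ses", covariates=())
        s = np.asarray(
            [0.4 / 2, 0.4 + 0.6 / 2]
        )  # shares (0.4, 0.6) -> ridits (0.2, 0.7)
        ratio = (24 / 60) / (8 / 40)
        assert math.exp(fit.coef("ridit") * (s[1] - s[0])) == pytest.approx(
            ratio, abs=1e-8
        )

    def test_intercept_score_equation(self):
        # the weighted mean of fitted prevalences equals the weighted
        # sample prevalence (log-link intercept score equation)
        data, _ = simulate_survey(make_config(years=("2013",), seed=31))
        fit = fit_inequality_model(data, "outcome", "schooling")
        sub = data.df.loc[fit.row_index]
        X = fit.spec.matrix(sub, year_col="year").to_numpy(float)
        mu = np.exp(X @ fit.params.to_numpy(float))
        w = sub["weight"].to_numpy()
        fitted_mean = float(w @ mu / w.sum())
        observed = float(w @ sub["outcome"].to_numpy() / w.sum())
        assert fitted_mean == pytest.approx(observed, abs=1e-8)

    def test_three_category_log_linear_oracle(self):
        # prevalences exactly log-linear in the ridit: the regression
        # path must agree with the direct two-point closed form
        data = category_dataset([50, 50, 50], [5, 10, 20])
        fit = fit_inequality_model(data, "y", "ses", covariates=())
        est = estimate_sii_rii(data=data, fit=fit)
        s1, s3 = 1 / 6, 5 / 6
        b = math.log((20 / 50) / (5 / 50)) / (s3 - s1)
        a = math.log(5 / 50) - b * s1
        assert est.rii == pytest.approx(math.exp(b), abs=1e-6)
        assert est.sii == pytest.approx(
            100 * (math.exp(a + b) - math.exp(a)), abs=1e-6
        )

    def test_constant_outcome_rejected(self):
        data = category_dataset([10, 10], [10, 10])
        with pytest.raises(ValueError, match="constant"):
            fit_inequality_model(data, "y", "ses", covariates=())

    def test_sandwich_matches_external_reference(self):
        """Cluster-robust SEs frozen from an independent sandwich-
        covariance implementation (R `sandwich::vcovCL`, HC0 with
        cluster adjustment) on this exact dataset."""
        rng = np.random.default_rng(7)
        n = 400
        df = pd.DataFrame(
            {
                "stratum": 1,
                "psu": rng.integers(1, 21, n),
                "weight": rng.lognormal(0, 0.4, n),
                "year": "2013",
                "sex": rng.choice(["female", "male"], n),
                "age_group": rng.choice(["18-29", "30-59", "60+"], n),
                "schooling": rng.integers(1, 7, n),
            }
        )
        p = 0.25 * np.exp(0.5 * (df.schooling - 1) / 5)
        df["y"] = (rng.random(n) < p).astype(int)
        fit = fit_inequality_model(SurveyDataset(df), "y", "schooling")
        expected_coef = [-1.50792240, 0.76359805, -0.02791973, -0.08733818, 0.02131499]
        expected_se = [0.2675027, 0.3094948, 0.1430298, 0.2298943, 0.1880440]
        assert np.allclose(fit.params, expected_coef, atol=1e-5)
        assert np.allclose(np.sqrt(np.diag(fit.vcov)), expected_se, rtol=2e-4)


class TestEstimateSiiRii:
    def test_zero_gradient_exact(self):
        data, _ = simulate_survey(make_config(seed=41))
        fit = fit_inequality_model(data, "outcome", "schooling", with_interaction=True)
        params = fit.params.copy()
        params["ridit"] = 0.0
        params["ridit:year[2019]"] = 0.0
        flat = dataclasses.replace(fit, params=params)
        for year in ("2013", "2019"):
            est = estimate_sii_rii(flat, data, year)
            assert est.sii == 0.0
            assert est.rii == 1.0

    def test_rii_equals_exponentiated_gradient(self):
        data, _ = simulate_survey(make_config(seed=42))
        fit = fit_inequality_model(data, "outcome", "schooling", with_interaction=True)
        for year, extra in (("2013", 0.0), ("2019", fit.coef("ridit:year[2019]"))):
            est = estimate_sii_rii(fit, data, year)
            assert abs(est.rii - math.exp(fit.coef("ridit") + extra)) < 1e-10

    def test_invariance_to_weights_scale_and_row_order(self):
        data, _ = simulate_survey(make_config(seed=43))
        ref = inequality_estimates(data, "outcome", "schooling")[0]
        df2 = data.df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        df2["weight"] = df2["weight"] * 137.0
        alt = inequality_estimates(SurveyDataset(df2), "outcome", "schooling")[0]
        assert alt.sii == pytest.approx(ref.sii, abs=1e-8)
        assert alt.rii == pytest.approx(ref.rii, abs=1e-10)
        assert alt.sii_ci == pytest.approx(ref.sii_ci, abs=1e-7)

    def test_refuses_nonconverged_fit(self):
        data, _ = simulate_survey(make_config(seed=44))
        fit = fit_inequality_model(data, "outcome", "schooling")
        broken = dataclasses.replace(fit, converged=False)
        with pytest.raises(ValueError, match="non-converged"):
            estimate_sii_rii(broken, data, "2013")

    def test_prediction_above_one_warns_but_returns(self):
        # a steep gradient on a common outcome pushes p(ridit=1) past 1
        data = category_dataset([60, 60], [30, 54])
        fit = fit_inequality_model(data, "y", "ses", covariates=())
        est = estimate_sii_rii(data=data, fit=fit)
        assert est.warnings and "exceed 1" in est.warnings[0]
        assert np.isfinite(est.sii)


def test_index_ci_coverage_nominal():
    """95% CIs for SII and RII cover the generator truth at the nominal
    rate over 200 replicates (within binomial bounds)."""
    base = make_config(
        n_strata=15,
        psus_per_stratum=6,
        respondents_per_psu=22,
        outcomes=(OutcomeSpec("y", 0.3, math.log(2.0)),),
    )
    hits_sii = hits_rii = 0
    n_reps = 200
    for rep in range(n_reps):
        data, truth = simulate_survey(dataclasses.replace(base, seed=70_000 + rep))
        fit = fit_inequality_model(data, "y", "schooling")
        est = estimate_sii_rii(fit, data, "2013")
        hits_sii += est.sii_ci[0] <= truth.sii("y", "2013") <= est.sii_ci[1]
        hits_rii += est.rii_ci[0] <= truth.rii("y", "2013") <= est.rii_ci[1]
    half = 1.96 * math.sqrt(0.95 * 0.05 / n_reps)
    assert 0.95 - half <= hits_sii / n_reps <= 0.95 + half
    assert 0.95 - half <= hits_rii / n_reps <= 0.95 + half


class TestTrendRule:
    def test_power_case_changing_gradient(self):
        # gradient ln 3 in the first year vs ln 2 in the second:
        # interaction retained, with a negative coefficient
        cfg = make_config(
            n_strata=25,
            psus_per_stratum=8,
            respondents_per_psu=100,
            outcomes=(
                OutcomeSpec(
                    "y", 0.2, {"2013": math.log(3.0), "2019": math.log(2.0)}
                ),
            ),
            seed=51,
        )
        data, _ = simulate_survey(cfg)
        fit = fit_inequality_model(data, "y", "schooling", with_interaction=True)
        retained, p = trend_rule(fit)
        assert retained and p < 0.05
        assert fit.coef("ridit:year[2019]") < 0

    def test_boundary_alpha_not_retained(self):
        data, _ = simulate_survey(make_config(seed=52))
        fit = fit_inequality_model(data, "outcome", "schooling", with_interaction=True)
        _, p = trend_rule(fit)
        retained_at_p, _ = trend_rule(fit, alpha=p)
        assert retained_at_p is False  # strict inequality at the boundary

    def test_missing_interaction_errors(self):
        data, _ = simulate_survey(make_config(seed=53))
        fit = fit_inequality_model(data, "outcome", "schooling")
        with pytest.raises(ValueError, match="interaction"):
            trend_rule(fit)


class TestPipelineRule:
    def test_pooled_refit_shares_rii_across_years(self):
        data, _ = simulate_survey(make_config(seed=61))
        ests = inequality_estimates(data, "outcome", "schooling")
        if not ests[0].interaction_retained:
            assert ests[0].rii == pytest.approx(ests[1].rii, abs=1e-12)
        assert ests[0].interaction_p == ests[1].interaction_p

    def test_table_layout(self):
        data, _ = simulate_survey(make_config(seed=62))
        table = inequality_table(data, ["outcome"], ["schooling", "income"])
        assert len(table) == 4  # 1 outcome x 2 dimensions x 2 years
        assert {"sii", "rii", "interaction_p", "interaction_retained"} <= set(
            table.columns
        )
        # SII and log(RII) agree in sign within each fitted row
        assert all(
            np.sign(r.sii) == np.sign(math.log(r.rii)) or r.sii == 0
            for r in table.itertuples()
        )
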