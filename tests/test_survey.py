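import math

import numpy as np
import pandas as pd
import pytest

from siirii import (
    OutcomeSpec,
    SurveyDataset,
    ValidationError,
    read_microdata,
    simulate_survey,
    weighted_prevalence,
    year_comparison_test,
)
from .conftest import make_config, marginal_prevalence


def toy_dataset(weights, y, **extra):
    n = len(y)
    df = pd.DataFrame(
        {
            "stratum": extra.get("stratum", [1] * n),
            "psu": extra.get("psu", list(range(n))),
            "weight": weights,
            "year": extra.get("year", ["2013"] * n),
            "y": y,
        }
    )
    return SurveyDataset(df)


class TestWeightedPrevalence:
    def test_hand_horvitz_thompson(self):
        # (1*1 + 2*1) / (1+1+2+4) = 3/8
        data = toy_dataset([1, 1, 2, 4], [1, 0, 1, 0])
        est = weighted_prevalence(data, "y")[0]
        assert est.estimate == pytest.approx(0.375, abs=1e-12)

    def test_degenerate_all_ones(self):
        data = toy_dataset([3, 1, 9], [1, 1, 1])
        est = weighted_prevalence(data, "y")[0]
        assert est.estimate == 1.0
        assert est.ci95 == (1.0, 1.0)

    def test_weight_scale_invariance(self):
        d1 = toy_dataset([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 0], psu=[1, 1, 2, 2, 3, 3])
        d2 = toy_dataset([10, 20, 30, 40, 50, 60], [1, 0, 1, 1, 0, 0], psu=[1, 1, 2, 2, 3, 3])
        e1, e2 = weighted_prevalence(d1, "y")[0], weighted_prevalence(d2, "y")[0]
        assert e1.estimate == pytest.approx(e2.estimate, abs=1e-14)
        assert e1.se == pytest.approx(e2.se, abs=1e-14)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        data, _ = simulate_survey(make_config(seed=2))
        est = weighted_prevalence(data, "outcome")
        perm = rng.permutation(len(data.df))
        shuffled = SurveyDataset(data.df.iloc[perm], data.design)
        est2 = weighted_prevalence(shuffled, "outcome")
        for a, b in zip(est, est2):
            assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
            assert a.se == pytest.approx(b.se, abs=1e-12)

    def test_srs_reduces_to_binomial_se(self):
        # each respondent its own PSU, equal weights, one stratum:
        # linearized SE must equal sqrt(p*(1-p)/(n-1)) exactly
        rng = np.random.default_rng(0)
        y = (rng.random(100) < 0.4).astype(int)
        data = toy_dataset(np.ones(100), y)
        est = weighted_prevalence(data, "y")[0]
        p = y.mean()
        assert est.estimate == pytest.approx(p, abs=1e-12)
        assert est.se == pytest.approx(math.sqrt(p * (1 - p) / 99), abs=1e-10)

    def test_few_psu_cell_flagged(self):
        data = toy_dataset([1, 1, 1], [1, 0, 1], psu=[1, 1, 1])
        est = weighted_prevalence(data, "y")[0]
        assert est.flagged and np.isnan(est.se)

    def test_missing_outcomes_complete_case(self):
        data = toy_dataset([1, 1, 2, 4], [1, np.nan, 1, 0], psu=[1, 1, 2, 2])
        est = weighted_prevalence(data, "y")[0]
        assert est.n_unweighted == 3
        assert est.estimate == pytest.approx(3 / 7)

    def test_ci_within_unit_interval_near_boundary(self):
        rng = np.random.default_rng(1)
        y = (rng.random(400) < 0.98).astype(int)
        data = toy_dataset(np.ones(400), y, psu=list(np.arange(400) // 10))
        est = weighted_prevalence(data, "y")[0]
        lo, hi = est.ci95
        assert 0 <= lo <= est.estimate <= hi <= 1

    def test_ci_coverage_nominal(self):
        """95% CI covers the true prevalence at the nominal rate over
        200 synthetic replicates (within binomial bounds)."""
        cfg0 = make_config(
            years=("2013",),
            n_strata=8,
            psus_per_stratum=5,
            respondents_per_psu=15,
            outcomes=(OutcomeSpec("y", 0.3, math.log(2.0)),),
        )
        truth = marginal_prevalence(cfg0, "y", "2013")
        hits = 0
        for rep in range(200):
            import dataclasses

            data, _ = simulate_survey(dataclasses.replace(cfg0, seed=3000 + rep))
            lo, hi = weighted_prevalence(data, "y")[0].ci95
            hits += lo <= truth <= hi
        # binomial 95% band around 0.95 with 200 draws
        assert 0.95 - 1.96 * math.sqrt(0.95 * 0.05 / 200) <= hits / 200 <= 1.0


class TestReadMicrodata:
    def test_missing_weight_column_fatal(self, tmp_path):
        p = tmp_path / "d.csv"
        pd.DataFrame({"stratum": [1], "psu": [1], "year": [2013], "y": [1]}).to_csv(
            p, index=False
        )
        with pytest.raises(ValidationError, match="weight"):
            read_microdata(p)

    def test_negative_weight_cites_row(self, tmp_path):
        p = tmp_path / "d.csv"
        pd.DataFrame(
            {
                "stratum": [1, 1],
                "psu": [1, 2],
                "weight": [1.0, -2.0],
                "year": [2013, 2013],
                "y": [1, 0],
            }
        ).to_csv(p, index=False)
        with pytest.raises(ValidationError, match=r"\[1\]"):
            read_microdata(p)

    def test_unknown_category_code_fatal(self, tmp_path):
        p = tmp_path / "d.csv"
        pd.DataFrame(
            {
                "stratum": [1, 1],
                "psu": [1, 2],
                "weight": [1.0, 2.0],
                "year": [2013, 2013],
                "sexo": ["F", "X"],
            }
        ).to_csv(p, index=False)
        mapping = {
            "rename": {"sexo": "sex"},
            "categories": {"sex": {"F": "female", "M": "male"}},
        }
        with pytest.raises(ValidationError, match="'X'"):
            read_microdata(p, mapping)

    def test_psu_crossing_strata_rejected(self):
        df = pd.DataFrame(
            {
                "stratum": [1, 2],
                "psu": ["a", "a"],
                "weight": [1.0, 1.0],
                "year": ["2013", "2013"],
            }
        )
        with pytest.raises(ValidationError, match="more than one stratum"):
            SurveyDataset(df)


class TestYearComparison:
    def test_null_identity_relabelled_years(self):
        cfg = make_config(years=("2013",), seed=6)
        data, _ = simulate_survey(cfg)
        df2 = data.df.copy()
        df2["year"] = "2019"
        df2["psu"] = df2["psu"] + "b"
        both = SurveyDataset(pd.concat([data.df, df2], ignore_index=True))
        res = year_comparison_test(both, "outcome")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_large_shift_detected(self):
        # prevalences near 0.53 vs 0.63 at 20,000/year: decisive evidence
        cfg = make_config(
            n_strata=25,
            psus_per_stratum=8,
            respondents_per_psu=100,
            outcomes=(
                OutcomeSpec("y", 0.53, {"2013": 0.0, "2019": math.log(0.63 / 0.53)}),
            ),
            sex_effect=0.0,
            age_effects=(0.0, 0.0),
            seed=17,
        )
        data, _ = simulate_survey(cfg)
        res = year_comparison_test(data, "y")
        assert res.pvalue < 0.001

    def test_single_year_errors(self):
        data, _ = simulate_survey(make_config(years=("2013",), seed=1))
        with pytest.raises(ValueError, match="exactly 2"):
            year_comparison_test(data, "outcome")
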