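"""BMI classification, survey-weighted summaries, and projections."""

import numpy as np
import pandas as pd
import pytest

from ssbreform import DomainError, classify_bmi, project_cases, weighted_summary
from ssbreform.outcomes import _bootstrap_ses, _taylor_se, weighted_mean


def make_population(n, rng, n_strata=8, psus=3):
    stratum = rng.integers(1, n_strata + 1, size=n)
    psu = (stratum - 1) * psus + rng.integers(1, psus + 1, size=n)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": rng.choice(["male", "female"], size=n),
            "age": rng.uniform(20, 80, size=n),
            "ses": rng.choice(["low", "middle", "high"], size=n),
            "sugar_ssb": rng.uniform(0, 200, size=n),
            "survey_weight": rng.lognormal(0, 0.4, size=n),
            "stratum": stratum,
            "psu": psu,
        }
    )


class TestClassifyBMI:
    @pytest.mark.parametrize(
        "bmi,cat",
        [
            (24.999, "normal"),
            (25.0, "overweight"),
            (29.999, "overweight"),
            (30.0, "obese"),
            (17.0, "normal"),  # underweight collapsed into normal
            (45.0, "obese"),
        ],
    )
    def test_half_open_boundaries(self, bmi, cat):
        assert classify_bmi(bmi) == cat

    def test_vectorized(self):
        out = classify_bmi(np.array([20.0, 27.0, 31.0]))
        assert out.tolist() == ["normal", "overweight", "obese"]

    def test_non_positive_rejected(self):
        with pytest.raises(DomainError):
            classify_bmi(0.0)


class TestProjectCases:
    def test_simple_products(self):
        assert project_cases(-3.9, 90_000_000) == pytest.approx(-3_510_000)
        assert project_cases(0.0, 1e9) == 0.0
        assert project_cases(3.8, 92_100_000) == pytest.approx(3_499_800)

    def test_requires_positive_population(self):
        with pytest.raises(DomainError):
            project_cases(1.0, 0.0)


class TestWeightedSummary:
    @staticmethod
    def _results_for(pop, delta_w):
        h = 1.70
        bmi0 = np.full(len(pop), 27.0)
        return pd.DataFrame(
            {
                "id": pop["id"],
                "delta_sugar": -50.0,
                "delta_intake": -28.0,
                "delta_weight": delta_w,
                "bmi_baseline": bmi0,
                "bmi_final": bmi0 + np.asarray(delta_w) / h**2,
                "delta_bmi": np.asarray(delta_w) / h**2,
            }
        )

    def test_two_record_weighted_mean(self):
        rng = np.random.default_rng(0)
        pop = make_population(2, rng)
        pop["survey_weight"] = [1.0, 3.0]
        res = self._results_for(pop, [-1.0, -2.0])
        out = weighted_summary(pop, res, ci_method="none")
        overall = out.loc[out["stratum_var"] == "overall"].iloc[0]
        assert overall["mean_delta_weight"] == pytest.approx(-1.75)

    def test_prevalence_deltas_sum_to_zero(self, pop_small):
        rng = np.random.default_rng(1)
        pop = pop_small
        h2 = pop["height"].to_numpy() ** 2
        res = pd.DataFrame(
            {
                "id": pop["id"],
                "delta_sugar": -50.0,
                "delta_intake": -28.0,
                "delta_weight": rng.normal(-1.3, 0.5, len(pop)),
            }
        )
        res["bmi_baseline"] = pop["weight"].to_numpy() / h2
        res["bmi_final"] = res["bmi_baseline"] + res["delta_weight"] / h2
        res["delta_bmi"] = res["delta_weight"] / h2
        out = weighted_summary(pop, res, ci_method="none")
        for _, row in out.iterrows():
            total = sum(row[f"delta_pp_{c}"] for c in ("normal", "overweight", "obese"))
            assert total == pytest.approx(0.0, abs=1e-9)
            base = sum(
                row[f"prev_baseline_{c}"] for c in ("normal", "overweight", "obese")
            )
            assert base == pytest.approx(100.0, abs=1e-9)

    def test_constructed_30_percent_crossing(self):
        """A population built so exactly 30%% of the weight mass crosses the
        obesity boundary downward recovers delta_pp = -30 exactly."""
        n = 100
        rng = np.random.default_rng(2)
        pop = make_population(n, rng)
        pop["survey_weight"] = 1.0  # equal mass
        bmi0 = np.where(np.arange(n) < 60, 31.0, 26.0)  # 60% obese at baseline
        crosses = np.arange(n) < 30  # exactly 30 records drop below 30
        bmi1 = np.where(crosses, 29.0, bmi0)
        res = pd.DataFrame(
            {
                "id": pop["id"],
                "delta_sugar": 0.0,
                "delta_intake": 0.0,
                "delta_weight": (bmi1 - bmi0) * 1.7**2,
                "bmi_baseline": bmi0,
                "bmi_final": bmi1,
                "delta_bmi": bmi1 - bmi0,
            }
        )
        out = weighted_summary(pop, res, ci_method="none")
        overall = out.loc[out["stratum_var"] == "overall"].iloc[0]
        assert overall["delta_pp_obese"] == pytest.approx(-30.0, abs=1e-9)
        assert overall["delta_pp_overweight"] == pytest.approx(30.0, abs=1e-9)

    def test_consumers_stratum_loses_more_weight(self, pop_small):
        """Non-consumers have zero change, so the consumers-only mean loss
        must strictly exceed the overall mean loss."""
        pop = pop_small
        h2 = pop["height"].to_numpy() ** 2
        dw = np.where(pop["sugar_ssb"] > 0, -2.0, 0.0)
        res = pd.DataFrame(
            {
                "id": pop["id"],
                "delta_sugar": 0.0,
                "delta_intake": 0.0,
                "delta_weight": dw,
                "bmi_baseline": pop["weight"].to_numpy() / h2,
                "bmi_final": (pop["weight"].to_numpy() + dw) / h2,
                "delta_bmi": dw / h2,
            }
        )
        out = weighted_summary(pop, res, ci_method="none").set_index("stratum_var")
        assert (
            out.loc["consumers", "mean_delta_weight"]
            < out.loc["overall", "mean_delta_weight"]
        )

    def test_bootstrap_and_taylor_ses_agree(self, pop_small):
        rng = np.random.default_rng(3)
        y = rng.normal(0.0, 1.0, len(pop_small))
        w = pop_small["survey_weight"].to_numpy()
        strata = pop_small["stratum"].to_numpy()
        psu = pop_small["psu"].to_numpy()
        se_t = _taylor_se(y, w, strata, psu)
        se_b = _bootstrap_ses({"y": y}, w, strata, psu, 400, np.random.default_rng(4))[
            "y"
        ]
        assert se_b == pytest.approx(se_t, rel=0.35)


class TestCICoverage:
    def test_taylor_interval_coverage_on_known_design(self):
        """95%% design-based CIs on a stratified clustered design with a
        known true mean cover it in 90-99%% of 200 seeded replicates."""
        truth = 5.0
        covered = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            pop = make_population(300, rng)
            cluster = rng.normal(0.0, 0.3, size=pop["psu"].max() + 1)
            y = truth + cluster[pop["psu"]] + rng.normal(0.0, 1.0, 300)
            w = pop["survey_weight"].to_numpy()
            est = weighted_mean(y, w)
            se = _taylor_se(y, w, pop["stratum"].to_numpy(), pop["psu"].to_numpy())
            if est - 1.96 * se <= truth <= est + 1.96 * se:
                covered += 1
        assert 0.90 * n_rep <= covered <= 0.99 * n_rep
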