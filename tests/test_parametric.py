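"""Parametric survival fitting, information criteria and family selection."""

import math

import numpy as np
import pandas as pd
import pytest

from psmcea import SurvivalModel, compare_families, fit, select_family
from psmcea.parametric import FAMILIES


def _model(family, **params):
    return SurvivalModel(family=family, params=params, loglik=0.0,
                         n_params=len(params), n_obs=10)


class TestFit:
    def test_exponential_closed_form_mle(self):
        # complete data {1,2,3}: rate MLE = events / total time = 3/6
        ipd = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1]})
        m = fit(ipd, "exponential")
        assert m.params["rate"] == pytest.approx(0.5, abs=1e-5)

    def test_weibull_recovers_simulation_truth(self, medium_arm):
        _, os_ipd = medium_arm  # Weibull(1.3, 12) with mild censoring
        m = fit(os_ipd, "weibull")
        assert 1.17 <= m.params["shape"] <= 1.43  # +/- 10%
        assert 10.8 <= m.params["scale"] <= 13.2

    def test_weibull_matches_lifelines_mle(self, medium_arm):
        # independent optimizer on the same likelihood
        from lifelines import WeibullFitter

        _, os_ipd = medium_arm
        ours = fit(os_ipd, "weibull")
        ref = WeibullFitter().fit(os_ipd["time"], os_ipd["event"])
        assert ours.loglik == pytest.approx(ref.log_likelihood_, abs=1e-4)
        assert ours.params["shape"] == pytest.approx(ref.rho_, rel=1e-4)
        assert ours.params["scale"] == pytest.approx(ref.lambda_, rel=1e-4)

    def test_weibull_shape_near_one_on_exponential_data(self):
        rng = np.random.default_rng(11)
        ipd = pd.DataFrame({"time": rng.exponential(8.0, 2000), "event": 1})
        m = fit(ipd, "weibull")
        assert abs(m.params["shape"] - 1.0) < 0.1

    def test_order_invariance(self, medium_arm):
        _, os_ipd = medium_arm
        shuffled = os_ipd.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a, b = fit(os_ipd, "weibull"), fit(shuffled, "weibull")
        assert a.params == pytest.approx(b.params)

    def test_all_censored_rejected(self):
        ipd = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 0]})
        with pytest.raises(ValueError):
            fit(ipd, "weibull")

    def test_unknown_family_rejected(self, medium_arm):
        with pytest.raises(ValueError):
            fit(medium_arm[1], "spline")

    @pytest.mark.parametrize("family", FAMILIES)
    def test_every_family_fits_and_is_proper(self, family, medium_arm):
        _, os_ipd = medium_arm
        m = fit(os_ipd, family)
        t = np.linspace(0.0, 400.0, 200)
        s = np.asarray(m.survival_at(t))
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)
        assert s[-1] < 0.01  # proper distribution: everyone eventually dies


class TestSurvivalAt:
    def test_unit_at_zero(self):
        m = _model("gompertz", shape=0.5, rate=0.1)
        assert m.survival_at(0.0) == 1.0

    def test_weibull_exponential_special_case(self):
        m = _model("weibull", shape=1.0, scale=10.0)
        assert m.survival_at(10.0) == pytest.approx(math.exp(-1), abs=1e-6)

    def test_weibull_closed_form(self):
        m = _model("weibull", shape=2.0, scale=10.0)
        assert m.survival_at(5.0) == pytest.approx(math.exp(-0.25), abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            _model("weibull", shape=1.0, scale=1.0).survival_at(-1.0)


class TestMedian:
    @pytest.mark.parametrize(
        "family,params,expected",
        [
            ("weibull", {"shape": 1.5, "scale": 12.0}, 12 * math.log(2) ** (1 / 1.5)),
            ("exponential", {"rate": 0.5}, math.log(2) / 0.5),
            ("lognormal", {"mu": 2.0, "sigma": 1.0}, math.e**2),
            ("loglogistic", {"shape": 2.0, "scale": 7.0}, 7.0),
        ],
    )
    def test_closed_forms(self, family, params, expected):
        assert _model(family, **params).median() == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_median_halves_survival(self, medium_arm, family):
        m = fit(medium_arm[1], family)
        assert m.survival_at(m.median()) == pytest.approx(0.5, abs=1e-6)


class TestComparisonAndSelection:
    def test_information_criteria_identities(self, medium_arm):
        table = compare_families(medium_arm[1])
        k = table["n_params"]
        n = len(medium_arm[1])
        assert np.allclose(table["aic"], -2 * table["loglik"] + 2 * k)
        assert np.allclose(table["bic"], -2 * table["loglik"] + k * np.log(n))
        assert table["aic"].is_monotonic_increasing

    def test_one_extra_parameter_costs_about_two_aic(self):
        rng = np.random.default_rng(5)
        ipd = pd.DataFrame({"time": rng.exponential(10.0, 4000), "event": 1})
        table = compare_families(ipd, families=("exponential", "weibull")).set_index("family")
        # on truly exponential data the Weibull adds ~0 log-likelihood
        assert abs(table.loc["weibull", "aic"] - table.loc["exponential", "aic"]) < 2.5

    def test_preference_rule_keeps_close_runner_up(self):
        # AIC gap 0.42% — well inside the 5% proximity band
        table = pd.DataFrame(
            {
                "family": ["loglogistic", "weibull"],
                "loglik": [-368.75, -370.33],
                "aic": [741.509, 744.655],
                "bic": [748.155, 751.301],
                "n_params": [2, 2],
            }
        )
        assert select_family(table, "weibull", 0.05) == "weibull"

    def test_single_row_table(self):
        table = pd.DataFrame(
            {"family": ["gamma"], "loglik": [-10.0], "aic": [24.0], "bic": [25.0],
             "n_params": [2]}
        )
        assert select_family(table, "weibull") == "gamma"

    def test_distant_preferred_family_loses(self):
        table = pd.DataFrame(
            {
                "family": ["lognormal", "weibull"],
                "loglik": [-350.0, -385.0],
                "aic": [704.0, 774.0],  # 10% worse
                "bic": [710.0, 780.0],
                "n_params": [2, 2],
            }
        )
        assert select_family(table, "weibull", 0.05) == "lognormal"

    def test_parameter_recovery_across_seeds(self):
        """Median absolute relative error of Weibull MLE < 5% over seeds."""
        errs_shape, errs_scale = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = 12.0 * rng.weibull(1.3, 500)
            c = rng.exponential(35.0, 500)  # ~20% censoring
            ipd = pd.DataFrame(
                {"time": np.minimum(t, c), "event": (t <= c).astype(int)}
            )
            m = fit(ipd, "weibull")
            errs_shape.append(abs(m.params["shape"] - 1.3) / 1.3)
            errs_scale.append(abs(m.params["scale"] - 12.0) / 12.0)
        assert np.median(errs_shape) < 0.05
        assert np.median(errs_scale) < 0.05


def test_json_round_trip(medium_arm):
    m = fit(medium_arm[1], "weibull")
    again = SurvivalModel.from_json(m.to_json())
    assert again.params == pytest.approx(m.params)
    assert again.aic == pytest.approx(m.aic)
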