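"""DSA tornado, PSA draws, CEAC and scenario machinery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psmcea.economics import EconomicInputs, evaluate
from psmcea.psm import occupancy_from_series
from psmcea.sensitivity import (
    ParamRange,
    PSASpec,
    apply_overrides,
    ceac,
    default_dsa_ranges,
    draw_psa_parameters,
    moment_match_beta,
    moment_match_gamma,
    one_way_dsa,
    run_psa,
    scenario_price_reduction,
    scenario_utilities,
)


@pytest.fixture(scope="module")
def occupancies():
    """A dominated-by-treatment pair of occupancy curves."""
    cycles = np.arange(105)
    s_os1 = np.exp(-((cycles * 21 / 30.4375 / 16.0) ** 1.4))
    s_pfs1 = np.exp(-((cycles * 21 / 30.4375 / 10.0) ** 1.4))
    s_os0 = np.exp(-((cycles * 21 / 30.4375 / 13.0) ** 1.4))
    s_pfs0 = np.exp(-((cycles * 21 / 30.4375 / 7.5) ** 1.4))
    return (
        occupancy_from_series(np.minimum(s_pfs1, s_os1), s_os1),
        occupancy_from_series(np.minimum(s_pfs0, s_os0), s_os0),
    )


class TestOneWayDSA:
    def _toy_model(self, overrides):
        # hand-built closure: ICER = 10,000 / (0.4 * u_pfs / 0.8)
        d_cost = overrides.get("d_cost", 10000.0)
        d_eff = 0.4 * overrides.get("u_pfs", 0.8) / 0.8
        return d_cost / d_eff

    def test_closed_form_endpoints(self):
        rows = one_way_dsa(
            self._toy_model, [ParamRange("u_pfs", 0.8, 0.6, 1.0)]
        ).iloc[0]
        assert rows["icer_at_low"] == pytest.approx(10000 / 0.3)
        assert rows["icer_at_high"] == pytest.approx(10000 / 0.5)

    def test_ignored_parameter_sorts_last_with_zero_width(self):
        ranges = [
            ParamRange("u_pfs", 0.8, 0.6, 1.0),
            ParamRange("unused", 1.0, 0.5, 1.5),
        ]
        out = one_way_dsa(self._toy_model, ranges)
        assert out.iloc[-1]["name"] == "unused"
        assert out.iloc[-1]["width"] == 0.0

    def test_width_invariant_to_parameter_order(self):
        ranges = [
            ParamRange("u_pfs", 0.8, 0.6, 1.0),
            ParamRange("d_cost", 10000.0, 7500.0, 12500.0),
        ]
        a = one_way_dsa(self._toy_model, ranges)
        b = one_way_dsa(self._toy_model, list(reversed(ranges)))
        pd.testing.assert_frame_equal(a, b)

    def test_utility_direction_on_real_model(self, occupancies, base_inputs):
        occ1, occ0 = occupancies

        def model(ov):
            return evaluate(occ1, occ0, apply_overrides(base_inputs, ov)).icer

        base = model({})
        assert model({"u_pfs": 0.840}) < base < model({"u_pfs": 0.603})

    def test_default_ranges_cover_costs_utilities_discount(self, base_inputs):
        names = {r.name for r in default_dsa_ranges(base_inputs)}
        assert {"u_pfs", "u_pd", "discount_rate", "arm1.cost_pfs", "arm0.one_time"} <= names


class TestMomentMatching:
    def test_gamma_twenty_percent_se_gives_shape_25(self):
        shape, scale = moment_match_gamma(904.48, 0.2 * 904.48)
        assert shape == pytest.approx(25.0)
        assert scale == pytest.approx(36.1792)

    def test_gamma_reproduces_moments_analytically(self):
        shape, scale = moment_match_gamma(3.7, 0.9)
        assert shape * scale == pytest.approx(3.7, abs=1e-9)
        assert np.sqrt(shape) * scale == pytest.approx(0.9, abs=1e-9)

    def test_beta_symmetric_case(self):
        a, b = moment_match_beta(0.5, 0.1)
        assert (a, b) == (pytest.approx(12.0), pytest.approx(12.0))

    def test_beta_progression_free_utility_draw(self):
        a, b = moment_match_beta(0.804, 0.2 * 0.804)
        assert a == pytest.approx(4.0960, abs=1e-4)
        assert b == pytest.approx(0.99852, abs=1e-4)
        assert a / (a + b) == pytest.approx(0.804, abs=1e-12)

    def test_beta_overdispersion_rejected(self):
        with pytest.raises(ValueError):
            moment_match_beta(0.95, 0.4)

    @given(mean=st.floats(0.05, 5000.0), se_frac=st.floats(0.01, 0.9))
    @settings(max_examples=50, deadline=None)
    def test_gamma_match_is_exact_for_any_inputs(self, mean, se_frac):
        shape, scale = moment_match_gamma(mean, se_frac * mean)
        assert shape * scale == pytest.approx(mean, rel=1e-9)
        assert np.sqrt(shape) * scale == pytest.approx(se_frac * mean, rel=1e-9)

    @given(mean=st.floats(0.02, 0.98), se_frac=st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_beta_match_is_exact_for_any_feasible_inputs(self, mean, se_frac):
        se = se_frac * np.sqrt(mean * (1 - mean))
        a, b = moment_match_beta(mean, se)
        assert a / (a + b) == pytest.approx(mean, rel=1e-9)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert np.sqrt(var) == pytest.approx(se, rel=1e-9)


class TestPSA:
    def test_reproducible_and_distinct_by_seed(self, occupancies, base_inputs):
        occ1, occ0 = occupancies

        def model(ov):
            r = evaluate(occ1, occ0, apply_overrides(base_inputs, ov))
            return r.inc_cost, r.inc_qalys

        a = run_psa(model, base_inputs, PSASpec(n_draws=40, seed=1))
        b = run_psa(model, base_inputs, PSASpec(n_draws=40, seed=1))
        c = run_psa(model, base_inputs, PSASpec(n_draws=40, seed=2))
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_gamma_draw_means_near_base(self, base_inputs):
        draws = draw_psa_parameters(base_inputs, PSASpec(n_draws=1000, seed=3))
        base = base_inputs.arm1.cost_pfs
        se = 0.2 * base
        assert abs(draws["arm1.cost_pfs"].mean() - base) < 3 * se / np.sqrt(1000)

    def test_mean_icer_matches_deterministic_on_linear_model(self, base_inputs):
        # ΔC and ΔE linear in the drawn parameters ⇒ PSA means converge on
        # the base case
        def linear_model(ov):
            d_cost = ov.get("arm1.cost_pfs", 904.48) - ov.get("arm0.cost_pfs", 774.54)
            d_eff = 0.3 * ov.get("u_pfs", 0.804) - 0.1 * ov.get("u_pd", 0.321)
            return 30 * d_cost, d_eff

        out = run_psa(linear_model, base_inputs, PSASpec(n_draws=1000, seed=4))
        det_cost, det_eff = linear_model({})
        assert out.attrs["mean_inc_cost"] == pytest.approx(det_cost, rel=0.05)
        assert out.attrs["mean_inc_qalys"] == pytest.approx(det_eff, rel=0.05)

    def test_ceac_equals_brute_force_count(self, occupancies, base_inputs):
        occ1, occ0 = occupancies

        def model(ov):
            r = evaluate(occ1, occ0, apply_overrides(base_inputs, ov))
            return r.inc_cost, r.inc_qalys

        draws = run_psa(model, base_inputs, PSASpec(n_draws=100, seed=5))
        curve = ceac(draws)
        for _, row in curve.iloc[::10].iterrows():
            lam = row["wtp_usd_per_qaly"]
            count = sum(
                1
                for dc, de in zip(draws["inc_cost"], draws["inc_qalys"])
                if lam * de - dc > 0
            )
            assert row["prob_cost_effective"] == pytest.approx(count / len(draws))

    def test_ceac_tiny_enumeration(self):
        draws = pd.DataFrame({"inc_cost": [1.0, 3.0], "inc_qalys": [1.0, 1.0]})
        out = ceac(draws, [0.0, 2.0, 10.0])
        assert out["prob_cost_effective"].tolist() == [0.0, 0.5, 1.0]

    def test_ceac_stable_across_seeds(self, occupancies, base_inputs):
        occ1, occ0 = occupancies

        def model(ov):
            r = evaluate(occ1, occ0, apply_overrides(base_inputs, ov))
            return r.inc_cost, r.inc_qalys

        c1 = ceac(run_psa(model, base_inputs, PSASpec(n_draws=1000, seed=10)))
        c2 = ceac(run_psa(model, base_inputs, PSASpec(n_draws=1000, seed=11)))
        gap = np.abs(c1["prob_cost_effective"] - c2["prob_cost_effective"])
        assert gap.max() < 0.05


class TestScenarios:
    def test_zero_cut_is_identity(self, occupancies, base_inputs):
        occ1, occ0 = occupancies
        base = evaluate(occ1, occ0, base_inputs)
        cut = scenario_price_reduction(occ1, occ0, base_inputs, 0.0)
        assert cut.inc_cost == base.inc_cost
        assert cut.icer == base.icer

    def test_icer_affine_in_cut_fraction(self, occupancies, base_inputs):
        occ1, occ0 = occupancies
        icers = [
            scenario_price_reduction(occ1, occ0, base_inputs, x).icer
            for x in (0.0, 0.2, 0.4, 0.6)
        ]
        steps = np.diff(icers)
        assert np.allclose(steps, steps[0], rtol=1e-9)

    def test_effects_untouched_by_price(self, occupancies, base_inputs):
        occ1, occ0 = occupancies
        base = evaluate(occ1, occ0, base_inputs)
        cut = scenario_price_reduction(occ1, occ0, base_inputs, 0.5)
        assert cut.inc_qalys == base.inc_qalys

    def test_utility_scenario_keeps_costs(self, occupancies, base_inputs):
        occ1, occ0 = occupancies
        base = evaluate(occ1, occ0, base_inputs)
        alt = scenario_utilities(occ1, occ0, base_inputs)
        assert (alt.cost1, alt.cost0) == (base.cost1, base.cost0)
        assert alt.inc_qalys != base.inc_qalys

    def test_equal_utilities_collapse_to_life_years(self, occupancies, base_inputs):
        occ1, occ0 = occupancies
        u = 0.6
        alt = scenario_utilities(occ1, occ0, base_inputs, u_pfs=u, u_pd=u)
        ly = scenario_utilities(occ1, occ0, base_inputs, u_pfs=1.0, u_pd=1.0)
        assert alt.qalys1 == pytest.approx(u * ly.qalys1, rel=1e-12)
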