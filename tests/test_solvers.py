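"""Break-even solvers, sweeps, ranking and sensitivity presets."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq

from pestbudget.economics import PriceModel, expected_net_revenue
from pestbudget.model_core import YieldModel
from pestbudget.solvers import (
    apply_preset,
    breakeven_outbreak_probability,
    breakeven_resistance_probability,
    probability_grid,
    rank_scenarios,
    round_half_up_percent,
    sensitivity_run,
    sweep,
)


def _with_price(config, price):
    return replace(config, price=PriceModel(price))


def _free_spray(config):
    ledger = replace(
        config.ledger,
        insecticide_costs={k: 0.0 for k in config.ledger.insecticide_costs},
        application_cost=0.0,
        scouting_cost=0.0,
    )
    return replace(config, ledger=ledger)


class TestBreakevenOutbreak:
    def test_wild_type_spray_threshold(self, config):
        result = breakeven_outbreak_probability("SHPN-W", "SHXN-W", config)
        oracle = (22.88 + 20.02) / (0.127 * 3537 * 0.33)
        assert result.crossing == pytest.approx(oracle, abs=1e-9)
        assert result.crossing_percent == 29
        assert result.favored_above == "SHPN-W"

    def test_threshold_at_high_price(self, config):
        result = breakeven_outbreak_probability("SHPN-W", "SHXN-W", _with_price(config, 0.52))
        assert result.crossing == pytest.approx(42.90 / (0.127 * 3537 * 0.52), abs=1e-9)

    def test_free_spraying_breaks_even_at_origin(self, config):
        result = breakeven_outbreak_probability("SHPN-W", "SHXN-W", _free_spray(config))
        assert result.crossing == pytest.approx(0.0, abs=1e-12)

    def test_parallel_lines_yield_no_crossing_with_diagnostic(self, config):
        # Both scenarios fully protected: E(R) constant in p_o, constant gap.
        result = breakeven_outbreak_probability("SHPN-W", "RCXN-W", config)
        assert result.crossing is None
        assert "parallel" in result.diagnostic
        assert result.favored_above == "RCXN-W"


class TestBreakevenResistance:
    def test_baseline_price_threshold(self, config):
        result = breakeven_resistance_probability("SHPN-I", "SHXN-I", config)
        oracle = 1.0 - (13.83 + 20.02) / (0.435 * 0.127 * 3537 * 0.33)
        assert result.crossing == pytest.approx(oracle, abs=1e-9)
        assert result.crossing_percent == 48
        assert result.favored_above == "SHXN-I"  # spraying loses above the crossing

    def test_average_price_threshold(self, config):
        result = breakeven_resistance_probability("SHPN-I", "SHXN-I", _with_price(config, 0.40))
        assert result.crossing == pytest.approx(
            1.0 - 33.85 / (0.435 * 0.127 * 3537 * 0.40), abs=1e-9
        )
        assert result.crossing_percent == 57

    def test_unprofitable_spraying_never_crosses(self, config):
        result = breakeven_resistance_probability("SHPN-I", "SHXN-I", _with_price(config, 0.05))
        assert result.crossing is None

    def test_closed_form_matches_bisection_on_random_configs(self, config):
        """500 randomized configs: exact crossing equals the brentq root."""
        rng = np.random.default_rng(20180401)
        checked = 0
        for i in range(500):
            ledger = replace(
                config.ledger,
                insecticide_costs={
                    "generic": rng.uniform(0, 60),
                    "3A": rng.uniform(0, 40),
                    "1B": rng.uniform(0, 60),
                    "4C": 61.78,
                },
                application_cost=rng.uniform(0, 40),
                scouting_cost=rng.uniform(0, 25),
            )
            randomized = replace(
                config,
                ledger=ledger,
                price=PriceModel(rng.uniform(0.05, 0.6)),
                yield_model=YieldModel(rng.uniform(2000, 5000), {"S": 0.873, "R": 1.0}),
            )
            if i % 2 == 0:
                result = breakeven_outbreak_probability("SHPN-W", "SHXN-W", randomized)

                def diff(x, cfg=randomized):
                    return expected_net_revenue("SHPN-W", cfg, p_outbreak=x) - (
                        expected_net_revenue("SHXN-W", cfg, p_outbreak=x)
                    )
            else:
                result = breakeven_resistance_probability("SHPN-I", "SHXN-I", randomized)

                def diff(x, cfg=randomized):
                    return expected_net_revenue("SHPN-I", cfg, p_resistant=x) - (
                        expected_net_revenue("SHXN-I", cfg, p_resistant=x)
                    )
            f0, f1 = diff(0.0), diff(1.0)
            if result.crossing is not None and f0 * f1 < 0:
                root = brentq(diff, 0.0, 1.0, xtol=1e-12)
                assert result.crossing == pytest.approx(root, abs=1e-9)
                checked += 1
        assert checked > 100  # the randomization actually exercises crossings

    def test_percent_rounding_is_half_up(self):
        assert round_half_up_percent(0.285) == 29
        assert round_half_up_percent(0.2849) == 28
        assert round_half_up_percent(0.475) == 48


class TestSweep:
    def test_default_grid_has_eleven_rows_per_scenario(self, config):
        grid = probability_grid(config.grid_step)
        assert grid == pytest.approx([0.1 * i for i in range(11)], abs=1e-12)
        frame = sweep(["SHXN-W", "RCXN-W"], "outbreak", grid, config)
        assert len(frame) == 22
        assert frame.groupby("scenario").size().eq(11).all()

    def test_rows_ordered_and_unmanaged_yield_at_certain_outbreak(self, config):
        frame = sweep(["SHXN-W", "SHPN-W"], "outbreak", probability_grid(0.1), config)
        assert frame.equals(frame.sort_values(["scenario", "axis_value"]).reset_index(drop=True))
        last = frame[(frame.scenario == "SHXN-W") & (frame.axis_value == 1.0)]
        assert last.expected_yield.iloc[0] == pytest.approx(3087.80, abs=0.005)

    def test_resistant_variety_revenue_constant_along_resistance_axis(self, config):
        frame = sweep(["RCXN-I"], "resistance", probability_grid(0.1), config)
        assert frame.expected_net_revenue.nunique() == 1

    def test_unmanaged_revenue_strictly_decreasing_in_outbreak(self, config):
        frame = sweep(["SHXN-W"], "outbreak", probability_grid(0.1), config)
        assert (np.diff(frame.expected_net_revenue) < 0).all()

    def test_revenue_columns_affine_along_axis(self, config):
        frame = sweep(
            ["SHXN-I", "SHPN-I", "SHPE-I", "RCXN-I"], "resistance", probability_grid(0.1), config
        )
        for _, group in frame.groupby("scenario"):
            second = np.diff(group.expected_net_revenue.to_numpy(), n=2)
            assert np.all(np.abs(second) < 1e-9)

    def test_invalid_grid_rejected(self, config):
        with pytest.raises(ValueError, match="outside"):
            sweep(["SHXN-W"], "outbreak", [0.0, 1.5], config)
        with pytest.raises(ValueError, match="axis"):
            sweep(["SHXN-W"], "sideways", [0.5], config)


class TestRanking:
    def test_case_study_order_at_high_risk_point(self, config):
        frame = rank_scenarios(
            ["SHXN-W", "SHPN-W", "SHPE-W", "RCXN-W"], config, p_outbreak=0.435
        )
        assert list(frame.scenario) == ["RCXN-W", "SHPN-W", "SHPE-W", "SHXN-W"]
        assert frame.expected_net_revenue.iloc[0] == pytest.approx(937.04, abs=1e-9)
        assert frame.expected_net_revenue.iloc[1] == pytest.approx(879.48, abs=1e-9)
        assert frame.expected_net_revenue.iloc[2] == pytest.approx(868.98, abs=1e-9)
        assert frame.expected_net_revenue.iloc[3] == pytest.approx(857.90, abs=0.005)

    def test_no_outbreak_risk_favors_no_management(self, config):
        frame = rank_scenarios(["SHXN-W", "SHPN-W"], config, p_outbreak=0.0)
        assert list(frame.scenario) == ["SHXN-W", "SHPN-W"]

    def test_ties_break_lexicographically(self, config):
        frame = rank_scenarios(
            ["SHPN-W", "SHXN-W", "SHPE-W"], _free_spray(config), p_outbreak=0.435
        )
        # all three fully tied on E(R) and E(C)? spraying still protects yield,
        # so only the spray scenarios tie with each other.
        sprayed = frame[frame.scenario.isin(["SHPN-W", "SHPE-W"])]
        assert list(sprayed.scenario) == ["SHPE-W", "SHPN-W"]


class TestSensitivity:
    def test_unknown_preset_lists_available(self, config):
        with pytest.raises(KeyError, match="yield_low"):
            apply_preset(config, "nonsense")

    def test_average_price_preset_reproduces_resistance_threshold(self, config):
        report = sensitivity_run(config, "price_avg")
        assert report["breakeven_resistance"].crossing == pytest.approx(0.5669, abs=5e-5)

    def test_input_cost_scaling_preset_scales_threshold(self, config):
        report = sensitivity_run(config, "input_scale_88")
        oracle = 42.90 * 0.88 / (0.127 * 3537 * 0.33)
        assert report["breakeven_outbreak"].crossing == pytest.approx(oracle, abs=1e-9)

    def test_threshold_direction_properties(self, config):
        baseline = breakeven_outbreak_probability("SHPN-W", "SHXN-W", config).crossing
        crossing = {
            name: sensitivity_run(config, name)["breakeven_outbreak"].crossing
            for name in ("yield_low", "yield_high", "price_avg", "price_high", "input_scale_88")
        }
        assert crossing["yield_low"] > baseline > crossing["yield_high"]
        assert baseline > crossing["price_avg"] > crossing["price_high"]
        assert crossing["input_scale_88"] < baseline

    def test_exactly_one_factor_modified(self, config):
        modified = apply_preset(config, "yield_high")
        assert modified.yield_model.attainable_yield == 4035.0
        assert modified.price == config.price
        assert modified.ledger == config.ledger
        modified = apply_preset(config, "price_high")
        assert modified.price.crop_price == 0.52
        assert modified.yield_model == config.yield_model
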