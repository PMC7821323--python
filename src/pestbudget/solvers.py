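"""Break-even solvers, probability sweeps, ranking and sensitivity analyses.

Expected net revenue is affine in the outbreak probability (for a pure
wild-type population) and in the resistant-class probability (at a fixed
outbreak probability), so the break-even point between two scenarios is the
exact root of a linear function — computed from evaluations at the axis
endpoints, never read off a grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CaseStudyConfig
from .economics import (
    apply_input_cost_scaling,
    apply_technology_fee,
    expected_cost,
    expected_net_revenue,
    scenario_point,
)
from .model_core import expected_yield
from .scenarios import ScenarioCode, default_spray_plan, parse_scenario

__all__ = [
    "BreakEvenResult",
    "SWEEP_COLUMNS",
    "round_half_up_percent",
    "breakeven_outbreak_probability",
    "breakeven_resistance_probability",
    "sweep",
    "probability_grid",
    "rank_scenarios",
    "apply_preset",
    "sensitivity_run",
]

SWEEP_COLUMNS = (
    "scenario",
    "axis",
    "axis_value",
    "expected_yield",
    "expected_cost",
    "expected_net_revenue",
)

_SLOPE_EPS = 1e-12


def round_half_up_percent(probability: float) -> int:
    """Probability to integer percent, ties rounded up (0.285 -> 29)."""
    from decimal import ROUND_HALF_UP, Decimal

    # go through repr to dodge binary artefacts like 0.285*100 = 28.499...
    scaled = Decimal(repr(float(probability))) * 100
    return int(scaled.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BreakEvenResult:
    """Crossing of two scenarios' expected net revenue along one axis."""

    scenario_a: ScenarioCode
    scenario_b: ScenarioCode
    axis: str  # "outbreak_probability" | "resistance_probability"
    crossing: float | None
    favored_above: str  # canonical code of the scenario with greater E(R) above the crossing
    diagnostic: str = ""

    @property
    def crossing_percent(self) -> int | None:
        if self.crossing is None:
            return None
        return round_half_up_percent(self.crossing)


def _affine_crossing(
    a: ScenarioCode,
    b: ScenarioCode,
    axis: str,
    difference: Callable[[float], float],
) -> BreakEvenResult:
    """Solve difference(x) = 0 for an affine difference on [0, 1]."""
    f0 = difference(0.0)
    f1 = difference(1.0)
    slope = f1 - f0
    if abs(slope) < _SLOPE_EPS:
        diag = (
            "identical revenue along the whole axis"
            if abs(f0) < 1e-9
            else f"parallel revenue lines (constant gap {f0:+.2f} USD/ha)"
        )
        favored = str(a) if f0 > 0 else str(b)
        return BreakEvenResult(a, b, axis, None, favored, diag)
    x = -f0 / slope
    favored = str(a) if slope > 0 else str(b)
    if 0.0 <= x <= 1.0:
        return BreakEvenResult(a, b, axis, x, favored)
    return BreakEvenResult(
        a, b, axis, None, str(a) if f0 > 0 else str(b),
        f"crossing at {x:.4f} lies outside [0, 1]",
    )


def breakeven_outbreak_probability(
    a: ScenarioCode | str,
    b: ScenarioCode | str,
    config: CaseStudyConfig,
) -> BreakEvenResult:
    """Outbreak probability at which scenarios a and b earn equal E(R)."""
    a, b = _as_code(a), _as_code(b)

    def diff(p_o: float) -> float:
        return expected_net_revenue(a, config, p_outbreak=p_o) - expected_net_revenue(
            b, config, p_outbreak=p_o
        )

    return _affine_crossing(a, b, "outbreak_probability", diff)


def breakeven_resistance_probability(
    a: ScenarioCode | str,
    b: ScenarioCode | str,
    config: CaseStudyConfig,
    p_outbreak: float | None = None,
) -> BreakEvenResult:
    """Resistant-class probability at which a and b earn equal E(R).

    The outbreak probability is held fixed (configured value by default) and
    the wild-type probability absorbs 1 - p_resistant; the cross-resistant
    class stays at its configured value (0 in the bundled preset).
    """
    a, b = _as_code(a), _as_code(b)

    def diff(p_s: float) -> float:
        kwargs = dict(p_outbreak=p_outbreak, p_resistant=p_s)
        return expected_net_revenue(a, config, **kwargs) - expected_net_revenue(
            b, config, **kwargs
        )

    return _affine_crossing(a, b, "resistance_probability", diff)


def _as_code(s: ScenarioCode | str) -> ScenarioCode:
    return s if isinstance(s, ScenarioCode) else parse_scenario(s)


def probability_grid(step: float) -> list[float]:
    """0 to 1 inclusive in increments of ``step`` (rounded to 10 decimals)."""
    n = int(round(1.0 / step))
    return [round(i * step, 10) for i in range(n)] + [1.0]


def sweep(
    scenarios: Iterable[ScenarioCode | str],
    axis: str,
    grid: Sequence[float],
    config: CaseStudyConfig,
    *,
    include_fixed: bool = False,
) -> pd.DataFrame:
    """Evaluate E(Y), E(C), E(R) for each scenario at each grid point.

    ``axis`` is ``"outbreak"`` (varying p_o, wild-type mix for -W scenarios)
    or ``"resistance"`` (varying p_resistant at the configured p_o). Rows are
    ordered by (scenario, axis_value).
    """
    if axis not in ("outbreak", "resistance"):
        raise ValueError(f"axis must be 'outbreak' or 'resistance', got {axis!r}")
    bad = [x for x in grid if not 0.0 <= x <= 1.0]
    if bad:
        raise ValueError(f"grid values outside [0, 1]: {bad}")
    rows = []
    codes = sorted((_as_code(s) for s in scenarios), key=str)
    for code in codes:
        plan = default_spray_plan(code, config)
        for x in grid:
            kwargs = (
                {"p_outbreak": float(x)} if axis == "outbreak" else {"p_resistant": float(x)}
            )
            outbreak, mix = scenario_point(code, config, **kwargs)
            ey = expected_yield(code, outbreak, mix, config.yield_model, plan)
            ec = expected_cost(code, config, include_fixed=include_fixed, plan=plan, **kwargs)
            rows.append((str(code), axis, float(x), ey, ec, ey * config.price.crop_price - ec))
    return pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))


def rank_scenarios(
    scenarios: Iterable[ScenarioCode | str],
    config: CaseStudyConfig,
    *,
    p_outbreak: float | None = None,
    p_resistant: float | None = None,
    include_fixed: bool = False,
) -> pd.DataFrame:
    """Scenarios ordered by descending E(R); ties by lower E(C), then code."""
    rows = []
    for code in (_as_code(s) for s in scenarios):
        kwargs = dict(p_outbreak=p_outbreak, p_resistant=p_resistant)
        er = expected_net_revenue(code, config, include_fixed=include_fixed, **kwargs)
        ec = expected_cost(code, config, include_fixed=include_fixed, **kwargs)
        rows.append((str(code), ec, er))
    frame = pd.DataFrame(rows, columns=["scenario", "expected_cost", "expected_net_revenue"])
    frame = frame.sort_values(
        by=["expected_net_revenue", "expected_cost", "scenario"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame


def apply_preset(config: CaseStudyConfig, preset: str) -> CaseStudyConfig:
    """Return the configuration with exactly one sensitivity factor changed."""
    from dataclasses import replace

    from .economics import PriceModel
    from .model_core import YieldModel

    try:
        body = config.sensitivity_presets[preset]
    except KeyError:
        raise KeyError(
            f"unknown sensitivity preset {preset!r}; available: "
            f"{sorted(config.sensitivity_presets)}"
        ) from None
    modified = config
    for key, value in body.items():
        if key == "attainable_yield":
            modified = replace(
                modified,
                yield_model=YieldModel(
                    float(value), dict(config.yield_model.retained_fraction_by_variety)
                ),
            )
        elif key == "crop_price":
            modified = replace(modified, price=PriceModel(float(value)))
        elif key == "technology_fee" and value:
            modified = apply_technology_fee(modified)
        elif key == "input_cost_scale":
            modified = apply_input_cost_scaling(modified, float(value))
        else:
            raise KeyError(f"preset {preset!r}: unknown modifier {key!r}")
    return modified


def sensitivity_run(config: CaseStudyConfig, preset: str) -> dict[str, Any]:
    """Recompute the headline break-even thresholds under one preset.

    The report carries the modified configuration, the wild-type spray
    threshold (SHPN-W vs SHXN-W over outbreak probability), the resistance
    thresholds against no management (SHPN-I and SHPE-I vs SHXN-I), the
    resistant-variety threshold (RCXN-W vs SHXN-W), and sweep tables over
    the default grid for both axes.
    """
    modified = apply_preset(config, preset)
    grid = probability_grid(modified.grid_step)
    wild = ["SHXN-W", "SHPN-W", "SHPE-W", "RCXN-W"]
    resistant = ["SHXN-I", "SHPN-I", "SHPE-I", "RCXN-I"]
    return {
        "preset": preset,
        "modifiers": dict(config.sensitivity_presets[preset]),
        "breakeven_outbreak": breakeven_outbreak_probability("SHPN-W", "SHXN-W", modified),
        "breakeven_resistant_variety": breakeven_outbreak_probability("RCXN-W", "SHXN-W", modified),
        "breakeven_resistance": breakeven_resistance_probability("SHPN-I", "SHXN-I", modified),
        "breakeven_resistance_rescue": breakeven_resistance_probability("SHPE-I", "SHXN-I", modified),
        "sweep_outbreak": sweep(wild, "outbreak", grid, modified),
        "sweep_resistance": sweep(resistant, "resistance", grid, modified),
        "config": modified,
    }
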