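"""Partial-budget economics: expected costs and expected net revenue.

Expected net revenue of a scenario is E(R) = E(Y) x E(P) - E(C), with yield
and crop price treated as independent. By default E(C) covers only the costs
that differ between scenarios (herbicide product, seed, insecticide product
and application, in-season scouting); the fixed production items common to
every scenario (tillage, herbicide application, planting, early-season
scouting, harvest, land rent) are tracked in the ledger and added when
``include_fixed=True``, so comparisons between scenarios are unaffected by
the convention.

Insecticide application counts are expectations over the outcome lottery: a
prophylactic first application always happens (it is calendar-based), a
threshold-based first application happens only in outbreak years, and a
rescue application happens when efficacy scouting reveals the first product
failed — i.e. with probability p_o times the probability mass of population
classes surviving the first product's mode-of-action group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Iterator, Mapping

import pandas as pd

from .model_core import OutbreakDistribution, PopulationMix
from .scenarios import ScenarioCode, SprayPlan, default_spray_plan, parse_scenario

if TYPE_CHECKING:  # pragma: no cover
    from .config import CaseStudyConfig

__all__ = [
    "CostItem",
    "CostLedger",
    "PriceModel",
    "scenario_point",
    "expected_application_count",
    "expected_scouting_activities",
    "cost_audit",
    "expected_cost",
    "expected_net_revenue",
    "technology_fee",
    "apply_technology_fee",
    "apply_input_cost_scaling",
]

AUDIT_COLUMNS = ("item", "trigger", "unit_cost", "expected_units", "expected_cost")


def _as_code(scenario: "ScenarioCode | str") -> ScenarioCode:
    return scenario if isinstance(scenario, ScenarioCode) else parse_scenario(scenario)



@dataclass(frozen=True)
class CostItem:
    """One ledger entry: a unit cost with its category and trigger."""

    name: str
    amount: float  # USD/ha or USD/activity depending on trigger
    category: str = "variable"  # "fixed" | "variable"
    trigger: str = "always"  # always | seed | herbicide_product | per_application | per_scouting_activity

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"cost item {self.name!r} has negative amount {self.amount!r}")
        if self.category not in ("fixed", "variable"):
            raise ValueError(f"cost item {self.name!r}: unknown category {self.category!r}")
        if self.trigger in ("seed", "herbicide_product") and self.category != "variable":
            raise ValueError(
                f"cost item {self.name!r}: trigger {self.trigger!r} must be variable"
            )


@dataclass(frozen=True)
class CostLedger:
    """Itemized 2018-USD/ha cost structure of the case study.

    ``seed_costs`` is keyed ``"<aphid trait>.<herbicide trait>"`` (e.g.
    ``"S.H"``), ``herbicide_costs`` by herbicide trait, ``insecticide_costs``
    by mode-of-action group (plus a ``"generic"`` all-products mean).
    """

    fixed_items: tuple[CostItem, ...]
    seed_costs: Mapping[str, float]
    herbicide_costs: Mapping[str, float]
    insecticide_costs: Mapping[str, float]
    application_cost: float  # USD per insecticide application
    scouting_cost: float  # USD per scouting activity
    early_scouting_count: int = 2
    monitoring_scouting_count: int = 6

    def __post_init__(self) -> None:
        for name, table in (
            ("seed_costs", self.seed_costs),
            ("herbicide_costs", self.herbicide_costs),
            ("insecticide_costs", self.insecticide_costs),
        ):
            for key, amount in table.items():
                if amount < 0:
                    raise ValueError(f"{name}[{key!r}] is negative: {amount!r}")
        if self.application_cost < 0 or self.scouting_cost < 0:
            raise ValueError("application and scouting costs must be non-negative")

    @property
    def fixed_total(self) -> float:
        return sum(item.amount for item in self.fixed_items)

    def scaled(self, factor: float) -> "CostLedger":
        """Every amount (fixed and variable) multiplied by ``factor``."""
        return CostLedger(
            fixed_items=tuple(replace(i, amount=i.amount * factor) for i in self.fixed_items),
            seed_costs={k: v * factor for k, v in self.seed_costs.items()},
            herbicide_costs={k: v * factor for k, v in self.herbicide_costs.items()},
            insecticide_costs={k: v * factor for k, v in self.insecticide_costs.items()},
            application_cost=self.application_cost * factor,
            scouting_cost=self.scouting_cost * factor,
            early_scouting_count=self.early_scouting_count,
            monitoring_scouting_count=self.monitoring_scouting_count,
        )


@dataclass(frozen=True)
class PriceModel:
    """Expected market price of the crop, USD/kg."""

    crop_price: float

    def __post_init__(self) -> None:
        if not self.crop_price > 0:
            raise ValueError(f"crop_price must be positive, got {self.crop_price!r}")


def scenario_point(
    scenario: ScenarioCode,
    config: "CaseStudyConfig",
    p_outbreak: float | None = None,
    p_resistant: float | None = None,
    p_cross_resistant: float | None = None,
) -> tuple[OutbreakDistribution, PopulationMix]:
    """Resolve the probability point a scenario is evaluated at.

    Wild-type (-W) scenarios pin the population mix to pure wild type; for
    resistant-pest (-I) scenarios the resistant/cross-resistant probabilities
    default to the configured mix and can be overridden axis-style, with
    ``p_wild`` absorbing the remainder.
    """
    scenario = _as_code(scenario)
    p_o = config.outbreak.p_outbreak if p_outbreak is None else p_outbreak
    outbreak = OutbreakDistribution.from_outbreak(p_o)
    profiles = config.population.resistance_profiles
    if scenario.pest_type == "W":
        mix = PopulationMix.wild_only(profiles)
    elif p_resistant is None and p_cross_resistant is None:
        mix = config.population
    else:
        p_s = config.population.p_resistant if p_resistant is None else p_resistant
        p_c = (
            config.population.p_cross_resistant
            if p_cross_resistant is None
            else p_cross_resistant
        )
        mix = PopulationMix(1.0 - p_s - p_c, p_s, p_c, profiles)
    return outbreak, mix


def _first_failure_probability(plan: SprayPlan, mix: PopulationMix) -> float:
    """P(first application fails | outbreak): mass of classes surviving it."""
    first = plan.first
    if first is None:
        return 0.0
    return sum(
        p_t
        for cls, p_t in mix.class_probabilities().items()
        if first.group in mix.resistance_profiles[cls]
    )


def _application_counts(
    scenario: ScenarioCode,
    plan: SprayPlan,
    outbreak: OutbreakDistribution,
    mix: PopulationMix,
) -> tuple[float, float]:
    """Expected (first, rescue) application counts."""
    if scenario.spray_policy == "X" or not plan.applications:
        return 0.0, 0.0
    first = 1.0 if scenario.spray_policy == "P" else outbreak.p_outbreak
    rescue = 0.0
    if plan.rescue_enabled and plan.rescue is not None:
        rescue = outbreak.p_outbreak * _first_failure_probability(plan, mix)
    return first, rescue


def expected_application_count(
    scenario: ScenarioCode,
    plan: SprayPlan,
    outbreak: OutbreakDistribution,
    mix: PopulationMix,
) -> float:
    """Expected number of insecticide applications (0 to 2)."""
    first, rescue = _application_counts(scenario, plan, outbreak, mix)
    return first + rescue


def expected_scouting_activities(
    scenario: ScenarioCode,
    plan: SprayPlan,
    outbreak: OutbreakDistribution,
    mix: PopulationMix,
    *,
    early_count: int = 2,
    monitoring_count: int = 6,
) -> float:
    """Expected scouting activities: early pair, plus monitoring or efficacy.

    Early-season scouting (weeds, stand, seedling disease) happens in every
    scenario. Monitoring adds a fixed six in-season visits; efficacy scouting
    adds one visit after the first application plus one more whenever a
    rescue application follows.
    """
    total = float(early_count)
    if scenario.scouting == "M":
        total += monitoring_count
    if scenario.scouting == "E" and plan.applications:
        total += 1.0 + outbreak.p_outbreak * _first_failure_probability(plan, mix)
    return total


def _audit_rows(
    scenario: ScenarioCode,
    config: "CaseStudyConfig",
    outbreak: OutbreakDistribution,
    mix: PopulationMix,
    plan: SprayPlan,
    include_fixed: bool,
) -> Iterator[tuple[str, str, float, float]]:
    ledger = config.ledger
    herb = scenario.variety_herbicide
    try:
        herb_cost = ledger.herbicide_costs[herb]
    except KeyError:
        raise KeyError(f"missing herbicide product cost for trait {herb!r}") from None
    yield (f"herbicide_product_{herb}", "herbicide_product", herb_cost, 1.0)

    seed_key = f"{scenario.variety_aphid}.{herb}"
    try:
        seed_cost = ledger.seed_costs[seed_key]
    except KeyError:
        raise KeyError(f"missing seed cost for variety combination {seed_key!r}") from None
    yield (f"seed_{seed_key}", "seed", seed_cost, 1.0)

    first_n, rescue_n = _application_counts(scenario, plan, outbreak, mix)
    if plan.first is not None and first_n > 0:
        yield (f"insecticide_{plan.first.group}", "per_application", plan.first.product_cost, first_n)
        yield ("insecticide_application", "per_application", ledger.application_cost, first_n)
    if plan.rescue is not None and rescue_n > 0:
        yield (f"insecticide_{plan.rescue.group}_rescue", "per_application", plan.rescue.product_cost, rescue_n)
        yield ("insecticide_application_rescue", "per_application", ledger.application_cost, rescue_n)

    in_season = expected_scouting_activities(
        scenario, plan, outbreak, mix,
        early_count=ledger.early_scouting_count,
        monitoring_count=ledger.monitoring_scouting_count,
    ) - ledger.early_scouting_count
    if in_season > 0:
        yield ("in_season_scouting", "per_scouting_activity", ledger.scouting_cost, in_season)

    if include_fixed:
        for item in ledger.fixed_items:
            yield (item.name, item.trigger, item.amount, 1.0)


def cost_audit(
    scenario: ScenarioCode,
    config: "CaseStudyConfig",
    *,
    include_fixed: bool = False,
    p_outbreak: float | None = None,
    p_resistant: float | None = None,
    p_cross_resistant: float | None = None,
    plan: SprayPlan | None = None,
) -> pd.DataFrame:
    """Per-item expected-cost breakdown.

    Columns: item, trigger, unit_cost, expected_units, expected_cost. The
    expected_cost column sums to :func:`expected_cost` at the same point.
    """
    scenario = _as_code(scenario)
    outbreak, mix = scenario_point(scenario, config, p_outbreak, p_resistant, p_cross_resistant)
    if plan is None:
        plan = default_spray_plan(scenario, config)
    rows = [
        (item, trigger, unit, units, unit * units)
        for item, trigger, unit, units in _audit_rows(
            scenario, config, outbreak, mix, plan, include_fixed
        )
    ]
    return pd.DataFrame(rows, columns=list(AUDIT_COLUMNS))


def expected_cost(
    scenario: ScenarioCode,
    config: "CaseStudyConfig",
    *,
    include_fixed: bool = False,
    p_outbreak: float | None = None,
    p_resistant: float | None = None,
    p_cross_resistant: float | None = None,
    plan: SprayPlan | None = None,
) -> float:
    """Expected cost E(C) in USD/ha (variable items only unless asked)."""
    scenario = _as_code(scenario)
    outbreak, mix = scenario_point(scenario, config, p_outbreak, p_resistant, p_cross_resistant)
    if plan is None:
        plan = default_spray_plan(scenario, config)
    return sum(
        unit * units
        for _, _, unit, units in _audit_rows(
            scenario, config, outbreak, mix, plan, include_fixed
        )
    )


def expected_net_revenue(
    scenario: ScenarioCode,
    config: "CaseStudyConfig",
    *,
    include_fixed: bool = False,
    p_outbreak: float | None = None,
    p_resistant: float | None = None,
    p_cross_resistant: float | None = None,
) -> float:
    """Expected net revenue E(R) = E(Y) x E(P) - E(C), USD/ha."""
    from .model_core import expected_yield

    scenario = _as_code(scenario)
    outbreak, mix = scenario_point(scenario, config, p_outbreak, p_resistant, p_cross_resistant)
    plan = default_spray_plan(scenario, config)
    ey = expected_yield(scenario, outbreak, mix, config.yield_model, plan)
    ec = expected_cost(
        scenario,
        config,
        include_fixed=include_fixed,
        p_outbreak=p_outbreak,
        p_resistant=p_resistant,
        p_cross_resistant=p_cross_resistant,
        plan=plan,
    )
    return ey * config.price.crop_price - ec


def technology_fee(config: "CaseStudyConfig") -> float:
    """Herbicide-tolerance seed premium: seed(S,H) minus seed(S,C)."""
    try:
        return config.ledger.seed_costs["S.H"] - config.ledger.seed_costs["S.C"]
    except KeyError as exc:
        raise KeyError(
            f"seed table must contain both 'S.H' and 'S.C' entries; missing {exc}"
        ) from None


def apply_technology_fee(config: "CaseStudyConfig") -> "CaseStudyConfig":
    """Price aphid-resistant seed as if it carried the tolerance tech fee.

    Adds the S.H minus S.C premium to the R.C seed cost; the input config is
    left untouched.
    """
    fee = technology_fee(config)
    seed = dict(config.ledger.seed_costs)
    if "R.C" not in seed:
        raise KeyError("seed table has no 'R.C' entry to apply the technology fee to")
    seed["R.C"] = seed["R.C"] + fee
    return replace(config, ledger=replace(config.ledger, seed_costs=seed))


def apply_input_cost_scaling(config: "CaseStudyConfig", factor: float) -> "CaseStudyConfig":
    """Scale every input cost by ``factor``; probabilities/yield/price untouched."""
    if not factor > 0:
        raise ValueError(f"cost scaling factor must be positive, got {factor!r}")
    return replace(config, ledger=config.ledger.scaled(factor))
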