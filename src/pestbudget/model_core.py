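"""Expected-yield model for pest-management scenarios under outbreak risk.

The season is modelled as a two-stage lottery. First, a pest outbreak either
occurs (probability ``p_o``) or not (``p_n = 1 - p_o``). Given an outbreak,
the pest population is one of three classes — wild-type, resistant to the
first-choice insecticide class, or additionally cross-resistant to the rescue
class — with conditional probabilities ``p_w``, ``p_s``, ``p_c`` summing to 1.

The fraction of attainable yield a farmer can expect is

    EY = p_n + p_o * sum_t p_t * f_t

where ``f_t`` is 1 when management is effective against class ``t`` and the
retained-on-damage fraction ``q`` of the variety when no management occurs or
management fails. Management is effective when the variety is host-plant
resistant, or when at least one applied insecticide belongs to a
mode-of-action group the realized population does not survive. Expected yield
in kg/ha is EY times the attainable yield.

Besides the closed-form evaluation, :func:`enumerate_outcomes` expands the
full outcome tree node by node; the probability-weighted mean of its yield
fractions must reproduce the closed form exactly, which the test suite uses
as a brute-force oracle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

from .scenarios import ScenarioCode, SprayPlan

__all__ = [
    "POPULATION_CLASSES",
    "ProbabilityError",
    "OutbreakDistribution",
    "PopulationMix",
    "YieldModel",
    "ManagementOutcome",
    "OutcomeNode",
    "management_effectiveness",
    "expected_yield_fraction",
    "expected_yield",
    "enumerate_outcomes",
]

#: Pest population classes conditional on an outbreak.
POPULATION_CLASSES = ("wild", "resistant", "cross_resistant")

_SUM_TOL = 1e-12


class ProbabilityError(ValueError):
    """A probability block violates bounds or its sum-to-one constraint."""


def _check_unit_interval(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ProbabilityError(f"{name} = {value!r} is outside [0, 1]")


@dataclass(frozen=True)
class OutbreakDistribution:
    """Season-level outbreak lottery: ``p_no_outbreak + p_outbreak = 1``."""

    p_no_outbreak: float
    p_outbreak: float

    def __post_init__(self) -> None:
        _check_unit_interval("p_no_outbreak", self.p_no_outbreak)
        _check_unit_interval("p_outbreak", self.p_outbreak)
        total = self.p_no_outbreak + self.p_outbreak
        if abs(total - 1.0) > _SUM_TOL:
            raise ProbabilityError(
                f"outbreak probabilities sum to {total!r}, expected 1 "
                "(p_no_outbreak + p_outbreak)"
            )

    @classmethod
    def from_outbreak(cls, p_outbreak: float) -> "OutbreakDistribution":
        return cls(1.0 - p_outbreak, p_outbreak)


@dataclass(frozen=True)
class PopulationMix:
    """Population-class probabilities conditional on an outbreak.

    ``resistance_profiles`` maps each class to the set of insecticide
    mode-of-action group codes that class survives; the wild type survives
    none, so any application controls it.
    """

    p_wild: float
    p_resistant: float
    p_cross_resistant: float
    resistance_profiles: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: DEFAULT_RESISTANCE_PROFILES
    )

    def __post_init__(self) -> None:
        _check_unit_interval("p_wild", self.p_wild)
        _check_unit_interval("p_resistant", self.p_resistant)
        _check_unit_interval("p_cross_resistant", self.p_cross_resistant)
        total = self.p_wild + self.p_resistant + self.p_cross_resistant
        if abs(total - 1.0) > _SUM_TOL:
            raise ProbabilityError(
                f"population-mix probabilities sum to {total!r}, expected 1 "
                "(p_wild + p_resistant + p_cross_resistant)"
            )
        missing = [c for c in POPULATION_CLASSES if c not in self.resistance_profiles]
        if missing:
            raise ProbabilityError(
                f"resistance profile missing for population class(es) {missing}"
            )

    @classmethod
    def wild_only(
        cls, profiles: Mapping[str, frozenset[str]] | None = None
    ) -> "PopulationMix":
        return cls(1.0, 0.0, 0.0, profiles or DEFAULT_RESISTANCE_PROFILES)

    def class_probabilities(self) -> dict[str, float]:
        return {
            "wild": self.p_wild,
            "resistant": self.p_resistant,
            "cross_resistant": self.p_cross_resistant,
        }


#: Case-study profiles: "resistant" survives pyrethroids (3A), "cross_resistant"
#: additionally survives organophosphates (1B). Nested by construction.
DEFAULT_RESISTANCE_PROFILES: Mapping[str, frozenset[str]] = {
    "wild": frozenset(),
    "resistant": frozenset({"3A"}),
    "cross_resistant": frozenset({"3A", "1B"}),
}


@dataclass(frozen=True)
class YieldModel:
    """Attainable yield plus the retained fraction ``q`` on unmanaged damage.

    ``q`` is indexed by the variety's aphid trait: susceptible varieties lose
    yield in an unmanaged/failed-management outbreak (case study: q = 0.873,
    a 12.7% loss), host-plant resistant varieties retain everything (q = 1).
    """

    attainable_yield: float  # kg/ha
    retained_fraction_by_variety: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.attainable_yield > 0:
            raise ValueError(
                f"attainable_yield must be positive, got {self.attainable_yield!r}"
            )
        for variety, q in self.retained_fraction_by_variety.items():
            if not 0.0 < q <= 1.0:
                raise ValueError(
                    f"retained fraction q for variety {variety!r} must lie in "
                    f"(0, 1], got {q!r}"
                )

    def retained_fraction(self, variety_aphid: str) -> float:
        try:
            return self.retained_fraction_by_variety[variety_aphid]
        except KeyError:
            raise KeyError(
                f"no retained fraction q configured for variety aphid trait "
                f"{variety_aphid!r}"
            ) from None


class ManagementOutcome(enum.Enum):
    """What management achieved against one realized population class."""

    NO_MANAGEMENT = "no_management"
    EFFECTIVE = "effective"
    INEFFECTIVE = "ineffective"


@dataclass(frozen=True)
class OutcomeNode:
    """One leaf of the season outcome tree."""

    label: str
    probability: float
    yield_fraction: float


def _applied_groups(
    scenario: ScenarioCode,
    plan: SprayPlan,
    population_class: str,
    profiles: Mapping[str, frozenset[str]],
) -> tuple[str, ...]:
    """Insecticide groups actually applied in an outbreak of this class.

    The first application is made whenever the plan holds one (prophylactic
    sprays are calendar-based; threshold sprays are triggered by the outbreak
    itself). The rescue fires only when efficacy scouting is part of the
    scenario and the realized class survives the first application's group.
    """
    if not plan.applications:
        return ()
    first = plan.applications[0]
    groups = [first.group]
    if (
        plan.rescue_enabled
        and plan.rescue is not None
        and scenario.scouting == "E"
        and first.group in profiles[population_class]
    ):
        groups.append(plan.rescue.group)
    return tuple(groups)


def management_effectiveness(
    scenario: ScenarioCode,
    plan: SprayPlan,
    population_class: str,
    profiles: Mapping[str, frozenset[str]],
) -> ManagementOutcome:
    """Classify the management result against one population class.

    Returns NO_MANAGEMENT when a susceptible variety receives no
    application, EFFECTIVE when the variety is aphid-resistant or at least
    one applied group is outside the class's survival set, INEFFECTIVE
    otherwise.
    """
    if population_class not in profiles:
        raise ValueError(
            f"unknown population class {population_class!r}; "
            f"expected one of {list(profiles)}"
        )
    if len(plan.applications) > 2:
        raise ValueError("at most two insecticide applications are supported")
    if scenario.variety_aphid == "R":
        return ManagementOutcome.EFFECTIVE
    groups = _applied_groups(scenario, plan, population_class, profiles)
    if not groups:
        return ManagementOutcome.NO_MANAGEMENT
    survives = profiles[population_class]
    if any(g not in survives for g in groups):
        return ManagementOutcome.EFFECTIVE
    return ManagementOutcome.INEFFECTIVE


def _class_yield_fraction(
    scenario: ScenarioCode,
    plan: SprayPlan,
    population_class: str,
    mix: PopulationMix,
    yields: YieldModel,
) -> float:
    outcome = management_effectiveness(
        scenario, plan, population_class, mix.resistance_profiles
    )
    if outcome is ManagementOutcome.EFFECTIVE:
        return 1.0
    return yields.retained_fraction(scenario.variety_aphid)


def expected_yield_fraction(
    scenario: ScenarioCode,
    outbreak: OutbreakDistribution,
    mix: PopulationMix,
    yields: YieldModel,
    plan: SprayPlan,
) -> float:
    """Expected fraction of attainable yield, EY = p_n + p_o * sum p_t f_t."""
    outbreak_term = sum(
        p_t * _class_yield_fraction(scenario, plan, cls, mix, yields)
        for cls, p_t in mix.class_probabilities().items()
    )
    return outbreak.p_no_outbreak + outbreak.p_outbreak * outbreak_term


def expected_yield(
    scenario: ScenarioCode,
    outbreak: OutbreakDistribution,
    mix: PopulationMix,
    yields: YieldModel,
    plan: SprayPlan,
) -> float:
    """Expected yield in kg/ha: EY fraction times attainable yield."""
    return (
        expected_yield_fraction(scenario, outbreak, mix, yields, plan)
        * yields.attainable_yield
    )


def enumerate_outcomes(
    scenario: ScenarioCode,
    outbreak: OutbreakDistribution,
    mix: PopulationMix,
    yields: YieldModel,
    plan: SprayPlan,
) -> list[OutcomeNode]:
    """Explicit outcome tree: one node per season realization.

    Nodes with zero probability are dropped, so the node probabilities always
    sum to 1 and the probability-weighted mean of ``yield_fraction`` equals
    :func:`expected_yield_fraction`.
    """
    nodes: list[OutcomeNode] = []
    if outbreak.p_no_outbreak > 0.0:
        nodes.append(OutcomeNode("no_outbreak", outbreak.p_no_outbreak, 1.0))
    for cls, p_t in mix.class_probabilities().items():
        p_node = outbreak.p_outbreak * p_t
        if p_node > 0.0:
            nodes.append(OutcomeNode(
                f"outbreak_{cls}",
                p_node,
                _class_yield_fraction(scenario, plan, cls, mix, yields),
            ))
    return nodes
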