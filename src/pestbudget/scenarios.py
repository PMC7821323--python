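"""Scenario-code algebra for five-component pest-management scenarios.

A management scenario is written as a five-letter code such as ``SHPE-I``,
one letter per decision component:

===  =======================  ================================================
pos  component                alphabet
===  =======================  ================================================
1    variety aphid trait      ``S`` susceptible, ``R`` aphid-resistant
2    variety herbicide trait  ``H`` herbicide-tolerant, ``C`` conventional
3    spray policy             ``X`` none, ``P`` prophylactic, ``T`` threshold
4    scouting                 ``N`` none, ``E`` efficacy, ``M`` monitoring
5    pest type                ``W`` wild-type, ``I`` insecticide-resistant
===  =======================  ================================================

``SHXN-W`` therefore reads: susceptible herbicide-tolerant variety, no
insecticide, no scouting, wild-type (insecticide-susceptible) pest.

Structural parsing is separated from rule validation: any code drawn from the
component alphabets parses, while combination rules (threshold spraying needs
monitoring, seed-trait availability, ...) are checked against a case-study
configuration by :func:`validate_scenario`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .config import CaseStudyConfig

__all__ = [
    "VARIETY_APHID",
    "VARIETY_HERBICIDE",
    "SPRAY_POLICY",
    "SCOUTING",
    "PEST_TYPE",
    "CASE_STUDY_SCENARIOS",
    "ScenarioCode",
    "ScenarioParseError",
    "Violation",
    "Application",
    "SprayPlan",
    "parse_scenario",
    "validate_scenario",
    "enumerate_scenarios",
    "default_spray_plan",
]

VARIETY_APHID = ("S", "R")
VARIETY_HERBICIDE = ("H", "C")
SPRAY_POLICY = ("X", "P", "T")
SCOUTING = ("N", "E", "M")
PEST_TYPE = ("W", "I")

#: The eight scenarios of the 2018 Iowa soybean-aphid case study.
CASE_STUDY_SCENARIOS = (
    "SHXN-W", "SHPN-W", "SHPE-W", "RCXN-W",
    "SHXN-I", "SHPN-I", "SHPE-I", "RCXN-I",
)

_COMPONENTS = (
    ("variety aphid trait", VARIETY_APHID),
    ("variety herbicide trait", VARIETY_HERBICIDE),
    ("spray policy", SPRAY_POLICY),
    ("scouting", SCOUTING),
    ("pest type", PEST_TYPE),
)

# Unicode hyphen/dash variants accepted on input; canonical form uses '-'.
_DASHES = "‐‑‒–—−"


class ScenarioParseError(ValueError):
    """Raised when a scenario code is structurally malformed."""


@dataclass(frozen=True, order=True)
class ScenarioCode:
    """One five-component management scenario."""

    variety_aphid: str
    variety_herbicide: str
    spray_policy: str
    scouting: str
    pest_type: str

    @property
    def canonical_string(self) -> str:
        """Canonical text form, hyphen before the pest type (``SHPE-I``)."""
        return (
            self.variety_aphid
            + self.variety_herbicide
            + self.spray_policy
            + self.scouting
            + "-"
            + self.pest_type
        )

    def __str__(self) -> str:
        return self.canonical_string


@dataclass(frozen=True)
class Violation:
    """One combination-rule violation (data, not an exception)."""

    rule: str
    message: str

    def __str__(self) -> str:
        return f"[{self.rule}] {self.message}"


@dataclass(frozen=True)
class Application:
    """One insecticide application: product group plus its per-hectare costs."""

    group: str  # IRAC mode-of-action code ("3A" pyrethroid, "1B" OP, ...) or "generic"
    product_cost: float  # USD/ha
    application_cost: float  # USD/ha


@dataclass(frozen=True)
class SprayPlan:
    """Ordered insecticide plan for a scenario; at most two applications.

    The second application, when present, is a rescue: it is made only after
    efficacy scouting finds that the first application failed to control the
    pest, so it fires conditionally on the realized population class.
    """

    applications: tuple[Application, ...] = ()
    rescue_enabled: bool = False

    def __post_init__(self) -> None:
        if len(self.applications) > 2:
            raise ValueError(
                "a spray plan holds at most two insecticide applications, "
                f"got {len(self.applications)}"
            )
        if self.rescue_enabled and len(self.applications) < 2:
            raise ValueError("rescue_enabled requires a second (rescue) application")

    @property
    def first(self) -> Application | None:
        return self.applications[0] if self.applications else None

    @property
    def rescue(self) -> Application | None:
        return self.applications[1] if len(self.applications) > 1 else None


def parse_scenario(code: str) -> ScenarioCode:
    """Parse a scenario code like ``"SHPE-I"`` (case-insensitive).

    Only structure is checked here; combination rules are the business of
    :func:`validate_scenario`.
    """
    raw = str(code).strip().upper()
    for dash in _DASHES:
        raw = raw.replace(dash, "-")
    if len(raw) != 6 or raw[4] != "-":
        raise ScenarioParseError(
            f"scenario code {code!r} must have the form 'XXXX-X' "
            "(four component letters, a hyphen, then the pest-type letter)"
        )
    letters = (raw[0], raw[1], raw[2], raw[3], raw[5])
    for position, (letter, (name, alphabet)) in enumerate(zip(letters, _COMPONENTS), 1):
        if letter not in alphabet:
            raise ScenarioParseError(
                f"scenario code {code!r}: component {position} ({name}) "
                f"letter {letter!r} not in {'/'.join(alphabet)}"
            )
    return ScenarioCode(*letters)


def validate_scenario(s: ScenarioCode, config: "CaseStudyConfig") -> list[Violation]:
    """Check combination rules; an empty list means the scenario is valid.

    Rules are data-driven where the underlying constraint is market
    availability (which seed trait combinations exist) rather than logic.
    """
    violations: list[Violation] = []
    if s.spray_policy == "T" and s.scouting != "M":
        violations.append(Violation(
            "T_REQUIRES_M",
            "threshold-based applications require in-season monitoring (M) "
            "to time the spray",
        ))
    if s.scouting == "E" and s.spray_policy == "X":
        violations.append(Violation(
            "E_REQUIRES_APPLICATION",
            "efficacy scouting only occurs after an insecticide application; "
            "spray policy X makes none",
        ))
    if (
        s.scouting == "M"
        and s.spray_policy != "T"
        and not config.grammar.allow_standalone_monitoring
    ):
        violations.append(Violation(
            "M_REQUIRES_T",
            "monitoring without threshold-based spraying is excluded from "
            "this configuration (allow_standalone_monitoring=false)",
        ))
    pair = f"{s.variety_aphid}.{s.variety_herbicide}"
    if pair not in config.availability:
        violations.append(Violation(
            "VARIETY_UNAVAILABLE",
            f"seed combining aphid trait {s.variety_aphid} with herbicide "
            f"trait {s.variety_herbicide} is not on the market in this "
            "configuration",
        ))
    return violations


def enumerate_scenarios(
    config: "CaseStudyConfig",
    pest_type: str | None = None,
) -> list[ScenarioCode]:
    """All valid scenarios under ``config``, lexicographic by canonical code.

    Optionally restrict to one pest type (``"W"`` or ``"I"``).
    """
    pests: Sequence[str] = PEST_TYPE if pest_type is None else (pest_type,)
    out = [
        s
        for combo in product(VARIETY_APHID, VARIETY_HERBICIDE, SPRAY_POLICY, SCOUTING, pests)
        if not validate_scenario(s := ScenarioCode(*combo), config)
    ]
    out.sort(key=lambda s: s.canonical_string)
    return out


def default_spray_plan(s: ScenarioCode, config: "CaseStudyConfig") -> SprayPlan:
    """Build the case-study spray plan for a valid scenario.

    Policy ``X`` yields an empty plan. Otherwise the first product is chosen
    by pest type (the cheapest effective class: a generic/mean-cost product
    for wild-type pests, a pyrethroid for the resistant-pest scenarios) and a
    rescue application with the configured fallback class (organophosphate by
    default) is attached when the scenario scouts for efficacy.
    """
    if s.spray_policy == "X":
        return SprayPlan()

    def _application(group: str) -> Application:
        try:
            product_cost = config.ledger.insecticide_costs[group]
        except KeyError:
            raise KeyError(
                f"no insecticide product cost configured for group {group!r} "
                f"(required by scenario {s})"
            ) from None
        return Application(group, product_cost, config.ledger.application_cost)

    apps = [_application(config.spray_first_group[s.pest_type])]
    rescue = s.scouting == "E"
    if rescue:
        apps.append(_application(config.spray_rescue_group))
    return SprayPlan(tuple(apps), rescue_enabled=rescue)
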