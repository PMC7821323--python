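"""Case-study configuration: schema, loading, saving and the bundled preset.

A configuration is a structured YAML document with blocks ``yield``,
``price``, ``probabilities``, ``costs``, ``spray``, ``availability``,
``grammar``, ``grid`` and ``sensitivity_presets``. The 2018 Iowa soybean-
aphid parameterization ships as the ``iowa_2018`` preset and is the default
everywhere. Validation is explicit rather than schema-library based: every
error names the offending field path, and probability-sum violations name
the block they occur in.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .economics import CostItem, CostLedger, PriceModel
from .model_core import (
    OutbreakDistribution,
    PopulationMix,
    ProbabilityError,
    YieldModel,
)

__all__ = [
    "SCHEMA_ID",
    "ConfigError",
    "GrammarFlags",
    "CaseStudyConfig",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
    "iowa_2018",
]

SCHEMA_ID = "pestbudget-config/1"


class ConfigError(ValueError):
    """Configuration is structurally or semantically invalid."""

    def __init__(self, field_path: str, message: str) -> None:
        super().__init__(f"{field_path}: {message}")
        self.field_path = field_path


@dataclass(frozen=True)
class GrammarFlags:
    """Widenings of the scenario grammar beyond the case-study preset."""

    allow_standalone_monitoring: bool = False


@dataclass(frozen=True)
class CaseStudyConfig:
    """Everything needed to evaluate scenarios: biology, prices, costs, rules."""

    yield_model: YieldModel
    price: PriceModel
    outbreak: OutbreakDistribution
    population: PopulationMix
    ledger: CostLedger
    availability: frozenset[str]  # allowed "<aphid>.<herbicide>" seed pairs
    spray_first_group: Mapping[str, str]  # pest type -> first-choice group
    spray_rescue_group: str
    grammar: GrammarFlags = GrammarFlags()
    grid_step: float = 0.1
    sensitivity_presets: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)
    metadata: Mapping[str, Any] = field(default_factory=dict)


def _require(mapping: Mapping[str, Any], key: str, path: str) -> Any:
    if not isinstance(mapping, Mapping):
        raise ConfigError(path.rsplit(".", 1)[0] or path, "expected a mapping block")
    if key not in mapping:
        raise ConfigError(path, "required field is missing")
    return mapping[key]


def _number(value: Any, path: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(path, f"expected a number, got {value!r}")
    return float(value)


def config_from_dict(doc: Mapping[str, Any]) -> CaseStudyConfig:
    """Build and validate a configuration from a parsed YAML/JSON document."""
    if not isinstance(doc, Mapping):
        raise ConfigError("<root>", "configuration document must be a mapping")
    schema = doc.get("schema", SCHEMA_ID)
    if schema != SCHEMA_ID:
        raise ConfigError("schema", f"expected {SCHEMA_ID!r}, got {schema!r}")

    yblock = _require(doc, "yield", "yield")
    try:
        yield_model = YieldModel(
            attainable_yield=_number(_require(yblock, "attainable", "yield.attainable"), "yield.attainable"),
            retained_fraction_by_variety={
                str(k): _number(v, f"yield.retained_fraction.{k}")
                for k, v in _require(yblock, "retained_fraction", "yield.retained_fraction").items()
            },
        )
    except ValueError as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError("yield", str(exc)) from None

    pblock = _require(doc, "price", "price")
    try:
        price = PriceModel(_number(_require(pblock, "crop_price", "price.crop_price"), "price.crop_price"))
    except ValueError as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError("price", str(exc)) from None

    prob = _require(doc, "probabilities", "probabilities")
    try:
        outbreak = OutbreakDistribution.from_outbreak(
            _number(_require(prob, "outbreak", "probabilities.outbreak"), "probabilities.outbreak")
        )
    except ProbabilityError as exc:
        raise ConfigError("probabilities.outbreak", str(exc)) from None
    pop = _require(prob, "population", "probabilities.population")
    profiles_raw = _require(prob, "resistance_profiles", "probabilities.resistance_profiles")
    profiles = {str(k): frozenset(str(g) for g in v) for k, v in profiles_raw.items()}
    try:
        population = PopulationMix(
            p_wild=_number(_require(pop, "wild", "probabilities.population.wild"), "probabilities.population.wild"),
            p_resistant=_number(_require(pop, "resistant", "probabilities.population.resistant"), "probabilities.population.resistant"),
            p_cross_resistant=_number(
                _require(pop, "cross_resistant", "probabilities.population.cross_resistant"),
                "probabilities.population.cross_resistant",
            ),
            resistance_profiles=profiles,
        )
    except ProbabilityError as exc:
        raise ConfigError("probabilities.population", str(exc)) from None

    costs = _require(doc, "costs", "costs")
    try:
        ledger = CostLedger(
            fixed_items=tuple(
                CostItem(
                    name=str(_require(item, "name", f"costs.fixed[{i}].name")),
                    amount=_number(_require(item, "amount", f"costs.fixed[{i}].amount"), f"costs.fixed[{i}].amount"),
                    category="fixed",
                    trigger="always",
                )
                for i, item in enumerate(_require(costs, "fixed", "costs.fixed"))
            ),
            seed_costs={str(k): _number(v, f"costs.seed.{k}") for k, v in _require(costs, "seed", "costs.seed").items()},
            herbicide_costs={
                str(k): _number(v, f"costs.herbicide.{k}")
                for k, v in _require(costs, "herbicide", "costs.herbicide").items()
            },
            insecticide_costs={
                str(k): _number(v, f"costs.insecticide.{k}")
                for k, v in _require(costs, "insecticide", "costs.insecticide").items()
            },
            application_cost=_number(_require(costs, "application", "costs.application"), "costs.application"),
            scouting_cost=_number(_require(costs, "scouting_activity", "costs.scouting_activity"), "costs.scouting_activity"),
            early_scouting_count=int(_require(costs, "scouting_counts", "costs.scouting_counts")["early"]),
            monitoring_scouting_count=int(costs["scouting_counts"]["monitoring"]),
        )
    except ConfigError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError("costs", str(exc)) from None

    spray = _require(doc, "spray", "spray")
    spray_first = {
        str(k): str(v)
        for k, v in _require(spray, "first_group_by_pest", "spray.first_group_by_pest").items()
    }
    rescue_group = str(_require(spray, "rescue_group", "spray.rescue_group"))
    for pest, group in spray_first.items():
        if group not in ledger.insecticide_costs:
            raise ConfigError(
                f"spray.first_group_by_pest.{pest}",
                f"group {group!r} has no entry in costs.insecticide",
            )
    if rescue_group not in ledger.insecticide_costs:
        raise ConfigError("spray.rescue_group", f"group {rescue_group!r} has no entry in costs.insecticide")

    avail = _require(doc, "availability", "availability")
    availability = frozenset(str(p) for p in _require(avail, "varieties", "availability.varieties"))
    for pair in sorted(availability):
        if pair not in ledger.seed_costs:
            raise ConfigError("availability.varieties", f"pair {pair!r} has no entry in costs.seed")

    grammar_block = doc.get("grammar", {})
    grammar = GrammarFlags(
        allow_standalone_monitoring=bool(grammar_block.get("allow_standalone_monitoring", False))
    )

    grid_step = _number(doc.get("grid", {}).get("step", 0.1), "grid.step")
    if not 0 < grid_step <= 1:
        raise ConfigError("grid.step", f"must lie in (0, 1], got {grid_step!r}")

    presets = {
        str(name): {str(k): v for k, v in body.items()}
        for name, body in doc.get("sensitivity_presets", {}).items()
    }

    return CaseStudyConfig(
        yield_model=yield_model,
        price=price,
        outbreak=outbreak,
        population=population,
        ledger=ledger,
        availability=availability,
        spray_first_group=spray_first,
        spray_rescue_group=rescue_group,
        grammar=grammar,
        grid_step=grid_step,
        sensitivity_presets=presets,
        metadata=dict(doc.get("metadata", {})),
    )


def config_to_dict(config: CaseStudyConfig) -> dict[str, Any]:
    """Serializable document; ``config_from_dict`` round-trips it exactly."""
    return {
        "schema": SCHEMA_ID,
        "metadata": dict(config.metadata),
        "yield": {
            "attainable": config.yield_model.attainable_yield,
            "retained_fraction": dict(config.yield_model.retained_fraction_by_variety),
        },
        "price": {"crop_price": config.price.crop_price},
        "probabilities": {
            "outbreak": config.outbreak.p_outbreak,
            "population": {
                "wild": config.population.p_wild,
                "resistant": config.population.p_resistant,
                "cross_resistant": config.population.p_cross_resistant,
            },
            "resistance_profiles": {
                cls: sorted(groups)
                for cls, groups in config.population.resistance_profiles.items()
            },
        },
        "costs": {
            "fixed": [{"name": i.name, "amount": i.amount} for i in config.ledger.fixed_items],
            "seed": dict(config.ledger.seed_costs),
            "herbicide": dict(config.ledger.herbicide_costs),
            "insecticide": dict(config.ledger.insecticide_costs),
            "application": config.ledger.application_cost,
            "scouting_activity": config.ledger.scouting_cost,
            "scouting_counts": {
                "early": config.ledger.early_scouting_count,
                "monitoring": config.ledger.monitoring_scouting_count,
            },
        },
        "spray": {
            "first_group_by_pest": dict(config.spray_first_group),
            "rescue_group": config.spray_rescue_group,
        },
        "availability": {"varieties": sorted(config.availability)},
        "grammar": {"allow_standalone_monitoring": config.grammar.allow_standalone_monitoring},
        "grid": {"step": config.grid_step},
        "sensitivity_presets": {k: dict(v) for k, v in config.sensitivity_presets.items()},
    }


def load_config(path: str | Path) -> CaseStudyConfig:
    """Load and validate a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc)


def save_config(config: CaseStudyConfig, path: str | Path) -> None:
    """Write a configuration to YAML; ``load_config`` recovers it exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def iowa_2018() -> CaseStudyConfig:
    """The bundled 2018 Iowa soybean-aphid case-study configuration."""
    text = importlib.resources.files("pestbudget").joinpath("data/iowa_2018.yaml").read_text("utf-8")
    return config_from_dict(yaml.safe_load(text))
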