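"""Scenario analysis: structured variations of the base-case model.

The published grid varies the HAQ-DI → utility mapping, the simulation
horizon (5–40 years), the annual discount rate (0–5%), the cohort starting
age (56 ± 5 years), a simplified treatment sequence (first-line failures go
straight to supportive care), and removal of non-pharmacological
supportive-care costs.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import pandas as pd

from .engine import LifeTable, run_cohort
from .outcomes import StrategyResult, icer
from .parameters import ConfigError, ModelConfig, UtilityMapping

logger = logging.getLogger("biosimce")

#: Fields a scenario may override.
ALLOWED_OVERRIDES = (
    "utility_mapping",
    "horizon_years",
    "annual_discount_rate",
    "baseline_age",
    "simplified",
    "include_nonpharma",
)


@dataclass
class ScenarioSpec:
    """A labelled set of overrides applied on top of the base configuration."""

    label: str
    overrides: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        for key in self.overrides:
            if key not in ALLOWED_OVERRIDES:
                raise ConfigError(
                    f"scenario[{self.label}].{key}",
                    f"not an overridable field (allowed: {ALLOWED_OVERRIDES})",
                )


def apply_scenario(config: ModelConfig, spec: ScenarioSpec) -> ModelConfig:
    """Deep-copy the config and apply one scenario's overrides."""
    spec.validate()
    cfg = copy.deepcopy(config)
    ov = spec.overrides

    if "utility_mapping" in ov:
        m = ov["utility_mapping"]
        if isinstance(m, Mapping):
            m = UtilityMapping(
                intercept=float(m["intercept"]),
                slope=float(m["slope"]),
                label=m.get("label", "scenario"),
            )
        cfg.economics.utility_mapping = m
    if "horizon_years" in ov:
        cfg.economics.horizon_years = float(ov["horizon_years"])
    if "annual_discount_rate" in ov:
        cfg.economics.annual_discount_rate = float(ov["annual_discount_rate"])
    if "baseline_age" in ov:
        cfg.population.baseline_age = float(ov["baseline_age"])
    if ov.get("simplified"):
        cfg.strategies = [
            replace(s, subsequent_lines=[], simplified=True) for s in cfg.strategies
        ]
    if "include_nonpharma" in ov:
        for s in cfg.strategies:
            s.supportive_care.include_nonpharma = bool(ov["include_nonpharma"])

    cfg.validate()
    return cfg


def default_scenario_grid(config: ModelConfig) -> list[ScenarioSpec]:
    """The published scenario grid, built from the base configuration."""
    specs: list[ScenarioSpec] = []
    for m in config.alt_utility_mappings:
        specs.append(
            ScenarioSpec(f"utility mapping: {m.label}", {"utility_mapping": m})
        )
    for years in (5, 10, 20, 30, 40):
        specs.append(ScenarioSpec(f"horizon {years} y", {"horizon_years": years}))
    for rate in (0.0, 0.05):
        specs.append(
            ScenarioSpec(f"discount {rate:.0%}", {"annual_discount_rate": rate})
        )
    base_age = config.population.baseline_age
    for age in (base_age - 5, base_age + 5):
        specs.append(ScenarioSpec(f"baseline age {age:g}", {"baseline_age": age}))
    specs.append(ScenarioSpec("simplified sequence", {"simplified": True}))
    specs.append(
        ScenarioSpec("no nonpharmacological costs", {"include_nonpharma": False})
    )
    return specs


def run_scenarios(
    config: ModelConfig,
    life_table: LifeTable,
    specs: Sequence[ScenarioSpec] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Evaluate the base case (scenario 0) plus each scenario.

    Returns (table, errors); an invalid scenario is reported in ``errors``
    and does not stop the remaining scenarios.  The table holds one row per
    scenario × strategy with net and incremental outcomes vs the reference.
    """
    all_specs = [ScenarioSpec("base case", {})] + (
        list(specs) if specs is not None else default_scenario_grid(config)
    )
    rows = []
    errors: list[tuple[str, str]] = []
    for k, spec in enumerate(all_specs):
        try:
            cfg = apply_scenario(config, spec)
        except ConfigError as exc:
            logger.warning("scenario %r invalid: %s", spec.label, exc)
            errors.append((spec.label, str(exc)))
            continue
        results = {
            s.label: StrategyResult.from_trace(
                run_cohort(s, cfg.economics, cfg.population, life_table)
            )
            for s in cfg.strategies
        }
        ref = results[cfg.reference_label]
        for label, res in results.items():
            row = {
                "scenario_index": k,
                "scenario": spec.label,
                "strategy": label,
                "cost": res.cost,
                "qaly": res.qaly,
            }
            if label != cfg.reference_label:
                cmp = icer(res, ref, cfg.economics)
                row.update(
                    {
                        "delta_cost": cmp.delta_cost,
                        "delta_qaly": cmp.delta_qaly,
                        "icer": cmp.icer,
                        "dominance": cmp.dominance,
                        "cost_effective_at_wtp": cmp.cost_effective_at_wtp,
                    }
                )
            rows.append(row)
    return pd.DataFrame(rows), errors
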