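"""Shared fixtures: the bundled base case, life tables, and small synthetic
model configurations for oracle comparisons."""

from __future__ import annotations

import copy

import numpy as np
import pytest

from biosimce import (
    AcrResponse,
    DistributionSpec,
    EconomicSettings,
    LifeTable,
    Param,
    PopulationProfile,
    StrategyResult,
    StrategySpec,
    SupportiveCareParams,
    TreatmentLineParams,
    load_base_case,
    load_synthetic_life_table,
    run_cohort,
)


@pytest.fixture(scope="session")
def base_config():
    return load_base_case()


@pytest.fixture(scope="session")
def life_table():
    return load_synthetic_life_table()


@pytest.fixture(scope="session")
def zero_life_table():
    return LifeTable.zero()


@pytest.fixture(scope="session")
def base_results(base_config, life_table):
    return {
        s.label: StrategyResult.from_trace(
            run_cohort(s, base_config.economics, base_config.population, life_table)
        )
        for s in base_config.strategies
    }


@pytest.fixture()
def config(base_config):
    """A mutable per-test copy of the base configuration."""
    return copy.deepcopy(base_config)


def fixed(name: str, value: float) -> Param:
    return Param(name, value, DistributionSpec("fixed"))


def make_line(
    name: str,
    cost: float = 500.0,
    cost_first: float | None = None,
    disc: float = 0.2,
    acr: tuple[float, float, float] | None = None,
    haq_cat: tuple[float, float, float, float] | None = None,
    haq_mean: float | None = None,
    is_tnfi: bool = False,
) -> TreatmentLineParams:
    """Small fully-fixed treatment line for oracle tests."""
    kwargs: dict = {}
    if acr is not None:
        kwargs["acr_response"] = AcrResponse(f"{name}.acr", *acr)
        cats = haq_cat or (-0.16, -0.45, -0.70, -1.02)
        kwargs["haq_change_by_category"] = {
            c: fixed(f"{name}.haq.{c}", v)
            for c, v in zip(("lt20", "acr20_50", "acr50_70", "ge70"), cats)
        }
    if haq_mean is not None:
        kwargs["haq_change_mean"] = fixed(f"{name}.haq_mean", haq_mean)
    return TreatmentLineParams(
        name=name,
        is_tnfi=is_tnfi,
        drug_cost_first_cycle=fixed(f"{name}.cf", cost_first if cost_first is not None else cost),
        drug_cost_subsequent=fixed(f"{name}.cs", cost),
        discontinuation_prob=fixed(f"{name}.disc", disc),
        **kwargs,
    )


def make_supportive(
    drug: float = 200.0,
    steroid: float = 300.0,
    physio: float = 2000.0,
    deltas: tuple[float, float, float] = (-0.04, 0.2, 0.28),
    include_nonpharma: bool = True,
) -> SupportiveCareParams:
    return SupportiveCareParams(
        drug_cost_per_cycle=fixed("sc.drug", drug),
        steroid_injection_cost=fixed("sc.steroid", steroid),
        physiotherapy_cost_per_cycle=fixed("sc.physio", physio),
        haq_delta_cycle1=deltas[0],
        haq_delta_cycle2=deltas[1],
        haq_delta_later=deltas[2],
        include_nonpharma=include_nonpharma,
    )


def make_strategy(
    label: str = "test",
    acr: tuple[float, float, float] = (0.7, 0.4, 0.2),
    disc: float = 0.2,
    n_subsequent: int = 2,
    **line_kwargs,
) -> StrategySpec:
    first = make_line(f"{label}.first", cost=800.0, disc=disc, acr=acr, **line_kwargs)
    subs = [
        make_line(f"{label}.line{j}", cost=600.0 + 100 * j, disc=0.25, haq_mean=-0.3)
        for j in range(1, n_subsequent + 1)
    ]
    return StrategySpec(
        label=label,
        first_line=first,
        subsequent_lines=subs,
        supportive_care=make_supportive(),
    )


def make_random_strategy(rng: np.random.Generator, label: str) -> StrategySpec:
    """A random small but structurally complete strategy."""
    c70 = rng.uniform(0.05, 0.3)
    c50 = c70 + rng.uniform(0.05, 0.3)
    c20 = min(c50 + rng.uniform(0.05, 0.35), 0.95)
    first = make_line(
        f"{label}.first",
        cost=float(rng.uniform(200, 2000)),
        cost_first=float(rng.uniform(200, 3000)),
        disc=float(rng.uniform(0.05, 0.4)),
        acr=(c20, c50, c70),
        haq_cat=tuple(-rng.uniform(0.05, 1.2, size=4)),
    )
    subs = [
        make_line(
            f"{label}.line{j}",
            cost=float(rng.uniform(300, 5000)),
            disc=float(rng.uniform(0.1, 0.4)),
            haq_mean=float(-rng.uniform(0.1, 0.6)),
        )
        for j in (1, 2)
    ]
    sc = make_supportive(
        drug=float(rng.uniform(100, 600)),
        steroid=float(rng.uniform(100, 500)),
        physio=float(rng.uniform(500, 3000)),
    )
    return StrategySpec(
        label=label, first_line=first, subsequent_lines=subs, supportive_care=sc
    )


def small_population(haq: float = 1.6, age: float = 56.0) -> PopulationProfile:
    return PopulationProfile(
        baseline_age=age, baseline_haq=fixed("pop.haq", haq)
    )


def short_settings(horizon: float = 10.0, rate: float = 0.035) -> EconomicSettings:
    return EconomicSettings(horizon_years=horizon, annual_discount_rate=rate)
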