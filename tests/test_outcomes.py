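"""Outcomes: utility mapping, discounting, accrual, ICER/dominance, NMB."""

from __future__ import annotations

import copy

import pandas as pd
import pytest

from biosimce import (
    EconomicSettings,
    StrategyResult,
    TraceSlot,
    accrue_cycle,
    base_case_table,
    discount_factor,
    icer,
    nmb,
    price_reduction,
    run_cohort,
    utility_from_haq,
)
from biosimce.engine import build_state_space, state_cost_components


def result(label: str, cost: float, qaly: float) -> StrategyResult:
    return StrategyResult(
        label=label, cost=cost, qaly=qaly, cost_drug=cost, cost_ae=0.0,
        cost_nonpharma=0.0, cost_undiscounted=cost, qaly_undiscounted=qaly,
        life_years=0.0,
    )


# Published base-case totals (Table-2 style net values) used as desk inputs.
LEF = result("Leflunomide", 154_632.0, 14.82)
IFX = result("Biosimilar infliximab", 152_326.0, 15.35)
ADA = result("Biosimilar adalimumab", 145_419.0, 15.55)
SETTINGS = EconomicSettings()


@pytest.mark.parametrize("haq, expected", [(0.0, 0.74), (1.6, 0.468), (3.0, 0.23)])
def test_utility_linear_mapping(haq, expected):
    assert utility_from_haq(haq) == pytest.approx(expected)


def test_discount_factor():
    s = EconomicSettings()
    assert discount_factor(0, s) == 1.0
    assert discount_factor(2, s) == pytest.approx(1 / 1.035)
    flat = EconomicSettings(annual_discount_rate=0.0)
    assert all(discount_factor(t, flat) == 1.0 for t in range(50))


class TestAccrual:
    def test_loading_dose_in_entry_cycle(self, base_config):
        """Infliximab bills the loading-dose price only in a line's first cycle."""
        strat = base_config.strategy("Biosimilar infliximab")
        space = build_state_space(strat, 1.6)
        by_label = {s.label: s for s in space.states}
        drug_entry, _, _ = state_cost_components(by_label["line0:entry"], strat)
        drug_on, _, _ = state_cost_components(by_label["line0:on:acr20_50"], strat)
        assert drug_entry == 2792.0
        assert drug_on == 1654.0

    def test_expected_adverse_event_cost(self, base_config):
        """Pneumonia 0.74% x US$4983 contributes US$36.87 per cycle."""
        line = base_config.strategy("Biosimilar infliximab").first_line
        contrib = line.ae_probs["pneumonia"].value * line.ae_costs["pneumonia"].value
        assert contrib == pytest.approx(36.87, abs=0.01)
        assert line.expected_ae_cost() >= contrib

    def test_steroid_cost_limited_to_first_two_sc_cycles(self, base_config):
        strat = base_config.strategies[0]
        space = build_state_space(strat, 1.6)
        sc_states = [s for s in space.states if s.kind == "sc"]
        nonpharma = [state_cost_components(s, strat)[2] for s in sc_states]
        steroid = strat.supportive_care.steroid_injection_cost.value
        assert nonpharma[0] - nonpharma[2] == pytest.approx(steroid)
        assert nonpharma[1] - nonpharma[2] == pytest.approx(steroid)
        assert len(set(round(c, 9) for c in nonpharma[2:])) == 1

    def test_full_occupancy_qaly_half_year(self):
        slot = TraceSlot(
            occupancy=1.0, haq=1.6, cycle_index=0, drug_cost=0.0, ae_expected_cost=0.0
        )
        cost, qaly = accrue_cycle(slot, EconomicSettings())
        assert qaly == pytest.approx(0.234)
        assert cost == 0.0

    def test_negative_cost_rejected(self):
        slot = TraceSlot(1.0, 1.0, 0, drug_cost=-5.0, ae_expected_cost=0.0)
        with pytest.raises(ValueError, match="negative"):
            accrue_cycle(slot, EconomicSettings())


class TestIcer:
    def test_published_infliximab_comparison(self):
        cmp = icer(IFX, LEF, SETTINGS)
        assert cmp.delta_cost == pytest.approx(-2306)
        assert round(cmp.delta_qaly, 2) == pytest.approx(0.53)
        assert round(cmp.icer) == -4351
        assert cmp.dominance == "dominant"

    def test_published_adalimumab_comparison(self):
        cmp = icer(ADA, LEF, SETTINGS)
        assert cmp.delta_cost == pytest.approx(-9213)
        assert round(cmp.delta_qaly, 2) == pytest.approx(0.73)
        assert round(cmp.icer) == -12_621
        assert cmp.dominance == "dominant"

    def test_identical_strategies_undefined_icer(self):
        cmp = icer(LEF, LEF, SETTINGS)
        assert cmp.delta_cost == 0.0 and cmp.delta_qaly == 0.0
        assert cmp.icer is None
        assert cmp.dominance == "trade-off"

    def test_antisymmetry(self):
        ab = icer(IFX, LEF, SETTINGS)
        ba = icer(LEF, IFX, SETTINGS)
        assert ab.delta_cost == -ba.delta_cost
        assert ab.delta_qaly == -ba.delta_qaly

    def test_dominated_classification(self):
        worse = result("worse", 200_000.0, 10.0)
        assert icer(worse, LEF, SETTINGS).dominance == "dominated"


class TestNmb:
    def test_zero_wtp_is_negative_cost(self):
        assert nmb(LEF, 0.0) == -LEF.cost

    def test_published_value(self):
        assert nmb(ADA, 48_555.0) == pytest.approx(609_611.25)

    def test_ranking_at_published_threshold(self):
        order = sorted([LEF, IFX, ADA], key=lambda r: nmb(r, 48_555.0), reverse=True)
        assert [r.label for r in order] == [
            "Biosimilar adalimumab",
            "Biosimilar infliximab",
            "Leflunomide",
        ]


@pytest.mark.parametrize(
    "bio, orig, expected", [(940, 7073, 87), (1654, 3609, 54), (500, 500, 0)]
)
def test_price_reduction(bio, orig, expected):
    assert price_reduction(bio, orig) == expected


def test_price_reduction_rejects_nonpositive_originator():
    with pytest.raises(ValueError):
        price_reduction(100, 0)


class TestTotals:
    def test_cost_decomposition_sums_exactly(self, base_results):
        for r in base_results.values():
            assert r.cost == pytest.approx(
                r.cost_drug + r.cost_ae + r.cost_nonpharma, abs=1e-6
            )

    def test_totals_equal_trace_increments(self, base_config, life_table):
        s = base_config.strategies[0]
        trace = run_cohort(s, base_config.economics, base_config.population, life_table)
        r = StrategyResult.from_trace(trace)
        assert r.cost == pytest.approx(trace.cost.sum(), abs=1e-6)
        assert r.qaly == pytest.approx(trace.qaly.sum(), abs=1e-9)

    def test_discounted_totals_monotone_in_rate(self, base_config, life_table):
        """Higher discount rates never increase lifetime cost or QALY."""
        prev = None
        for rate in (0.0, 0.01, 0.02, 0.035, 0.05):
            cfg = copy.deepcopy(base_config)
            cfg.economics.annual_discount_rate = rate
            s = cfg.strategies[0]
            r = StrategyResult.from_trace(
                run_cohort(s, cfg.economics, cfg.population, life_table)
            )
            if prev is not None:
                assert r.cost <= prev.cost and r.qaly <= prev.qaly
            prev = r

    def test_report_table_layout(self, base_results, base_config):
        table = base_case_table(
            list(base_results.values()), base_config.economics, "Leflunomide"
        )
        assert list(table.strategy) == list(base_results)
        ref_row = table[table.strategy == "Leflunomide"].iloc[0]
        assert ref_row.dominance == "reference"
        assert pd.isna(ref_row.icer)
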