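"""Cohort engine: mortality adjustment, transition rules, trace invariants."""

from __future__ import annotations

import copy

import numpy as np
import pytest

from biosimce import (
    LifeTable,
    StrategySpec,
    adjusted_mortality,
    build_state_space,
    first_cycle_transition,
    maintenance_transition,
    run_cohort,
    supportive_haq_delta,
)

from conftest import (
    fixed,
    make_line,
    make_strategy,
    make_supportive,
    short_settings,
    small_population,
)


@pytest.mark.parametrize(
    "base_q, haq, hr, expected",
    [
        (0.01, 0.0, 1.33, 0.01),
        (0.01, 1.0, 1.33, 0.0133),
        (0.9, 3.0, 1.33, 1.0),  # 0.9 * 1.33**3 = 2.117, capped at 1
    ],
)
def test_adjusted_mortality(base_q, haq, hr, expected):
    assert adjusted_mortality(base_q, haq, hr) == pytest.approx(expected)


@pytest.mark.parametrize("cycle, expected", [(1, -0.04), (2, 0.2), (3, 0.28), (10, 0.28)])
def test_supportive_haq_trajectory(cycle, expected):
    assert supportive_haq_delta(cycle) == expected


def test_supportive_haq_clamps_at_scale_ceiling():
    """From HAQ 2.9 the +0.28 deterioration stops at 3.0, not 3.18."""
    strat = make_strategy(n_subsequent=0)
    space = build_state_space(strat, baseline_haq=2.9)
    sc_haqs = [s.haq for s in space.states if s.kind == "sc"]
    assert max(sc_haqs) == 3.0
    assert sc_haqs[-1] == 3.0  # absorbing at the ceiling


class TestFirstCycle:
    def test_leflunomide_split(self, base_config):
        first = base_config.strategy("Leflunomide").first_line
        cats, _, switch = first_cycle_transition(first, 1.6)
        assert switch == pytest.approx(0.38)
        assert cats.p_lt20 + cats.p_20_50 + cats.p_50_70 + cats.p_ge70 == pytest.approx(1)

    def test_infliximab_remaining_fraction(self, base_config):
        first = base_config.strategy("Biosimilar infliximab").first_line
        cats, _, switch = first_cycle_transition(first, 1.6)
        assert 1.0 - switch == pytest.approx(0.734)

    def test_haq_floor_at_zero(self):
        """A >=ACR70 responder entering at HAQ 1.02 lands exactly at 0."""
        line = make_line("x", acr=(0.7, 0.4, 0.2))
        _, haq_after, _ = first_cycle_transition(line, 1.02)
        assert haq_after["ge70"] == 0.0


class TestMaintenance:
    @pytest.mark.parametrize(
        "label, expected", [("Biosimilar infliximab", 0.154), ("Leflunomide", 0.365)]
    )
    def test_published_discontinuation(self, base_config, label, expected):
        move, stay = maintenance_transition(base_config.strategy(label).first_line)
        assert move == pytest.approx(expected)
        assert move + stay == pytest.approx(1.0)

    def test_zero_discontinuation_is_identity(self):
        move, stay = maintenance_transition(make_line("x", disc=0.0))
        assert (move, stay) == (0.0, 1.0)


class TestRunCohort:
    def test_mass_conservation_zero_mortality(self, zero_life_table):
        strat = StrategySpec(
            label="simplified",
            first_line=make_line("lef", cost=124.0, disc=0.365, acr=(0.62, 0.38, 0.07)),
            subsequent_lines=[],
            supportive_care=make_supportive(),
            simplified=True,
        )
        trace = run_cohort(strat, short_settings(20), small_population(), zero_life_table)
        assert np.allclose(trace.survival(), 1.0, atol=1e-12)
        assert trace.conservation_error() < 1e-10

    def test_mass_conservation_on_fixture(self, base_config, life_table):
        for s in base_config.strategies:
            trace = run_cohort(s, base_config.economics, base_config.population, life_table)
            assert trace.conservation_error() < 1e-10
            assert np.all(trace.occupancy >= -1e-15)

    def test_forced_routing_to_supportive_care(self, zero_life_table):
        """Non-response 1.0 routes the whole cohort to supportive care at cycle 1."""
        strat = StrategySpec(
            label="forced",
            first_line=make_line("x", disc=1.0, acr=(0.0, 0.0, 0.0)),
            subsequent_lines=[],
            supportive_care=make_supportive(),
            simplified=True,
        )
        trace = run_cohort(strat, short_settings(5), small_population(), zero_life_table)
        sc_idx = [i for i, s in enumerate(trace.states) if s.kind == "sc"]
        assert trace.occupancy[1, sc_idx].sum() == pytest.approx(1.0)

    def test_survival_decreases_with_baseline_haq(self, life_table):
        """With HR 1.33 per HAQ point, a sicker cohort never outlives a healthier one."""
        strat = make_strategy()
        st = short_settings(30)
        lo = run_cohort(strat, st, small_population(haq=0.8), life_table)
        hi = run_cohort(strat, st, small_population(haq=2.4), life_table)
        assert np.all(hi.survival() <= lo.survival() + 1e-12)
        assert hi.survival()[-1] < lo.survival()[-1]

    def test_survival_non_increasing(self, base_config, life_table):
        s = base_config.strategies[0]
        trace = run_cohort(s, base_config.economics, base_config.population, life_table)
        assert np.all(np.diff(trace.survival()) <= 1e-12)

    def test_rebound_rule_on_state_space(self, base_config):
        """Every line is entered at the HAQ of the abandoned line's entry —
        here the first line's entry value, by induction."""
        for s in base_config.strategies:
            space = build_state_space(s, base_config.population.baseline_haq.value)
            for state in space.states:
                if state.kind == "entry":
                    assert state.haq == state.haq_at_line_entry
                    assert state.haq == base_config.population.baseline_haq.value

    def test_trace_frames_shapes(self, base_config, life_table):
        s = base_config.strategies[0]
        trace = run_cohort(s, base_config.economics, base_config.population, life_table)
        frame = trace.to_frame()
        assert len(frame) == trace.n_cycles
        sf = trace.state_frame()
        assert set(sf.state.unique()) == {st.label for st in trace.states} | {"dead"}


class TestLifeTable:
    def test_cycle_prob_halves_annual_risk(self, life_table):
        q_year = life_table.blended_annual_q(70, 0.727)
        q_cycle = life_table.cycle_prob(70, 0.727, 0.5)
        assert q_cycle == pytest.approx(1 - (1 - q_year) ** 0.5)

    def test_age_clamped_to_table_range(self, life_table):
        assert life_table.annual_q(150, "female") == life_table.annual_q(100, "female")

    def test_rejects_bad_probabilities(self):
        import pandas as pd

        frame = pd.DataFrame({"age": [0, 1], "sex": "female", "annual_qx": [0.5, 1.5]})
        with pytest.raises(ValueError, match="outside"):
            LifeTable(frame)
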