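"""Brute-force individual-level microsimulation oracle.

Independent reimplementation of the cohort rules by per-patient Monte-Carlo
sampling: each simulated patient draws their own ACR response category,
per-cycle death and discontinuation events, and walks the treatment sequence
into supportive care.  Expected (mean) discounted cost and QALY must agree
with the deterministic cohort engine within Monte-Carlo error.

Adverse-event costs enter as expected per-cycle amounts (they are linear in
occupancy, so sampling them would only add variance, not change the mean
being compared).
"""

from __future__ import annotations

import numpy as np

from biosimce.engine import LifeTable
from biosimce.parameters import (
    EconomicSettings,
    PopulationProfile,
    StrategySpec,
    acr_cumulative_to_categories,
)


def microsimulate(
    strategy: StrategySpec,
    settings: EconomicSettings,
    population: PopulationProfile,
    life_table: LifeTable,
    n_patients: int,
    seed: int,
) -> dict[str, float]:
    """Simulate n patients; returns means and standard errors of discounted
    lifetime cost and QALY."""
    rng = np.random.default_rng(seed)
    cl = settings.cycle_length_years
    hr = population.mortality_hr_per_haq
    ff = population.female_fraction
    r = settings.annual_discount_rate
    um = settings.utility_mapping
    clamp = lambda h: np.clip(h, 0.0, 3.0)
    h0 = float(clamp(population.baseline_haq.value))

    lines = [strategy.first_line] + list(strategy.subsequent_lines)
    n_lines = len(lines)
    sc = strategy.supportive_care
    experienced = strategy.first_line.is_tnfi

    cats = acr_cumulative_to_categories(strategy.first_line.acr_response).as_tuple()
    hbc = strategy.first_line.haq_change_by_category
    cat_haq = {
        1: float(clamp(h0 + hbc["acr20_50"].value)),
        2: float(clamp(h0 + hbc["acr50_70"].value)),
        3: float(clamp(h0 + hbc["ge70"].value)),
    }
    line_haq = {
        j: float(clamp(h0 + ln.haq_change_for(experienced)))
        for j, ln in enumerate(lines[1:], start=1)
    }
    drug_first = [ln.drug_cost_first_cycle.value for ln in lines]
    drug_sub = [ln.drug_cost_subsequent.value for ln in lines]
    ae_cost = [ln.expected_ae_cost() for ln in lines]
    disc_prob = [ln.discontinuation_prob.value for ln in lines]

    years = population.max_age - population.baseline_age
    if settings.horizon_years is not None:
        years = min(years, settings.horizon_years)
    cycles = int(round(years / cl))

    n = n_patients
    alive = np.ones(n, dtype=bool)
    line = np.zeros(n, dtype=int)  # index n_lines means supportive care
    entry = np.ones(n, dtype=bool)  # currently in the first cycle of a line
    haq = np.full(n, h0)
    sc_done = np.zeros(n, dtype=int)  # completed supportive-care cycles
    cost = np.zeros(n)
    qaly = np.zeros(n)
    edges = np.cumsum(cats)

    for t in range(cycles):
        age = population.baseline_age + t * cl
        qb = life_table.cycle_prob(age, ff, cl)
        p_die = np.minimum(qb * hr**haq, 1.0)
        alive &= ~(alive & (rng.random(n) < p_die))
        if not alive.any():
            break

        t_disc = (t + 0.5) * cl if settings.half_cycle_correction else t * cl
        df = (1.0 + r) ** (-t_disc)

        # accrual at start-of-cycle HAQ for survivors
        c = np.zeros(n)
        for j in range(n_lines):
            sel = alive & (line == j)
            c[sel & entry] = drug_first[j] + ae_cost[j]
            c[sel & ~entry] = drug_sub[j] + ae_cost[j]
        in_sc = alive & (line == n_lines)
        if in_sc.any():
            cyc = sc_done[in_sc] + 1
            extra = np.zeros(len(cyc))
            if sc.include_nonpharma:
                extra += sc.physiotherapy_cost_per_cycle.value
                extra[cyc <= sc.max_steroid_cycles] += sc.steroid_injection_cost.value
            c[in_sc] = sc.drug_cost_per_cycle.value + extra
        cost += c * df
        qaly += np.where(alive, (um.intercept + um.slope * haq) * cl, 0.0) * df

        # end-of-cycle transitions, from a start-of-cycle snapshot
        line0, entry0 = line.copy(), entry.copy()
        u_disc = rng.random(n)
        u_cat = rng.random(n)

        # first line, first cycle: ACR category draw
        sel = alive & (line0 == 0) & entry0
        category = np.searchsorted(edges, u_cat, side="right")
        switch = sel & (category == 0)
        for k in (1, 2, 3):
            stay = sel & (category == k)
            haq[stay] = cat_haq[k]
        entry[sel] = False
        line[switch] = 1
        haq[switch] = h0  # rebound to line-entry HAQ
        entry[switch] = True

        # maintenance discontinuation (cycles after a line's first)
        for j in range(n_lines):
            sel = alive & (line0 == j) & ~entry0 & (u_disc < disc_prob[j])
            line[sel] = j + 1
            haq[sel] = h0
            entry[sel] = True

        # a subsequent line's entry cycle ends on treatment with its HAQ change
        for j in range(1, n_lines):
            sel = alive & (line0 == j) & entry0
            haq[sel] = line_haq[j]
            entry[sel] = False

        # supportive-care HAQ trajectory
        sel = alive & (line0 == n_lines)
        if sel.any():
            cyc = sc_done[sel] + 1
            delta = np.where(
                cyc == 1,
                sc.haq_delta_cycle1,
                np.where(cyc == 2, sc.haq_delta_cycle2, sc.haq_delta_later),
            )
            haq[sel] = clamp(haq[sel] + delta)
            sc_done[sel] += 1

    return {
        "cost_mean": float(cost.mean()),
        "cost_se": float(cost.std(ddof=1) / np.sqrt(n)),
        "qaly_mean": float(qaly.mean()),
        "qaly_se": float(qaly.std(ddof=1) / np.sqrt(n)),
    }
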