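"""Deterministic cohort propagation through the expanded treatment-sequence state space.

The model is a multistate Markov cohort engine on 6-month cycles.  Expanded
states carry the information that makes history-dependent rules Markovian:
the treatment line, the ACR response stratum on the first line, the
time-in-state counter for supportive care (its HAQ-DI trajectory and the
twice-in-a-lifetime steroid injections depend on it), and the HAQ-DI anchor
for the rebound rule (on abandoning a line, disability returns to its value
at that line's entry).

Within a cycle the event order is: background mortality adjusted for the
start-of-cycle HAQ-DI (hazard ratio 1.33 per HAQ-DI point), accrual of cost
and utility for survivors at start-of-cycle HAQ-DI, then end-of-cycle
switching (ACR-based routing in the first cycle of the first line,
per-cycle discontinuation afterwards).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import (
    ACR_CATEGORIES,
    AcrCategories,
    EconomicSettings,
    PopulationProfile,
    StrategySpec,
    SupportiveCareParams,
    TreatmentLineParams,
    acr_cumulative_to_categories,
)

HAQ_MAX = 3.0

#: Responder strata that remain on the first line after the ACR assessment.
RESPONDER_CATEGORIES = ("acr20_50", "acr50_70", "ge70")


def _clamp_haq(h: float) -> float:
    return min(HAQ_MAX, max(0.0, h))


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------


class LifeTable:
    """Annual death probabilities by integer age and sex.

    The cohort uses a single blended table (female share fixed at the
    cohort's sex mix); annual probabilities convert to per-cycle
    probabilities via 1 − (1 − q)^cycle_length.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"age", "sex", "annual_qx"}
        if not required.issubset(frame.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        self.frame = frame.sort_values(["sex", "age"]).reset_index(drop=True)
        self._qx: dict[str, np.ndarray] = {}
        ages = None
        for sex, grp in self.frame.groupby("sex"):
            a = grp["age"].to_numpy(dtype=int)
            if ages is None:
                ages = a
            elif not np.array_equal(ages, a):
                raise ValueError("life table sexes cover different age ranges")
            self._qx[sex] = grp["annual_qx"].to_numpy(dtype=float)
        if ages is None or len(ages) == 0:
            raise ValueError("empty life table")
        self.min_age = int(ages.min())
        self.max_age = int(ages.max())
        for sex, q in self._qx.items():
            if np.any((q < 0) | (q > 1)):
                raise ValueError(f"life table {sex} probabilities outside [0, 1]")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls(pd.read_csv(path))

    @classmethod
    def zero(cls, max_age: int = 110) -> "LifeTable":
        """All-zero mortality, for closed-form limit checks."""
        ages = np.arange(0, max_age + 1)
        frame = pd.DataFrame(
            {
                "age": np.tile(ages, 2),
                "sex": ["female"] * len(ages) + ["male"] * len(ages),
                "annual_qx": 0.0,
            }
        )
        return cls(frame)

    def annual_q(self, age: float, sex: str) -> float:
        idx = int(np.clip(np.floor(age), self.min_age, self.max_age)) - self.min_age
        return float(self._qx[sex][idx])

    def blended_annual_q(self, age: float, female_fraction: float) -> float:
        qf = self.annual_q(age, "female")
        qm = self.annual_q(age, "male")
        return female_fraction * qf + (1.0 - female_fraction) * qm

    def cycle_prob(
        self, age: float, female_fraction: float, cycle_length_years: float
    ) -> float:
        q = self.blended_annual_q(age, female_fraction)
        return 1.0 - (1.0 - q) ** cycle_length_years


def adjusted_mortality(base_q: float, haq: float, hr: float) -> float:
    """HAQ-adjusted per-cycle death probability: min(base_q · hr^HAQ, 1)."""
    return min(base_q * hr**haq, 1.0)


# ---------------------------------------------------------------------------
# Local transition rules (used both directly and to assemble the matrix)
# ---------------------------------------------------------------------------


def first_cycle_transition(
    params: TreatmentLineParams, haq_at_entry: float
) -> tuple[AcrCategories, dict[str, float], float]:
    """End of the first cycle on a first-line drug.

    Returns the ACR category split, the post-change HAQ-DI for each
    responder stratum, and the fraction routed onward (<ACR20, whose HAQ-DI
    rebounds to the line-entry value).
    """
    cats = acr_cumulative_to_categories(params.acr_response)
    if params.haq_change_by_category is None:
        raise ValueError(f"{params.name}: first-line HAQ changes by category missing")
    haq_after = {
        cat: _clamp_haq(haq_at_entry + params.haq_change_by_category[cat].value)
        for cat in RESPONDER_CATEGORIES
    }
    return cats, haq_after, cats.p_lt20


def maintenance_transition(params: TreatmentLineParams) -> tuple[float, float]:
    """(probability of moving to the next line, probability of staying)."""
    d = params.discontinuation_prob.value
    return d, 1.0 - d


def supportive_haq_delta(
    cycles_in_supportive_care: int, params: SupportiveCareParams | None = None
) -> float:
    """HAQ-DI increment for the n-th supportive-care cycle (1-based).

    Default trajectory: −0.04, +0.2, then +0.28 every subsequent cycle;
    application always clamps to the scale ceiling of 3.
    """
    if cycles_in_supportive_care < 1:
        raise ValueError("cycles_in_supportive_care is 1-based")
    if params is not None:
        return params.haq_delta(cycles_in_supportive_care)
    return {1: -0.04, 2: 0.2}.get(cycles_in_supportive_care, 0.28)


# ---------------------------------------------------------------------------
# Expanded state space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpandedState:
    """One alive state of the expanded Markov chain."""

    label: str
    line_index: int  # 0-based treatment line; -1 = supportive care
    kind: str  # "entry" | "on" | "sc"
    stratum: str | None  # ACR category for first-line maintenance
    cycles_in_state: int  # 1-based supportive-care tunnel cycle; 0 otherwise
    haq: float  # start-of-cycle HAQ-DI
    haq_at_line_entry: float


@dataclass
class StateSpace:
    states: list[ExpandedState]
    transition: np.ndarray  # survivors, end-of-cycle; rows sum to 1
    index: dict[str, int]

    @property
    def haq(self) -> np.ndarray:
        return np.array([s.haq for s in self.states])


def build_state_space(
    strategy: StrategySpec, baseline_haq: float
) -> StateSpace:
    """Enumerate expanded states and the static survivor transition matrix."""
    h0 = _clamp_haq(baseline_haq)
    lines = [strategy.first_line] + list(strategy.subsequent_lines)
    sc = strategy.supportive_care

    states: list[ExpandedState] = []

    def add(state: ExpandedState) -> int:
        states.append(state)
        return len(states) - 1

    i_entry0 = add(ExpandedState("line0:entry", 0, "entry", None, 0, h0, h0))
    cats, haq_after, _ = first_cycle_transition(strategy.first_line, h0)
    i_on0 = {
        cat: add(
            ExpandedState(f"line0:on:{cat}", 0, "on", cat, 0, haq_after[cat], h0)
        )
        for cat in RESPONDER_CATEGORIES
    }

    i_entry, i_on = {}, {}
    experienced = strategy.first_line.is_tnfi
    for j, line in enumerate(lines[1:], start=1):
        # rebound rule: every line is entered at the first line's entry HAQ-DI,
        # because abandoning any line restores the HAQ-DI at its own entry
        i_entry[j] = add(ExpandedState(f"line{j}:entry", j, "entry", None, 0, h0, h0))
        haq_on = _clamp_haq(h0 + line.haq_change_for(experienced))
        i_on[j] = add(ExpandedState(f"line{j}:on", j, "on", None, 0, haq_on, h0))

    # supportive-care tunnel: HAQ-DI trajectory from the (rebounded) entry value
    sc_haqs = [h0]
    while (
        sc_haqs[-1] < HAQ_MAX - 1e-12 and sc.haq_delta_later > 0
    ) or len(sc_haqs) <= sc.max_steroid_cycles:
        if len(sc_haqs) >= 400:
            raise RuntimeError("supportive-care tunnel failed to terminate")
        sc_haqs.append(_clamp_haq(sc_haqs[-1] + sc.haq_delta(len(sc_haqs))))
    i_sc = [
        add(ExpandedState(f"sc:{c}", -1, "sc", None, c, h, h0))
        for c, h in enumerate(sc_haqs, start=1)
    ]

    n = len(states)
    T = np.zeros((n, n))

    def next_line_entry(j: int) -> int:
        return i_entry[j + 1] if (j + 1) in i_entry else i_sc[0]

    # first line, first cycle: ACR split
    T[i_entry0, next_line_entry(0)] = cats.p_lt20
    for cat, p in zip(RESPONDER_CATEGORIES, (cats.p_20_50, cats.p_50_70, cats.p_ge70)):
        T[i_entry0, i_on0[cat]] = p
    # first line, maintenance
    d0, stay0 = maintenance_transition(strategy.first_line)
    for cat in RESPONDER_CATEGORIES:
        T[i_on0[cat], next_line_entry(0)] = d0
        T[i_on0[cat], i_on0[cat]] = stay0
    # subsequent lines
    for j, line in enumerate(lines[1:], start=1):
        T[i_entry[j], i_on[j]] = 1.0
        dj, stayj = maintenance_transition(line)
        T[i_on[j], next_line_entry(j)] = dj
        T[i_on[j], i_on[j]] = stayj
    # supportive-care tunnel, last state absorbing
    for k in range(len(i_sc) - 1):
        T[i_sc[k], i_sc[k + 1]] = 1.0
    T[i_sc[-1], i_sc[-1]] = 1.0

    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
        raise RuntimeError("transition rows do not sum to 1")
    return StateSpace(states, T, {s.label: i for i, s in enumerate(states)})


def state_cost_components(
    state: ExpandedState, strategy: StrategySpec
) -> tuple[float, float, float]:
    """(drug, adverse-event, non-pharmacological) cost per occupied cycle.

    Implements the loading-dose rule (first-cycle drug price in a line's
    entry cycle), expected adverse-event costs (probability × episode cost),
    and supportive care's steroid-injection (first two cycles only) and
    physiotherapy costs.
    """
    if state.kind == "sc":
        sc = strategy.supportive_care
        return (
            sc.drug_cost_per_cycle.value,
            0.0,
            sc.nonpharma_cost(state.cycles_in_state),
        )
    lines = [strategy.first_line] + list(strategy.subsequent_lines)
    line = lines[state.line_index]
    drug = (
        line.drug_cost_first_cycle.value
        if state.kind == "entry"
        else line.drug_cost_subsequent.value
    )
    return drug, line.expected_ae_cost(), 0.0


# ---------------------------------------------------------------------------
# Cohort trace
# ---------------------------------------------------------------------------


@dataclass
class CohortTrace:
    """Per-cycle ledger of one strategy's cohort simulation."""

    strategy_label: str
    states: list[ExpandedState]
    occupancy: np.ndarray  # (cycles, n_states) start-of-cycle alive occupancy
    dead: np.ndarray  # (cycles,) cumulative dead at start of cycle
    age: np.ndarray  # (cycles,) cohort age at start of cycle
    mean_haq_alive: np.ndarray
    cost_drug: np.ndarray  # discounted increments per cycle
    cost_ae: np.ndarray
    cost_nonpharma: np.ndarray
    qaly: np.ndarray
    cost_undiscounted: np.ndarray
    qaly_undiscounted: np.ndarray
    settings: EconomicSettings = field(repr=False, default=None)

    @property
    def n_cycles(self) -> int:
        return len(self.age)

    @property
    def cost(self) -> np.ndarray:
        return self.cost_drug + self.cost_ae + self.cost_nonpharma

    def conservation_error(self) -> float:
        return float(np.max(np.abs(self.occupancy.sum(axis=1) + self.dead - 1.0)))

    def survival(self) -> np.ndarray:
        return self.occupancy.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles),
                "age": self.age,
                "alive": self.survival(),
                "dead": self.dead,
                "mean_haq_alive": self.mean_haq_alive,
                "cost_drug": self.cost_drug,
                "cost_ae": self.cost_ae,
                "cost_nonpharma": self.cost_nonpharma,
                "cost": self.cost,
                "qaly": self.qaly,
                "cost_undiscounted": self.cost_undiscounted,
                "qaly_undiscounted": self.qaly_undiscounted,
            }
        )

    def state_frame(self) -> pd.DataFrame:
        """Long format: one row per cycle × state."""
        rows = []
        for t in range(self.n_cycles):
            for i, s in enumerate(self.states):
                rows.append(
                    {
                        "cycle": t,
                        "state": s.label,
                        "line_index": s.line_index,
                        "kind": s.kind,
                        "haq": s.haq,
                        "occupancy": self.occupancy[t, i],
                    }
                )
            rows.append(
                {
                    "cycle": t,
                    "state": "dead",
                    "line_index": -2,
                    "kind": "dead",
                    "haq": np.nan,
                    "occupancy": self.dead[t],
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort propagation
# ---------------------------------------------------------------------------


def n_model_cycles(settings: EconomicSettings, population: PopulationProfile) -> int:
    years = population.max_age - population.baseline_age
    if settings.horizon_years is not None:
        years = min(years, settings.horizon_years)
    return int(round(years / settings.cycle_length_years))


def run_cohort(
    strategy: StrategySpec,
    settings: EconomicSettings,
    population: PopulationProfile,
    life_table: LifeTable,
) -> CohortTrace:
    """Propagate the full cohort through one strategy's state space.

    Terminates at the economic horizon or when the cohort reaches the
    population's maximum age, whichever comes first.
    """
    space = build_state_space(strategy, population.baseline_haq.value)
    n = len(space.states)
    cycles = n_model_cycles(settings, population)
    cl = settings.cycle_length_years
    hr = population.mortality_hr_per_haq
    r = settings.annual_discount_rate
    um = settings.utility_mapping

    haq = space.haq
    comp = np.array(
        [state_cost_components(s, strategy) for s in space.states]
    )  # (n, 3): drug, ae, nonpharma
    util = np.array([um(h) for h in haq]) * cl  # QALY per occupied cycle

    occ = np.zeros(n)
    occ[space.index["line0:entry"]] = 1.0
    dead = 0.0

    occ_hist = np.zeros((cycles, n))
    dead_hist = np.zeros(cycles)
    age_hist = np.zeros(cycles)
    haq_hist = np.zeros(cycles)
    cdrug = np.zeros(cycles)
    cae = np.zeros(cycles)
    cnp = np.zeros(cycles)
    q_disc = np.zeros(cycles)
    c_undisc = np.zeros(cycles)
    q_undisc = np.zeros(cycles)

    Tt = space.transition.T
    for t in range(cycles):
        age = population.baseline_age + t * cl
        if not np.all(np.isfinite(occ)):
            raise RuntimeError(f"non-finite occupancy at cycle {t}")
        total = occ.sum() + dead
        if abs(total - 1.0) > 1e-8:
            raise RuntimeError(f"occupancy mass {total} != 1 at cycle {t}")

        occ_hist[t] = occ
        dead_hist[t] = dead
        age_hist[t] = age
        alive = occ.sum()
        haq_hist[t] = float(occ @ haq / alive) if alive > 0 else np.nan

        # 1. mortality at start-of-cycle HAQ-DI
        qb = life_table.cycle_prob(age, population.female_fraction, cl)
        q = np.minimum(qb * hr**haq, 1.0)
        deaths = occ * q
        dead += float(deaths.sum())
        surv = occ - deaths

        # 2. accrual for survivors (start-of-cycle HAQ-DI, full cycle)
        t_disc = (t + 0.5) * cl if settings.half_cycle_correction else t * cl
        df = (1.0 + r) ** (-t_disc)
        cdrug[t] = float(surv @ comp[:, 0]) * df
        cae[t] = float(surv @ comp[:, 1]) * df
        cnp[t] = float(surv @ comp[:, 2]) * df
        q_disc[t] = float(surv @ util) * df
        c_undisc[t] = float(surv @ comp.sum(axis=1))
        q_undisc[t] = float(surv @ util)

        # 3. end-of-cycle switching
        occ = Tt @ surv

    return CohortTrace(
        strategy_label=strategy.label,
        states=space.states,
        occupancy=occ_hist,
        dead=dead_hist,
        age=age_hist,
        mean_haq_alive=haq_hist,
        cost_drug=cdrug,
        cost_ae=cae,
        cost_nonpharma=cnp,
        qaly=q_disc,
        cost_undiscounted=c_undisc,
        qaly_undiscounted=q_undisc,
        settings=settings,
    )


def run_all(
    strategies: Sequence[StrategySpec],
    settings: EconomicSettings,
    population: PopulationProfile,
    life_table: LifeTable,
) -> list[CohortTrace]:
    return [run_cohort(s, settings, population, life_table) for s in strategies]
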