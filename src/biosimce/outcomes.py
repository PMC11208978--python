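"""Discounted lifetime outcomes, ICERs, dominance and net monetary benefit.

Utilities come from the linear HAQ-DI mapping u = 0.74 − 0.17·HAQ-DI; costs
and QALYs are discounted at 3.5% per year by default and compared against a
willingness-to-pay threshold of US $48 555 per QALY (1× 2022 GDP per capita
in the modelled health system).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import CohortTrace
from .parameters import EconomicSettings, UtilityMapping

#: |ΔQALY| below which an ICER is reported as undefined.
QALY_TIE_EPS = 1e-12


def utility_from_haq(haq: float, mapping: UtilityMapping | None = None) -> float:
    """Per-year utility for a HAQ-DI level (linear mapping)."""
    mapping = mapping or UtilityMapping()
    return mapping(haq)


def discount_factor(cycle_index: int, settings: EconomicSettings) -> float:
    """Discount factor at the start of a cycle: (1+r)^(−cycle·cycle_length)."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    t = cycle_index * settings.cycle_length_years
    if settings.half_cycle_correction:
        t += 0.5 * settings.cycle_length_years
    return (1.0 + settings.annual_discount_rate) ** (-t)


@dataclass(frozen=True)
class TraceSlot:
    """One resolved cycle × state accrual input (a trace row)."""

    occupancy: float
    haq: float
    cycle_index: int
    drug_cost: float
    ae_expected_cost: float
    nonpharma_cost: float = 0.0


def accrue_cycle(
    slot: TraceSlot, settings: EconomicSettings
) -> tuple[float, float]:
    """Discounted (cost, QALY) increment for one trace row.

    Cost = occupancy × (drug + expected adverse-event + non-pharmacological);
    QALY = occupancy × utility(HAQ) × cycle length; both × discount factor.
    """
    df = discount_factor(slot.cycle_index, settings)
    cost = slot.occupancy * (
        slot.drug_cost + slot.ae_expected_cost + slot.nonpharma_cost
    )
    qaly = (
        slot.occupancy
        * utility_from_haq(slot.haq, settings.utility_mapping)
        * settings.cycle_length_years
    )
    if cost < 0:
        raise ValueError(f"negative cost increment {cost}")
    return cost * df, qaly * df


# ---------------------------------------------------------------------------
# Strategy-level results
# ---------------------------------------------------------------------------


@dataclass
class StrategyResult:
    """Lifetime discounted totals for one treatment sequence."""

    label: str
    cost: float
    qaly: float
    cost_drug: float
    cost_ae: float
    cost_nonpharma: float
    cost_undiscounted: float
    qaly_undiscounted: float
    life_years: float  # discounted

    @classmethod
    def from_trace(cls, trace: CohortTrace) -> "StrategyResult":
        s = trace.settings
        df = np.array([discount_factor(t, s) for t in range(trace.n_cycles)])
        ly = float((trace.survival() * s.cycle_length_years * df).sum())
        return cls(
            label=trace.strategy_label,
            cost=float(trace.cost.sum()),
            qaly=float(trace.qaly.sum()),
            cost_drug=float(trace.cost_drug.sum()),
            cost_ae=float(trace.cost_ae.sum()),
            cost_nonpharma=float(trace.cost_nonpharma.sum()),
            cost_undiscounted=float(trace.cost_undiscounted.sum()),
            qaly_undiscounted=float(trace.qaly_undiscounted.sum()),
            life_years=ly,
        )

    @property
    def components(self) -> dict[str, float]:
        return {
            "drug": self.cost_drug,
            "adverse_event": self.cost_ae,
            "nonpharma": self.cost_nonpharma,
        }


def nmb(result: StrategyResult, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay: wtp × QALY − cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.qaly - result.cost


@dataclass
class ICERResult:
    """Pairwise incremental comparison (comparator − reference)."""

    comparator: str
    reference: str
    delta_cost: float
    delta_qaly: float
    icer: float | None  # None when |ΔQALY| is numerically zero
    dominance: str  # "dominant" | "dominated" | "trade-off"
    cost_effective_at_wtp: bool
    delta_nmb: float


def icer(
    a: StrategyResult, b: StrategyResult, settings: EconomicSettings
) -> ICERResult:
    """Incremental cost-effectiveness of strategy *a* against reference *b*.

    The raw ratio is reported even when negative (a dominant comparator),
    alongside the dominance label; cost-effectiveness at the threshold uses
    the net-monetary-benefit comparison.
    """
    dc = a.cost - b.cost
    dq = a.qaly - b.qaly
    ratio = dc / dq if abs(dq) > QALY_TIE_EPS else None
    if dc < 0 and dq > 0:
        dominance = "dominant"
    elif dc > 0 and dq < 0:
        dominance = "dominated"
    else:
        dominance = "trade-off"
    wtp = settings.wtp_threshold
    dn = nmb(a, wtp) - nmb(b, wtp)
    return ICERResult(
        comparator=a.label,
        reference=b.label,
        delta_cost=dc,
        delta_qaly=dq,
        icer=ratio,
        dominance=dominance,
        cost_effective_at_wtp=dn > 0,
        delta_nmb=dn,
    )


def price_reduction(biosimilar_cost: float, originator_cost: float) -> int:
    """Percent price reduction of a biosimilar vs its originator, rounded."""
    if originator_cost <= 0:
        raise ValueError("originator cost must be > 0")
    return int(round(100.0 * (1.0 - biosimilar_cost / originator_cost)))


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------


def base_case_table(
    results: list[StrategyResult],
    settings: EconomicSettings,
    reference_label: str,
) -> pd.DataFrame:
    """Net and incremental cost/QALY per strategy vs the reference.

    Report rounding: costs to whole US$, QALYs to 2 d.p., ICERs to whole
    US$/QALY; the unrounded pipeline is preserved in the result objects.
    """
    ref = next(r for r in results if r.label == reference_label)
    rows = []
    for r in results:
        if r.label == reference_label:
            rows.append(
                {
                    "strategy": r.label,
                    "cost": round(r.cost),
                    "incremental_cost": None,
                    "qaly": round(r.qaly, 2),
                    "incremental_qaly": None,
                    "icer": None,
                    "dominance": "reference",
                }
            )
            continue
        cmp = icer(r, ref, settings)
        rows.append(
            {
                "strategy": r.label,
                "cost": round(r.cost),
                "incremental_cost": round(cmp.delta_cost),
                "qaly": round(r.qaly, 2),
                "incremental_qaly": round(cmp.delta_qaly, 2),
                "icer": round(cmp.icer) if cmp.icer is not None else None,
                "dominance": cmp.dominance,
            }
        )
    return pd.DataFrame(rows)
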