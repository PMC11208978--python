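"""Parameter model for the treatment-sequence cost-effectiveness analysis.

Everything the model consumes is described here: first-line drug parameters
(ACR response triples, discontinuation, adverse-event probabilities, cycle
costs), pooled subsequent-line classes (TNFi, non-TNFi DMARD, JAKi),
supportive care, economic settings and the population profile.  Each
uncertain quantity is a :class:`Param` — a point value plus a
:class:`DistributionSpec` describing how probabilistic and deterministic
sensitivity analyses vary it — together with a provenance tag
(``"paper"`` for published values, ``"synthetic"`` for generated stand-ins).

Configs round-trip through a YAML/JSON dialect (see :func:`load_config` /
:func:`save_config`); validation raises :class:`ConfigError` naming the
offending field.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterator, Mapping, Sequence

import yaml

logger = logging.getLogger("biosimce")

#: Adverse events carried as expected per-cycle costs on biologic / JAKi lines.
AE_EVENTS = ("pneumonia", "herpes_zoster", "tuberculosis", "hepatitis_b")

#: ACR response categories, mutually exclusive, from cumulative 20/50/70 rates.
ACR_CATEGORIES = ("lt20", "acr20_50", "acr50_70", "ge70")

#: Recognised sampling families for uncertain parameters.
FAMILIES = ("fixed", "beta", "gamma", "uniform_range", "dirichlet")

DEFAULT_SD_FRACTION = 0.25  # SD assumed as 25% of the mean when unreported


class ConfigError(ValueError):
    """Validation failure, carrying the dotted path of the offending field."""

    def __init__(self, field_path: str, message: str):
        self.field_path = field_path
        super().__init__(f"{field_path}: {message}")


# ---------------------------------------------------------------------------
# Scalar parameters and their sampling descriptions
# ---------------------------------------------------------------------------


@dataclass
class DistributionSpec:
    """How an uncertain parameter is varied in sensitivity analyses.

    ``family`` selects the PSA sampling distribution (method-of-moments fit
    to the mean carried by the owning :class:`Param` and ``sd``); ``low`` /
    ``high`` give the one-way (tornado) excursion range, defaulting to the
    95% CI ``mean ± 1.96·sd`` when absent.
    """

    family: str = "fixed"
    sd: float | None = None
    low: float | None = None
    high: float | None = None

    def validate(self, path: str) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"{path}.family", f"unknown family {self.family!r}")
        if self.sd is not None and self.sd < 0:
            raise ConfigError(f"{path}.sd", "standard deviation must be >= 0")
        if (self.low is None) != (self.high is None):
            raise ConfigError(f"{path}.range", "low/high must be given together")
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ConfigError(f"{path}.range", f"low {self.low} > high {self.high}")


@dataclass
class Param:
    """A scalar model input: point value, uncertainty, and provenance."""

    name: str
    value: float
    dist: DistributionSpec = field(default_factory=DistributionSpec)
    provenance: str = "synthetic"

    def validate(self) -> None:
        if not math.isfinite(self.value):
            raise ConfigError(self.name, "value must be finite")
        if self.provenance not in ("paper", "synthetic"):
            raise ConfigError(f"{self.name}.provenance", f"got {self.provenance!r}")
        self.dist.validate(self.name)

    @property
    def is_uncertain(self) -> bool:
        return self.dist.family != "fixed"

    def ci_range(self, z: float = 1.96) -> tuple[float, float] | None:
        """One-way excursion range: printed range, else mean ± z·sd."""
        d = self.dist
        if d.low is not None and d.high is not None:
            return (d.low, d.high)
        if d.sd is not None and d.sd > 0:
            return (self.value - z * d.sd, self.value + z * d.sd)
        return None


def probability_param(p: Param, path: str | None = None) -> None:
    path = path or p.name
    if not 0.0 <= p.value <= 1.0:
        raise ConfigError(path, f"probability {p.value} outside [0, 1]")


def cost_param(p: Param, path: str | None = None) -> None:
    path = path or p.name
    if p.value < 0:
        raise ConfigError(path, f"cost {p.value} must be >= 0")


# ---------------------------------------------------------------------------
# ACR response
# ---------------------------------------------------------------------------


@dataclass
class AcrResponse:
    """Cumulative fractions achieving at least ACR20 / ACR50 / ACR70.

    ``sds`` are the per-component standard deviations of the cumulative
    fractions, used to fit the Dirichlet effective sample size for the PSA.
    ``sampled_categories`` carries a PSA draw and is never serialised.
    """

    name: str
    cum20: float
    cum50: float
    cum70: float
    sds: tuple[float, float, float] | None = None
    provenance: str = "paper"
    sampled_categories: tuple[float, float, float, float] | None = None

    def validate(self) -> None:
        c20, c50, c70 = self.cum20, self.cum50, self.cum70
        if not (0.0 <= c70 <= c50 <= c20 <= 1.0):
            raise ConfigError(
                self.name,
                f"cumulative ACR rates must satisfy 1 >= cum20 >= cum50 >= cum70 >= 0, "
                f"got ({c20}, {c50}, {c70})",
            )
        if self.sds is not None and any(s < 0 for s in self.sds):
            raise ConfigError(f"{self.name}.sds", "standard deviations must be >= 0")


@dataclass(frozen=True)
class AcrCategories:
    """Mutually exclusive response split (sums to one)."""

    p_lt20: float
    p_20_50: float
    p_50_70: float
    p_ge70: float

    def __post_init__(self) -> None:
        probs = self.as_tuple()
        if any(p < -1e-12 for p in probs):
            raise ConfigError("acr_categories", f"negative probability in {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ConfigError("acr_categories", f"probabilities {probs} do not sum to 1")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_lt20, self.p_20_50, self.p_50_70, self.p_ge70)


def acr_cumulative_to_categories(r: AcrResponse) -> AcrCategories:
    """Convert cumulative ACR20/50/70 rates into exclusive category probabilities.

    p(<ACR20) = 1 − cum20, p(ACR20–50) = cum20 − cum50,
    p(ACR50–70) = cum50 − cum70, p(≥ACR70) = cum70.
    """
    r.validate()
    if r.sampled_categories is not None:
        return AcrCategories(*r.sampled_categories)
    return AcrCategories(
        p_lt20=1.0 - r.cum20,
        p_20_50=r.cum20 - r.cum50,
        p_50_70=r.cum50 - r.cum70,
        p_ge70=r.cum70,
    )


# ---------------------------------------------------------------------------
# Treatment lines, supportive care, strategies
# ---------------------------------------------------------------------------


@dataclass
class TreatmentLineParams:
    """Efficacy, persistence, safety and cost parameters for one line.

    First-line drugs carry an :class:`AcrResponse` and per-category HAQ-DI
    changes; pooled subsequent-line classes carry a single mean HAQ-DI change
    (for the TNFi class, split into TNFi-naive vs TNFi-experienced, selected
    by the identity of the first-line drug).
    """

    name: str
    drug_cost_first_cycle: Param
    drug_cost_subsequent: Param
    discontinuation_prob: Param
    ae_probs: dict[str, Param] = field(default_factory=dict)
    ae_costs: dict[str, Param] = field(default_factory=dict)
    is_tnfi: bool = False
    acr_response: AcrResponse | None = None
    haq_change_by_category: dict[str, Param] | None = None
    haq_change_mean: Param | None = None
    haq_change_experienced: Param | None = None

    def validate(self) -> None:
        cost_param(self.drug_cost_first_cycle)
        cost_param(self.drug_cost_subsequent)
        probability_param(self.discontinuation_prob)
        for ev, p in self.ae_probs.items():
            if ev not in AE_EVENTS:
                raise ConfigError(f"{self.name}.ae_probs", f"unknown event {ev!r}")
            probability_param(p)
        for p in self.ae_costs.values():
            cost_param(p)
        if self.acr_response is not None:
            self.acr_response.validate()
            if self.haq_change_by_category is None:
                raise ConfigError(
                    f"{self.name}.haq_change_by_category",
                    "first-line drugs require per-ACR-category HAQ changes",
                )
            missing = [c for c in ACR_CATEGORIES if c not in self.haq_change_by_category]
            if missing:
                raise ConfigError(
                    f"{self.name}.haq_change_by_category", f"missing categories {missing}"
                )
        for p in self._haq_params():
            if not -3.0 <= p.value <= 3.0:
                raise ConfigError(p.name, f"HAQ change {p.value} outside [-3, 3]")

    def _haq_params(self) -> list[Param]:
        out: list[Param] = []
        if self.haq_change_by_category:
            out.extend(self.haq_change_by_category.values())
        for p in (self.haq_change_mean, self.haq_change_experienced):
            if p is not None:
                out.append(p)
        return out

    def expected_ae_cost(self) -> float:
        """Expected adverse-event cost per cycle on this line."""
        return sum(
            self.ae_probs[ev].value * self.ae_costs[ev].value
            for ev in self.ae_probs
            if ev in self.ae_costs
        )

    def haq_change_for(self, tnfi_experienced: bool) -> float:
        """Mean on-treatment HAQ change for a subsequent line."""
        if tnfi_experienced and self.haq_change_experienced is not None:
            return self.haq_change_experienced.value
        if self.haq_change_mean is None:
            raise ConfigError(f"{self.name}.haq_change_mean", "missing HAQ change")
        return self.haq_change_mean.value


@dataclass
class SupportiveCareParams:
    """Terminal palliative state: progressive disability and its costs.

    The published HAQ-DI trajectory is −0.04 in the first half-year of
    supportive care, +0.2 in the second, then +0.28 per cycle until the
    scale ceiling of 3.  Non-pharmacological care comprises intraarticular
    steroid injections every 6 months (at most twice in a lifetime) and
    biweekly physiotherapy.
    """

    drug_cost_per_cycle: Param
    steroid_injection_cost: Param
    physiotherapy_cost_per_cycle: Param
    haq_delta_cycle1: float = -0.04
    haq_delta_cycle2: float = 0.2
    haq_delta_later: float = 0.28
    include_nonpharma: bool = True
    max_steroid_cycles: int = 2

    def validate(self) -> None:
        cost_param(self.drug_cost_per_cycle)
        cost_param(self.steroid_injection_cost)
        cost_param(self.physiotherapy_cost_per_cycle)
        for d in (self.haq_delta_cycle1, self.haq_delta_cycle2, self.haq_delta_later):
            if not -3.0 <= d <= 3.0:
                raise ConfigError("supportive_care.haq_deltas", f"delta {d} outside [-3, 3]")

    def haq_delta(self, cycles_in_care: int) -> float:
        """HAQ-DI increment applied at the end of supportive-care cycle *n* (1-based)."""
        if cycles_in_care < 1:
            raise ValueError("cycles_in_care is 1-based")
        if cycles_in_care == 1:
            return self.haq_delta_cycle1
        if cycles_in_care == 2:
            return self.haq_delta_cycle2
        return self.haq_delta_later

    def nonpharma_cost(self, cycles_in_care: int) -> float:
        """Non-pharmacological cost for supportive-care cycle *n* (1-based)."""
        if not self.include_nonpharma:
            return 0.0
        cost = self.physiotherapy_cost_per_cycle.value
        if cycles_in_care <= self.max_steroid_cycles:
            cost += self.steroid_injection_cost.value
        return cost


@dataclass
class UtilityMapping:
    """Linear HAQ-DI → utility map, u = intercept + slope·HAQ."""

    intercept: float = 0.74
    slope: float = -0.17
    label: str = "linear-0.74-0.17"

    def __call__(self, haq: float) -> float:
        return self.intercept + self.slope * haq

    def validate(self) -> None:
        for h in (0.0, 3.0):
            if not math.isfinite(self(h)):
                raise ConfigError("utility_mapping", "mapping not finite on [0, 3]")


@dataclass
class EconomicSettings:
    """Cycle length, discounting, decision threshold and utility mapping."""

    cycle_length_years: float = 0.5
    annual_discount_rate: float = 0.035
    wtp_threshold: float = 48_555.0
    horizon_years: float | None = None  # None = run to the population max age
    utility_mapping: UtilityMapping = field(default_factory=UtilityMapping)
    half_cycle_correction: bool = False
    currency_note: str = "2022 US$; exchange US $1 = HK $7.78"

    def validate(self) -> None:
        if not 0.0 <= self.annual_discount_rate <= 1.0:
            raise ConfigError("economics.annual_discount_rate", "must be in [0, 1]")
        if self.cycle_length_years <= 0:
            raise ConfigError("economics.cycle_length_years", "must be > 0")
        if self.horizon_years is not None and self.horizon_years <= 0:
            raise ConfigError("economics.horizon_years", "must be > 0")
        if self.wtp_threshold < 0:
            raise ConfigError("economics.wtp_threshold", "must be >= 0")
        self.utility_mapping.validate()


@dataclass
class PopulationProfile:
    """Cohort entering the model at first-line initiation."""

    baseline_age: float = 56.0
    age_sd: float = 17.0
    female_fraction: float = 0.727
    baseline_haq: Param = field(
        default_factory=lambda: Param(
            "population.baseline_haq",
            1.6,
            DistributionSpec("uniform_range", low=1.2, high=2.0),
            provenance="paper",
        )
    )
    mortality_hr_per_haq: float = 1.33
    max_age: float = 100.0

    def validate(self) -> None:
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("population.female_fraction", "must be in [0, 1]")
        if not 0.0 <= self.baseline_haq.value <= 3.0:
            raise ConfigError("population.baseline_haq", "must be in [0, 3]")
        if self.mortality_hr_per_haq <= 0:
            raise ConfigError("population.mortality_hr_per_haq", "must be > 0")
        if not 0 < self.baseline_age < self.max_age:
            raise ConfigError("population.baseline_age", "must lie below max_age")


@dataclass
class StrategySpec:
    """An ordered treatment sequence ending in supportive care."""

    label: str
    first_line: TreatmentLineParams
    subsequent_lines: list[TreatmentLineParams]
    supportive_care: SupportiveCareParams
    simplified: bool = False

    def validate(self) -> None:
        self.first_line.validate()
        if self.first_line.acr_response is None:
            raise ConfigError(f"{self.label}.first_line", "first line needs an ACR response")
        if self.simplified and self.subsequent_lines:
            raise ConfigError(
                f"{self.label}.subsequent_lines",
                "simplified strategies route first-line failures straight to supportive care",
            )
        for line in self.subsequent_lines:
            line.validate()
        self.supportive_care.validate()

    def simplify(self) -> "StrategySpec":
        """Variant where first-line failures go directly to supportive care."""
        return replace(self, subsequent_lines=[], simplified=True,
                       label=f"{self.label} (simplified)")


@dataclass
class ModelConfig:
    """Everything one model run needs; unpacks as (strategies, economics, population)."""

    strategies: list[StrategySpec]
    economics: EconomicSettings
    population: PopulationProfile
    reference_label: str = "Leflunomide"
    alt_utility_mappings: list[UtilityMapping] = field(default_factory=list)
    defaults_applied: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[Any]:
        return iter((self.strategies, self.economics, self.population))

    def validate(self) -> None:
        if not self.strategies:
            raise ConfigError("strategies", "at least one strategy is required")
        labels = [s.label for s in self.strategies]
        if len(set(labels)) != len(labels):
            raise ConfigError("strategies", f"duplicate labels in {labels}")
        for s in self.strategies:
            s.validate()
        self.economics.validate()
        self.population.validate()

    def strategy(self, label: str) -> StrategySpec:
        for s in self.strategies:
            if s.label == label:
                return s
        raise KeyError(label)

    def provenance_manifest(self) -> dict[str, str]:
        """Dotted parameter name → "paper" | "synthetic", one entry each."""
        out: dict[str, str] = {}
        for name, obj in collect_params(self).items():
            out[name] = obj.provenance
        return out


# ---------------------------------------------------------------------------
# Market-share pooling
# ---------------------------------------------------------------------------


def _weighted_param(
    name: str, params: Sequence[Param], weights: Sequence[float]
) -> Param:
    value = float(sum(w * p.value for w, p in zip(weights, params)))
    family = params[0].dist.family
    sd = DEFAULT_SD_FRACTION * abs(value) if family != "fixed" else None
    provenance = "paper" if all(p.provenance == "paper" for p in params) else "synthetic"
    return Param(name, value, DistributionSpec(family, sd=sd), provenance)


def pool_by_market_share(
    drug_params: Sequence[TreatmentLineParams],
    shares: Sequence[float],
    name: str | None = None,
) -> TreatmentLineParams:
    """Collapse several drugs of one class into a share-weighted pseudo-drug.

    Efficacy, cost, discontinuation and adverse-event fields are weighted
    means; pooled uncertainty reverts to the 25%-of-mean SD rule.  Shares
    that do not sum to one are renormalised with a warning.
    """
    if not drug_params:
        raise ConfigError("pool_by_market_share", "empty drug list")
    if len(shares) != len(drug_params):
        raise ConfigError("pool_by_market_share", "one share per drug required")
    if any(s < 0 for s in shares):
        raise ConfigError("pool_by_market_share", f"negative share in {list(shares)}")
    total = float(sum(shares))
    if total <= 0:
        raise ConfigError("pool_by_market_share", "shares sum to zero")
    if abs(total - 1.0) > 1e-9:
        logger.warning(
            "market shares %s sum to %.6g; renormalising", list(shares), total
        )
    w = [s / total for s in shares]
    name = name or "pooled(" + "+".join(d.name for d in drug_params) + ")"

    def wp(attr: str) -> Param:
        return _weighted_param(
            f"{name}.{attr}", [getattr(d, attr) for d in drug_params], w
        )

    ae_probs = {}
    for ev in AE_EVENTS:
        if all(ev in d.ae_probs for d in drug_params):
            ae_probs[ev] = _weighted_param(
                f"{name}.ae_probs.{ev}", [d.ae_probs[ev] for d in drug_params], w
            )
    ae_costs = dict(drug_params[0].ae_costs)  # episode costs are class-independent

    acr = None
    if all(d.acr_response is not None for d in drug_params):
        rs = [d.acr_response for d in drug_params]
        acr = AcrResponse(
            name=f"{name}.acr_response",
            cum20=float(sum(wi * r.cum20 for wi, r in zip(w, rs))),
            cum50=float(sum(wi * r.cum50 for wi, r in zip(w, rs))),
            cum70=float(sum(wi * r.cum70 for wi, r in zip(w, rs))),
            sds=tuple(
                DEFAULT_SD_FRACTION * float(sum(wi * c for wi, c in zip(w, cums)))
                for cums in zip(*[(r.cum20, r.cum50, r.cum70) for r in rs])
            ),
            provenance="paper" if all(r.provenance == "paper" for r in rs) else "synthetic",
        )

    def opt(attr: str) -> Param | None:
        vals = [getattr(d, attr) for d in drug_params]
        if any(v is None for v in vals):
            return None
        return _weighted_param(f"{name}.{attr}", vals, w)

    pooled = TreatmentLineParams(
        name=name,
        drug_cost_first_cycle=wp("drug_cost_first_cycle"),
        drug_cost_subsequent=wp("drug_cost_subsequent"),
        discontinuation_prob=wp("discontinuation_prob"),
        ae_probs=ae_probs,
        ae_costs=ae_costs,
        is_tnfi=drug_params[0].is_tnfi,
        acr_response=acr,
        haq_change_mean=opt("haq_change_mean"),
        haq_change_experienced=opt("haq_change_experienced"),
        haq_change_by_category=drug_params[0].haq_change_by_category,
    )
    pooled.validate()
    return pooled


# ---------------------------------------------------------------------------
# Parameter registry (shared-object aware) for PSA / DSA
# ---------------------------------------------------------------------------


def collect_params(config: ModelConfig) -> dict[str, Param | AcrResponse]:
    """Unique uncertain objects in a config, keyed by dotted name.

    Objects shared between strategies (pooled subsequent lines, supportive
    care, episode costs) appear once, so one PSA draw moves every user.
    """
    seen: dict[int, str] = {}
    out: dict[str, Param | AcrResponse] = {}

    def add(obj: Param | AcrResponse | None) -> None:
        if obj is None or id(obj) in seen:
            return
        seen[id(obj)] = obj.name
        if obj.name in out:
            raise ConfigError(obj.name, "duplicate parameter name for distinct objects")
        out[obj.name] = obj

    def add_line(line: TreatmentLineParams) -> None:
        add(line.drug_cost_first_cycle)
        add(line.drug_cost_subsequent)
        add(line.discontinuation_prob)
        for p in line.ae_probs.values():
            add(p)
        for p in line.ae_costs.values():
            add(p)
        add(line.acr_response)
        if line.haq_change_by_category:
            for p in line.haq_change_by_category.values():
                add(p)
        add(line.haq_change_mean)
        add(line.haq_change_experienced)

    for s in config.strategies:
        add_line(s.first_line)
        for line in s.subsequent_lines:
            add_line(line)
        add(s.supportive_care.drug_cost_per_cycle)
        add(s.supportive_care.steroid_injection_cost)
        add(s.supportive_care.physiotherapy_cost_per_cycle)
    add(config.population.baseline_haq)
    return out


def apply_default_sds(config: ModelConfig) -> list[str]:
    """Fill missing SDs with 25% of the mean (the published convention); log each."""
    applied: list[str] = []
    for name, obj in collect_params(config).items():
        if isinstance(obj, Param):
            if obj.dist.family in ("beta", "gamma") and obj.dist.sd is None:
                obj.dist.sd = DEFAULT_SD_FRACTION * abs(obj.value)
                logger.info("defaulted SD of %s to 0.25 x mean = %g", name, obj.dist.sd)
                applied.append(name)
        elif isinstance(obj, AcrResponse) and obj.sds is None:
            obj.sds = (
                DEFAULT_SD_FRACTION * obj.cum20,
                DEFAULT_SD_FRACTION * obj.cum50,
                DEFAULT_SD_FRACTION * obj.cum70,
            )
            logger.info("defaulted ACR sds of %s to 0.25 x mean", name)
            applied.append(name)
    config.defaults_applied = applied
    return applied


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def _param_to_dict(p: Param) -> dict[str, Any]:
    d: dict[str, Any] = {"value": p.value, "dist": p.dist.family, "provenance": p.provenance}
    if p.dist.sd is not None:
        d["sd"] = p.dist.sd
    if p.dist.low is not None:
        d["range"] = [p.dist.low, p.dist.high]
    return d


def _param_from_dict(name: str, d: Any) -> Param:
    if isinstance(d, (int, float)):
        return Param(name, float(d), DistributionSpec("fixed"))
    if not isinstance(d, Mapping) or "value" not in d:
        raise ConfigError(name, f"expected a number or a mapping with 'value', got {d!r}")
    rng = d.get("range")
    p = Param(
        name,
        float(d["value"]),
        DistributionSpec(
            family=d.get("dist", "fixed"),
            sd=float(d["sd"]) if d.get("sd") is not None else None,
            low=float(rng[0]) if rng else None,
            high=float(rng[1]) if rng else None,
        ),
        provenance=d.get("provenance", "synthetic"),
    )
    p.validate()
    return p


def _acr_to_dict(r: AcrResponse) -> dict[str, Any]:
    d: dict[str, Any] = {
        "cum20": r.cum20,
        "cum50": r.cum50,
        "cum70": r.cum70,
        "provenance": r.provenance,
    }
    if r.sds is not None:
        d["sds"] = list(r.sds)
    return d


def _acr_from_dict(name: str, d: Mapping[str, Any]) -> AcrResponse:
    r = AcrResponse(
        name=name,
        cum20=float(d["cum20"]),
        cum50=float(d["cum50"]),
        cum70=float(d["cum70"]),
        sds=tuple(float(s) for s in d["sds"]) if d.get("sds") else None,
        provenance=d.get("provenance", "paper"),
    )
    r.validate()
    return r


def _line_to_dict(line: TreatmentLineParams) -> dict[str, Any]:
    d: dict[str, Any] = {
        "name": line.name,
        "is_tnfi": line.is_tnfi,
        "drug_cost_first_cycle": _param_to_dict(line.drug_cost_first_cycle),
        "drug_cost_subsequent": _param_to_dict(line.drug_cost_subsequent),
        "discontinuation_prob": _param_to_dict(line.discontinuation_prob),
        "ae_probs": {ev: _param_to_dict(p) for ev, p in line.ae_probs.items()},
    }
    if line.acr_response is not None:
        d["acr_response"] = _acr_to_dict(line.acr_response)
    if line.haq_change_mean is not None:
        d["haq_change_mean"] = _param_to_dict(line.haq_change_mean)
    if line.haq_change_experienced is not None:
        d["haq_change_experienced"] = _param_to_dict(line.haq_change_experienced)
    return d


def _line_from_dict(
    path: str,
    d: Mapping[str, Any],
    ae_costs: dict[str, Param],
    haq_by_cat: dict[str, Param] | None,
) -> TreatmentLineParams:
    name = d.get("name")
    if not name:
        raise ConfigError(f"{path}.name", "treatment line needs a name")
    # semantic, position-independent parameter names: first-line drugs get a
    # "first_line." prefix, pooled subsequent lines use their own pool name
    prefix = f"first_line.{name}" if "acr_response" in d else name
    line = TreatmentLineParams(
        name=name,
        is_tnfi=bool(d.get("is_tnfi", False)),
        drug_cost_first_cycle=_param_from_dict(
            f"{prefix}.drug_cost_first_cycle", d["drug_cost_first_cycle"]
        ),
        drug_cost_subsequent=_param_from_dict(
            f"{prefix}.drug_cost_subsequent", d["drug_cost_subsequent"]
        ),
        discontinuation_prob=_param_from_dict(
            f"{prefix}.discontinuation_prob", d["discontinuation_prob"]
        ),
        ae_probs={
            ev: _param_from_dict(f"{prefix}.ae_probs.{ev}", pd)
            for ev, pd in d.get("ae_probs", {}).items()
        },
        ae_costs=ae_costs,
        acr_response=(
            _acr_from_dict(f"{prefix}.acr_response", d["acr_response"])
            if "acr_response" in d
            else None
        ),
        haq_change_by_category=haq_by_cat if "acr_response" in d else None,
        haq_change_mean=(
            _param_from_dict(f"{prefix}.haq_change_mean", d["haq_change_mean"])
            if "haq_change_mean" in d
            else None
        ),
        haq_change_experienced=(
            _param_from_dict(
                f"{prefix}.haq_change_experienced", d["haq_change_experienced"]
            )
            if "haq_change_experienced" in d
            else None
        ),
    )
    return line


def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    """Serialisable form of a config; inverse of :func:`config_from_dict`."""
    eco, pop = config.economics, config.population
    sc = config.strategies[0].supportive_care
    shared_lines = next(
        (s.subsequent_lines for s in config.strategies if not s.simplified), []
    )
    first = config.strategies[0].first_line
    return {
        "economics": {
            "cycle_length_years": eco.cycle_length_years,
            "annual_discount_rate": eco.annual_discount_rate,
            "wtp_threshold": eco.wtp_threshold,
            "horizon_years": eco.horizon_years,
            "half_cycle_correction": eco.half_cycle_correction,
            "currency_note": eco.currency_note,
            "utility_mapping": {
                "intercept": eco.utility_mapping.intercept,
                "slope": eco.utility_mapping.slope,
                "label": eco.utility_mapping.label,
            },
        },
        "population": {
            "baseline_age": pop.baseline_age,
            "age_sd": pop.age_sd,
            "female_fraction": pop.female_fraction,
            "baseline_haq": _param_to_dict(pop.baseline_haq),
            "mortality_hr_per_haq": pop.mortality_hr_per_haq,
            "max_age": pop.max_age,
        },
        "ae_episode_costs": {
            ev: _param_to_dict(p) for ev, p in first.ae_costs.items()
        },
        "first_line_haq_changes": {
            cat: _param_to_dict(p)
            for cat, p in (first.haq_change_by_category or {}).items()
        },
        "supportive_care": {
            "drug_cost_per_cycle": _param_to_dict(sc.drug_cost_per_cycle),
            "steroid_injection_cost": _param_to_dict(sc.steroid_injection_cost),
            "physiotherapy_cost_per_cycle": _param_to_dict(sc.physiotherapy_cost_per_cycle),
            "haq_deltas": [sc.haq_delta_cycle1, sc.haq_delta_cycle2, sc.haq_delta_later],
            "include_nonpharma": sc.include_nonpharma,
            "max_steroid_cycles": sc.max_steroid_cycles,
        },
        "subsequent_lines": [_line_to_dict(line) for line in shared_lines],
        "alternative_utility_mappings": [
            {"intercept": m.intercept, "slope": m.slope, "label": m.label}
            for m in config.alt_utility_mappings
        ],
        "reference_label": config.reference_label,
        "strategies": [
            {
                "label": s.label,
                "simplified": s.simplified,
                "first_line": _line_to_dict(s.first_line),
            }
            for s in config.strategies
        ],
    }


def config_from_dict(raw: Mapping[str, Any]) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from a parsed YAML/JSON document."""
    for key in ("economics", "population", "strategies"):
        if key not in raw:
            raise ConfigError(key, "missing required section")

    e = raw["economics"]
    um = e.get("utility_mapping", {})
    economics = EconomicSettings(
        cycle_length_years=float(e.get("cycle_length_years", 0.5)),
        annual_discount_rate=float(e.get("annual_discount_rate", 0.035)),
        wtp_threshold=float(e.get("wtp_threshold", 48_555.0)),
        horizon_years=(
            float(e["horizon_years"]) if e.get("horizon_years") is not None else None
        ),
        half_cycle_correction=bool(e.get("half_cycle_correction", False)),
        currency_note=e.get("currency_note", EconomicSettings.currency_note),
        utility_mapping=UtilityMapping(
            intercept=float(um.get("intercept", 0.74)),
            slope=float(um.get("slope", -0.17)),
            label=um.get("label", "linear-0.74-0.17"),
        ),
    )

    p = raw["population"]
    population = PopulationProfile(
        baseline_age=float(p.get("baseline_age", 56.0)),
        age_sd=float(p.get("age_sd", 17.0)),
        female_fraction=float(p.get("female_fraction", 0.727)),
        baseline_haq=_param_from_dict("population.baseline_haq", p["baseline_haq"]),
        mortality_hr_per_haq=float(p.get("mortality_hr_per_haq", 1.33)),
        max_age=float(p.get("max_age", 100.0)),
    )

    ae_costs = {
        ev: _param_from_dict(f"ae_episode_costs.{ev}", pd)
        for ev, pd in raw.get("ae_episode_costs", {}).items()
    }
    haq_by_cat = {
        cat: _param_from_dict(f"first_line_haq_changes.{cat}", pd)
        for cat, pd in raw.get("first_line_haq_changes", {}).items()
    }

    scd = raw.get("supportive_care")
    if scd is None:
        raise ConfigError("supportive_care", "missing required section")
    deltas = scd.get("haq_deltas", [-0.04, 0.2, 0.28])
    supportive = SupportiveCareParams(
        drug_cost_per_cycle=_param_from_dict(
            "supportive_care.drug_cost_per_cycle", scd["drug_cost_per_cycle"]
        ),
        steroid_injection_cost=_param_from_dict(
            "supportive_care.steroid_injection_cost", scd["steroid_injection_cost"]
        ),
        physiotherapy_cost_per_cycle=_param_from_dict(
            "supportive_care.physiotherapy_cost_per_cycle",
            scd["physiotherapy_cost_per_cycle"],
        ),
        haq_delta_cycle1=float(deltas[0]),
        haq_delta_cycle2=float(deltas[1]),
        haq_delta_later=float(deltas[2]),
        include_nonpharma=bool(scd.get("include_nonpharma", True)),
        max_steroid_cycles=int(scd.get("max_steroid_cycles", 2)),
    )

    shared_lines = [
        _line_from_dict(f"subsequent_lines[{i}]", ld, ae_costs, None)
        for i, ld in enumerate(raw.get("subsequent_lines", []))
    ]

    strategies = []
    for i, sd in enumerate(raw["strategies"]):
        label = sd.get("label")
        if not label:
            raise ConfigError(f"strategies[{i}].label", "strategy needs a label")
        simplified = bool(sd.get("simplified", False))
        first = _line_from_dict(
            f"strategies[{i}].first_line", sd["first_line"], ae_costs, haq_by_cat
        )
        strategies.append(
            StrategySpec(
                label=label,
                first_line=first,
                subsequent_lines=[] if simplified else shared_lines,
                supportive_care=supportive,
                simplified=simplified,
            )
        )

    config = ModelConfig(
        strategies=strategies,
        economics=economics,
        population=population,
        reference_label=raw.get("reference_label", strategies[0].label),
        alt_utility_mappings=[
            UtilityMapping(
                intercept=float(m["intercept"]),
                slope=float(m["slope"]),
                label=m.get("label", "alternative"),
            )
            for m in raw.get("alternative_utility_mappings", [])
        ],
    )
    config.validate()
    apply_default_sds(config)
    return config


def load_config(path: str | Path) -> ModelConfig:
    """Load, validate and default-fill a model configuration (YAML or JSON)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(raw)


def save_config(config: ModelConfig, path: str | Path) -> None:
    path = Path(path)
    doc = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
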