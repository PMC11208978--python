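"""Probabilistic and deterministic sensitivity analysis.

PSA: every uncertain parameter is drawn jointly and independently per
iteration — Dirichlet for ACR response splits, beta for probabilities,
gamma for costs and HAQ-DI change magnitudes (sign restored), uniform for
range-only quantities — with method-of-moments fits to the declared mean/SD
(SD defaulting to 25% of the mean).  All strategies are evaluated on the
same draw; substreams are counter-based so results do not depend on
execution order.

DSA: one-way excursions over each scalar parameter's 95% CI (printed range
where available, else mean ± 1.96·SD), producing tornado entries sorted by
ICER bar width.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .engine import LifeTable, run_cohort
from .outcomes import StrategyResult, icer
from .parameters import (
    AcrResponse,
    ModelConfig,
    Param,
    acr_cumulative_to_categories,
    collect_params,
)

logger = logging.getLogger("biosimce")

Sampler = Callable[[np.random.Generator], float | tuple[float, ...]]


# ---------------------------------------------------------------------------
# Distribution fitting
# ---------------------------------------------------------------------------


def beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta parameters; raises if infeasible."""
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(f"beta moments infeasible: sd {sd} for mean {mean}")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale); with the 25%-SD rule shape = 16."""
    return (mean / sd) ** 2, sd * sd / mean


def dirichlet_effective_n(
    cum_means: Sequence[float], cum_sds: Sequence[float]
) -> float:
    """Effective sample size best matching the cumulative-component SDs.

    Under Dirichlet(α) with total N, any partial sum s of category means has
    SD sqrt(s(1−s)/(N+1)); the least-squares fit over the three cumulative
    components gives sqrt(N+1) = Σa² / Σ(a·t) with a = sqrt(s(1−s)).
    """
    a = np.sqrt([s * (1.0 - s) for s in cum_means])
    t = np.asarray(cum_sds, dtype=float)
    denom = float((a * t).sum())
    if denom <= 0:
        return math.inf
    root = float((a * a).sum()) / denom
    return max(root * root - 1.0, 1.0)


def _constant(value: float | tuple[float, ...]) -> Sampler:
    return lambda rng: value


def _scaled_range(p: Param, sd_scale: float) -> tuple[float, float] | None:
    d = p.dist
    if d.low is None or d.high is None:
        return None
    return (
        p.value - (p.value - d.low) * sd_scale,
        p.value + (d.high - p.value) * sd_scale,
    )


def fit_distribution(obj: Param | AcrResponse, sd_scale: float = 1.0) -> Sampler:
    """Build a PSA sampler for one uncertain parameter.

    ``sd_scale`` multiplies every declared SD (and shrinks uniform ranges
    toward the mean), supporting the continuity check PSA → base case.
    """
    if isinstance(obj, AcrResponse):
        return _fit_dirichlet(obj, sd_scale)

    family = obj.dist.family
    m = obj.value
    sd = (obj.dist.sd or 0.0) * sd_scale

    if family == "fixed" or sd == 0.0 and family != "uniform_range":
        return _constant(m)

    if family == "beta":
        if m <= 0.0 or m >= 1.0:
            return _constant(m)
        try:
            a, b = beta_moments(m, sd)
        except ValueError:
            rng_bounds = _scaled_range(obj, sd_scale)
            if rng_bounds is None:
                logger.warning(
                    "beta moments infeasible for %s and no range; holding fixed", obj.name
                )
                return _constant(m)
            logger.warning(
                "beta moments infeasible for %s; falling back to uniform on %s",
                obj.name,
                rng_bounds,
            )
            lo, hi = rng_bounds
            return lambda rng: float(rng.uniform(lo, hi))
        return lambda rng: float(rng.beta(a, b))

    if family == "gamma":
        mag = abs(m)
        if mag == 0.0:
            return _constant(m)
        shape, scale = gamma_moments(mag, sd)
        sign = -1.0 if m < 0 else 1.0
        return lambda rng: float(sign * rng.gamma(shape, scale))

    if family == "uniform_range":
        bounds = _scaled_range(obj, sd_scale)
        if bounds is None:
            return _constant(m)
        lo, hi = bounds
        return lambda rng: float(rng.uniform(lo, hi))

    raise ValueError(f"{obj.name}: unsupported family {family!r}")


def _fit_dirichlet(acr: AcrResponse, sd_scale: float) -> Sampler:
    cats = acr_cumulative_to_categories(acr).as_tuple()
    if acr.sds is None:
        return _constant(cats)
    sds = tuple(s * sd_scale for s in acr.sds)
    n_eff = dirichlet_effective_n((acr.cum20, acr.cum50, acr.cum70), sds)
    if not math.isfinite(n_eff):
        return _constant(cats)
    pos = [i for i, p in enumerate(cats) if p > 0]
    alphas = np.array([cats[i] for i in pos]) * n_eff

    def sample(rng: np.random.Generator) -> tuple[float, ...]:
        draw = rng.dirichlet(alphas)
        out = [0.0, 0.0, 0.0, 0.0]
        for i, v in zip(pos, draw):
            out[i] = float(v)
        return tuple(out)

    return sample


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PsaResult:
    """Draw-level PSA outputs: the cost-effectiveness plane scatter."""

    draws: pd.DataFrame  # iteration, strategy, cost, qaly
    n_iter: int
    n_failed: int
    seed: int

    def means(self) -> pd.DataFrame:
        return self.draws.groupby("strategy")[["cost", "qaly"]].mean()

    def wide(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        cost = self.draws.pivot(index="iteration", columns="strategy", values="cost")
        qaly = self.draws.pivot(index="iteration", columns="strategy", values="qaly")
        return cost.to_numpy(), qaly.to_numpy(), list(cost.columns)


def run_psa(
    config: ModelConfig,
    life_table: LifeTable,
    n_iter: int,
    seed: int,
    sd_scale: float = 1.0,
) -> PsaResult:
    """Monte-Carlo loop: one joint parameter draw per iteration, all
    strategies evaluated on the same draw; reproducible given the seed."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    base = collect_params(config)
    samplers = {
        name: fit_distribution(obj, sd_scale)
        for name, obj in base.items()
        if (isinstance(obj, AcrResponse) or obj.is_uncertain)
    }
    names = sorted(samplers)

    records = []
    n_failed = 0
    for i in range(n_iter):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        cfg = copy.deepcopy(config)
        reg = collect_params(cfg)
        for name in names:
            value = samplers[name](rng)
            obj = reg[name]
            if isinstance(obj, AcrResponse):
                obj.sampled_categories = value  # type: ignore[assignment]
            else:
                obj.value = float(value)  # type: ignore[arg-type]
        try:
            row = []
            for s in cfg.strategies:
                res = StrategyResult.from_trace(
                    run_cohort(s, cfg.economics, cfg.population, life_table)
                )
                if not (math.isfinite(res.cost) and math.isfinite(res.qaly)):
                    raise FloatingPointError(res.label)
                row.append(res)
        except (FloatingPointError, RuntimeError) as exc:
            n_failed += 1
            logger.warning("PSA iteration %d failed (%s); excluded", i, exc)
            continue
        for res in row:
            records.append(
                {"iteration": i, "strategy": res.label, "cost": res.cost, "qaly": res.qaly}
            )

    draws = pd.DataFrame.from_records(records)
    return PsaResult(draws=draws, n_iter=n_iter, n_failed=n_failed, seed=seed)


# ---------------------------------------------------------------------------
# Cost-effectiveness acceptability curve
# ---------------------------------------------------------------------------


def default_wtp_grid(grid_max: float = 80_000.0, step: float = 2_000.0) -> np.ndarray:
    return np.arange(0.0, grid_max + step / 2, step)


def ceac(result: PsaResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Probability each strategy has the highest net monetary benefit.

    At each willingness-to-pay the winner of every draw takes one unit of
    probability; exact ties split it equally.  Columns: wtp, strategy,
    probability (summing to one at each grid point).
    """
    if result.draws.empty:
        raise ValueError("no successful PSA draws")
    cost, qaly, labels = result.wide()
    rows = []
    for wtp in wtp_grid:
        nmb = wtp * qaly - cost
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb >= best - 1e-9
        credit = is_best / is_best.sum(axis=1, keepdims=True)
        probs = credit.mean(axis=0)
        for label, p in zip(labels, probs):
            rows.append({"wtp": float(wtp), "strategy": label, "probability": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis (tornado)
# ---------------------------------------------------------------------------


def default_comparison_pairs(config: ModelConfig) -> list[tuple[str, str]]:
    labels = [s.label for s in config.strategies]
    return [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i)]


def _evaluate(config: ModelConfig, life_table: LifeTable) -> dict[str, StrategyResult]:
    return {
        s.label: StrategyResult.from_trace(
            run_cohort(s, config.economics, config.population, life_table)
        )
        for s in config.strategies
    }


def tornado_dsa(
    config: ModelConfig,
    life_table: LifeTable,
    pairs: Sequence[tuple[str, str]] | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """One-way excursions of every scalar parameter with a declared range.

    ACR response splits carry no printed range and are varied jointly in the
    PSA only.  Returns one row per parameter per comparison pair, sorted
    within each pair by descending ICER bar width; ``non_monotone`` flags
    entries whose base-case ICER falls outside [low, high].
    """
    pairs = list(pairs) if pairs is not None else default_comparison_pairs(config)
    base = _evaluate(config, life_table)
    base_icer = {
        (a, b): icer(base[a], base[b], config.economics).icer for a, b in pairs
    }

    varied: list[tuple[str, tuple[float, float]]] = []
    for name, obj in collect_params(config).items():
        if isinstance(obj, Param) and obj.is_uncertain:
            rng = obj.ci_range()
            if rng is not None:
                varied.append((name, rng))

    rows = []
    for name, (lo, hi) in varied:
        side_results = []
        for bound in (lo, hi):
            cfg = copy.deepcopy(config)
            reg = collect_params(cfg)
            reg[name].value = bound  # type: ignore[union-attr]
            side_results.append(_evaluate(cfg, life_table))
        for a, b in pairs:
            icers = [
                icer(res[a], res[b], config.economics).icer for res in side_results
            ]
            vals = [v for v in icers if v is not None]
            bi = base_icer[(a, b)]
            width = abs(icers[1] - icers[0]) if len(vals) == 2 else np.nan
            non_mono = (
                bi is not None
                and len(vals) == 2
                and not (min(vals) - 1e-9 <= bi <= max(vals) + 1e-9)
            )
            rows.append(
                {
                    "comparator": a,
                    "reference": b,
                    "parameter": name,
                    "low": lo,
                    "high": hi,
                    "icer_low": icers[0],
                    "icer_high": icers[1],
                    "icer_base": bi,
                    "bar_width": width,
                    "non_monotone": non_mono,
                }
            )

    frame = pd.DataFrame(rows)
    frame = (
        frame.sort_values(
            ["comparator", "reference", "bar_width"], ascending=[True, True, False]
        )
        .reset_index(drop=True)
    )
    if top_k is not None:
        frame = (
            frame.groupby(["comparator", "reference"], sort=False)
            .head(top_k)
            .reset_index(drop=True)
        )
    return frame
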