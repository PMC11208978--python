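"""Sensitivity analyses: distribution fits, PSA reproducibility, CEAC, tornado."""

from __future__ import annotations

import copy
import logging

import numpy as np
import pandas as pd
import pytest

from biosimce import (
    AcrResponse,
    DistributionSpec,
    Param,
    StrategyResult,
    beta_moments,
    ceac,
    dirichlet_effective_n,
    fit_distribution,
    gamma_moments,
    run_cohort,
    run_psa,
    tornado_dsa,
)
from biosimce.parameters import collect_params
from biosimce.uncertainty import PsaResult, default_wtp_grid


def rng():
    return np.random.default_rng(42)


class TestFits:
    def test_gamma_quarter_sd_rule_gives_shape_16(self):
        shape, scale = gamma_moments(100.0, 25.0)
        assert shape == pytest.approx(16.0)
        assert scale == pytest.approx(6.25)

    def test_beta_moments_match_mean_and_sd(self):
        a, b = beta_moments(0.154, 0.025)
        m = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert m == pytest.approx(0.154)
        assert np.sqrt(var) == pytest.approx(0.025)

    def test_beta_infeasible_falls_back_to_range(self, caplog):
        p = Param("p", 0.5, DistributionSpec("beta", sd=0.6, low=0.2, high=0.8))
        with caplog.at_level(logging.WARNING, logger="biosimce"):
            sampler = fit_distribution(p)
        assert "infeasible" in caplog.text
        draws = [sampler(rng()) for _ in range(5)]
        assert all(0.2 <= d <= 0.8 for d in draws)

    def test_negative_mean_gamma_restores_sign(self):
        p = Param("h", -0.45, DistributionSpec("gamma", sd=0.1125))
        sampler = fit_distribution(p)
        draws = np.array([sampler(g) for g in [np.random.default_rng(i) for i in range(200)]])
        assert np.all(draws < 0)
        assert draws.mean() == pytest.approx(-0.45, abs=0.03)

    def test_dirichlet_draws_live_on_simplex(self):
        acr = AcrResponse("acr", 0.62, 0.38, 0.07, sds=(0.04, 0.04, 0.021))
        sampler = fit_distribution(acr)
        g = rng()
        for _ in range(100):
            draw = sampler(g)
            assert sum(draw) == pytest.approx(1.0, abs=1e-12)
            assert all(v >= 0 for v in draw)

    def test_dirichlet_zero_category_stays_zero(self):
        acr = AcrResponse("acr", 1.0, 0.5, 0.0, sds=(0.0, 0.05, 0.0))
        draw = fit_distribution(acr)(rng())
        assert draw[0] == 0.0 and draw[3] == 0.0  # no <ACR20, no >=ACR70 mass

    def test_effective_sample_size_reproduces_sds(self):
        cums, sds = (0.62, 0.38, 0.07), (0.04, 0.04, 0.021)
        n = dirichlet_effective_n(cums, sds)
        implied = [np.sqrt(c * (1 - c) / (n + 1)) for c in cums]
        assert implied == pytest.approx(list(sds), rel=0.35)


class TestPsa:
    def test_same_seed_bit_identical(self, base_config, life_table):
        a = run_psa(base_config, life_table, n_iter=5, seed=11)
        b = run_psa(base_config, life_table, n_iter=5, seed=11)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_different_seeds_differ(self, base_config, life_table):
        a = run_psa(base_config, life_table, n_iter=3, seed=1)
        b = run_psa(base_config, life_table, n_iter=3, seed=2)
        assert not a.draws.equals(b.draws)

    def test_degenerate_distributions_reproduce_base_case(
        self, base_config, life_table, base_results
    ):
        cfg = copy.deepcopy(base_config)
        for obj in collect_params(cfg).values():
            if isinstance(obj, Param):
                obj.dist = DistributionSpec("fixed")
            else:
                obj.sds = None
        res = run_psa(cfg, life_table, n_iter=3, seed=5)
        for label, r in base_results.items():
            sub = res.draws[res.draws.strategy == label]
            assert np.allclose(sub.cost, r.cost)
            assert np.allclose(sub.qaly, r.qaly)


class TestCeac:
    def make_result(self, cost, qaly, labels=("A", "B")):
        rows = []
        for i in range(len(cost)):
            for j, lab in enumerate(labels):
                rows.append(
                    {"iteration": i, "strategy": lab, "cost": cost[i][j], "qaly": qaly[i][j]}
                )
        return PsaResult(pd.DataFrame(rows), len(cost), 0, 0)

    def test_probabilities_partition_unity(self, base_config, life_table):
        res = run_psa(base_config, life_table, n_iter=20, seed=3)
        curve = ceac(res, default_wtp_grid())
        sums = curve.groupby("wtp").probability.sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_zero_wtp_rewards_cheapest(self):
        res = self.make_result(cost=[(10, 20), (30, 5)], qaly=[(1, 2), (1, 2)])
        curve = ceac(res, [0.0]).set_index("strategy").probability
        assert curve["A"] == 0.5 and curve["B"] == 0.5  # each wins one draw

    def test_single_strategy_probability_one(self):
        res = self.make_result(cost=[(10,), (20,)], qaly=[(1,), (1,)], labels=("only",))
        curve = ceac(res, [0.0, 50_000.0])
        assert (curve.probability == 1.0).all()

    def test_ties_split_equally(self):
        res = self.make_result(cost=[(10, 10)], qaly=[(1, 1)])
        curve = ceac(res, [10_000.0]).set_index("strategy").probability
        assert curve["A"] == 0.5 and curve["B"] == 0.5

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError, match="no successful"):
            ceac(PsaResult(pd.DataFrame(), 0, 0, 0), [0.0])


class TestTornado:
    def test_sorted_descending_and_flagged(self, base_config, life_table):
        frame = tornado_dsa(
            base_config, life_table, pairs=[("Biosimilar adalimumab", "Leflunomide")]
        )
        widths = frame.bar_width.to_numpy()
        assert np.all(np.diff(widths[~np.isnan(widths)]) <= 1e-9)
        assert {"parameter", "low", "high", "icer_low", "icer_high"} <= set(frame.columns)

    def test_zero_width_range_gives_zero_bar(self, base_config, life_table):
        cfg = copy.deepcopy(base_config)
        p = collect_params(cfg)["ae_episode_costs.pneumonia"]
        p.dist.low = p.dist.high = p.value
        frame = tornado_dsa(cfg, life_table, pairs=[("Biosimilar adalimumab", "Leflunomide")])
        row = frame[frame.parameter == "ae_episode_costs.pneumonia"].iloc[0]
        assert row.bar_width == pytest.approx(0.0, abs=1e-9)

    def test_cost_excursion_moves_delta_cost_linearly(self, base_config, life_table):
        """Unit drug price enters cost accrual linearly, so the strategy's
        lifetime cost is affine in it."""
        def total_cost(price):
            cfg = copy.deepcopy(base_config)
            reg = collect_params(cfg)
            reg["first_line.leflunomide.drug_cost_subsequent"].value = price
            s = cfg.strategy("Leflunomide")
            return StrategyResult.from_trace(
                run_cohort(s, cfg.economics, cfg.population, life_table)
            ).cost

        c0, c1, c2 = total_cost(100.0), total_cost(150.0), total_cost(200.0)
        assert c2 - c1 == pytest.approx(c1 - c0, rel=1e-9)

    def test_every_fixture_excursion_stays_cost_effective(
        self, base_config, life_table
    ):
        """One-way excursions never push an ICER above the willingness-to-pay
        threshold on the bundled fixture."""
        frame = tornado_dsa(base_config, life_table)
        wtp = base_config.economics.wtp_threshold
        gained = frame.dropna(subset=["icer_low", "icer_high"])
        assert (gained.icer_low < wtp).all()
        assert (gained.icer_high < wtp).all()
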